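"""End-to-end synthetic-study pipeline and its configuration.

``run_all`` chains every stage on generated data with known ground truth:
atlas -> cohort -> voxel analysis (GLM + TFCE + permutation FWE) ->
parcellation -> phenotype-coupled expression -> spatial-null surrogates ->
PLS gene ranking -> preranked GSEA on planted/decoy sets -> cell-type FPKM
-> SI/pSI gene sets -> GSEA on the cell-type sets.  A single top-level seed
is split into per-stage seeds with a counter-based rule
(``SeedSequence([seed, stage_index])``), so every stochastic stage is
reproducible and independent.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .gsea import gsea_preranked
from .nulls import generate_surrogates
from .pls import gene_z_scores, plsr_fit, validate_ranking, zscore_columns, zscore_vector
from .specificity import CELL_TYPES, derive_celltype_sets
from .synthetic import gen_atlas, gen_celltype_fpkm, gen_cohort, gen_expression, gen_genesets
from .voxelstats import TFCEParams, parcellate, voxel_analysis

__all__ = ["PipelineConfig", "StageError", "stage_seed", "run_all"]

logger = logging.getLogger(__name__)

_STAGES = (
    "atlas",
    "cohort",
    "vba",
    "expression",
    "genesets",
    "nulls",
    "gsea",
    "fpkm",
    "psi",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed (counter-based split, < 2**31)."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """Synthetic quick-start configuration (scaled-down study conditions)."""

    seed: int = 0
    # atlas / cohort
    shape: tuple[int, int, int] = (16, 16, 16)
    n_regions: int = 20
    n_per_group: int = 20
    effect_size: float = 1.5
    n_effect_regions: int = 2
    fwhm_mm: float = 3.0
    n_perm_fwe: int = 200
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    connectivity: int = 26
    # expression / ranking
    n_genes: int = 2000
    n_coupled: int = 50          # per sign
    rho: float = 0.8
    spatial_range: float = 5.0
    n_null: int = 200
    pls_components: int = 10
    pls_component: int = 1
    # enrichment
    n_decoy_sets: int = 50
    decoy_size_range: tuple[int, int] = (10, 50)
    gsea_n_perm: int = 1000
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    celltype_gsea_min_size: int = 3  # pSI marker panels are small at this scale
    # cell types
    fpkm_n_genes: int = 2000
    fpkm_fold: float = 10.0
    fpkm_samples_per_type: int = 5
    fpkm_specific_per_type: int = 5
    psi_n_perm: int = 100
    psi_threshold: float = 0.001

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("shape", "decoy_size_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full pipeline; optionally write all result tables.

    Returns a bundle with the atlas, truth records, stat maps, regional
    phenotype, ranking, enrichment tables (synthetic and cell-type
    collections), validation regression and provenance record.
    """
    cfg = config
    bundle: dict = {}

    def _stage(name, fn):
        try:
            logger.info("stage %s", name)
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise StageError(name, exc) from exc

    atlas = _stage("atlas", lambda: gen_atlas(cfg.shape, cfg.n_regions, stage_seed(cfg.seed, "atlas")))
    bundle["atlas"] = atlas

    effect_regions = set(atlas.region_ids[: cfg.n_effect_regions].tolist())

    def _cohort():
        return gen_cohort(
            atlas, cfg.n_per_group, cfg.effect_size, effect_regions,
            seed=stage_seed(cfg.seed, "cohort"),
        )

    cohort, cohort_truth = _stage("cohort", _cohort)
    bundle["cohort_truth"] = cohort_truth

    def _vba():
        params = TFCEParams(
            E=cfg.tfce_E, H=cfg.tfce_H, connectivity=cfg.connectivity,
            n_perm=cfg.n_perm_fwe, seed=stage_seed(cfg.seed, "vba"),
        )
        maps = voxel_analysis(cohort, params, fwhm_mm=cfg.fwhm_mm)
        phenotype = parcellate(maps["tfce"], atlas)
        return maps, phenotype

    maps, phenotype = _stage("vba", _vba)
    bundle["maps"] = maps
    bundle["phenotype"] = phenotype

    def _expression():
        coupling = {f"CPLP{i:03d}": cfg.rho for i in range(cfg.n_coupled)}
        coupling.update({f"CPLN{i:03d}": -cfg.rho for i in range(cfg.n_coupled)})
        return gen_expression(
            atlas, phenotype, cfg.n_genes, coupling,
            spatial_range=cfg.spatial_range, seed=stage_seed(cfg.seed, "expression"),
        )

    expression, expr_truth = _stage("expression", _expression)
    bundle["expression"] = expression
    bundle["expression_truth"] = expr_truth

    collection = _stage(
        "genesets",
        lambda: gen_genesets(
            expr_truth, list(expression.columns), cfg.n_decoy_sets,
            cfg.decoy_size_range, seed=stage_seed(cfg.seed, "genesets"),
        ),
    )
    bundle["genesets"] = collection

    def _rank():
        surrogates = generate_surrogates(
            phenotype.values, atlas.centroids, n_null=cfg.n_null,
            seed=stage_seed(cfg.seed, "nulls"),
        )
        X = zscore_columns(expression)
        y = zscore_vector(phenotype.values)
        model = plsr_fit(X, y, cfg.pls_components)
        ranking = gene_z_scores(X, y, surrogates, k=cfg.pls_component)
        validation = validate_ranking(expression, phenotype.values, ranking)
        return surrogates, model, ranking, validation

    surrogates, model, ranking, validation = _stage("nulls", _rank)
    bundle.update(
        surrogates=surrogates, pls_model=model, ranking=ranking, validation=validation
    )

    enrichment = _stage(
        "gsea",
        lambda: gsea_preranked(
            ranking, collection, n_perm=cfg.gsea_n_perm,
            seed=stage_seed(cfg.seed, "gsea"),
            min_size=cfg.gsea_min_size, max_size=cfg.gsea_max_size,
        ),
    )
    bundle["enrichment"] = enrichment

    def _fpkm():
        genes = [f"G{i:05d}" for i in range(cfg.fpkm_n_genes)]
        rng = np.random.default_rng(stage_seed(cfg.seed, "fpkm"))
        picks = rng.choice(
            genes, size=cfg.fpkm_specific_per_type * len(CELL_TYPES), replace=False
        )
        specific = {
            t: set(picks[i * cfg.fpkm_specific_per_type : (i + 1) * cfg.fpkm_specific_per_type])
            for i, t in enumerate(CELL_TYPES)
        }
        return gen_celltype_fpkm(
            cfg.fpkm_n_genes, specific, fold=cfg.fpkm_fold,
            n_samples_per_type=cfg.fpkm_samples_per_type,
            seed=stage_seed(cfg.seed, "fpkm"),
        )

    tables, fpkm_truth = _stage("fpkm", _fpkm)
    bundle["fpkm_truth"] = fpkm_truth

    def _psi():
        return derive_celltype_sets(
            tables, n_perm=cfg.psi_n_perm, seed=stage_seed(cfg.seed, "psi"),
            threshold=cfg.psi_threshold,
        )

    celltype_sets = _stage("psi", _psi)
    bundle["celltype_sets"] = celltype_sets

    def _celltype_gsea():
        out = {}
        base = stage_seed(cfg.seed, "gsea")
        for i, coll in enumerate(celltype_sets):
            out[f"series{i + 1}"] = gsea_preranked(
                ranking, coll, n_perm=cfg.gsea_n_perm, seed=base + 1 + i,
                min_size=cfg.celltype_gsea_min_size, max_size=cfg.gsea_max_size,
            )
        return out

    celltype_enrichment = _stage("gsea", _celltype_gsea)
    bundle["celltype_enrichment"] = celltype_enrichment

    provenance = {
        "config": cfg.to_dict(),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
        "n_genes_ranked": int(len(ranking)),
        "explained_variance_y": model.explained_variance_y.tolist(),
        "score_phenotype_corr": model.score_phenotype_corr.tolist(),
    }
    bundle["provenance"] = provenance

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.save_atlas(atlas, outdir / "atlas.nii.gz")
        io.save_nifti(maps["t"].values, outdir / "tmap.nii.gz")
        io.save_nifti(maps["tfce"].values, outdir / "tfce.nii.gz")
        io.save_nifti(maps["p_fwe"].values, outdir / "p_fwe.nii.gz")
        io.write_phenotype(phenotype, outdir / "regional_phenotype.tsv")
        io.write_tsv(expression, outdir / "expression.tsv")
        io.write_gmt(collection, outdir / "genesets.gmt")
        io.write_tsv(ranking, outdir / "gene_ranking.tsv")
        io.write_tsv(validation, outdir / "ranking_validation.tsv")
        enr = enrichment.copy()
        enr["leading_edge"] = enr["leading_edge"].map(",".join)
        io.write_tsv(enr, outdir / "enrichment.tsv")
        for coll in celltype_sets:
            name = next(iter(coll.sets)).split("_")[0]
            io.write_gmt(coll, outdir / f"celltype_{name}.gmt")
        for series, table in celltype_enrichment.items():
            tab = table.copy()
            tab["leading_edge"] = tab["leading_edge"].map(",".join)
            io.write_tsv(tab, outdir / f"celltype_enrichment_{series}.tsv")
        io.write_provenance(provenance, outdir / "provenance.json")
    return bundle
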