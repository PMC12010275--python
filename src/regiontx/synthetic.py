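"""Synthetic study inputs with known ground truth.

Every input the pipeline consumes can be generated here: a Voronoi
parcellation atlas, a two-group voxel cohort with a planted focal group
effect and age/sex covariates, a regions x genes expression matrix whose
planted genes are coupled (positively or negatively) to a regional
phenotype on top of spatially autocorrelated noise, six-cell-type FPKM
tables with planted specific genes (three independent series), and gene-set
collections containing the planted sets among random decoys.

All generators are fully determined by their integer seed.  The defaults
mirror the study conditions the pipeline targets: an 83-region
parcellation, unit-variance Gaussian voxel noise, age ~ U(45, 75) years and
sex ~ Bernoulli(0.5) covariates, exponential-kernel spatial autocorrelation
of expression noise on region centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .gsea import GeneSetCollection
from .specificity import CELL_TYPES, CellTypeTable
from .voxelstats import RegionalPhenotype, VoxelCohort

__all__ = [
    "ParcellationAtlas",
    "SyntheticTruth",
    "gen_atlas",
    "gen_cohort",
    "gen_expression",
    "gen_celltype_fpkm",
    "gen_genesets",
]

DEFAULT_N_REGIONS = 83  # emulates the volumetric Desikan-Killiany parcellation


@dataclass
class ParcellationAtlas:
    """Integer label volume (0 = background) with region ids and centroids."""

    labels: np.ndarray
    region_ids: np.ndarray
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        present = set(np.unique(self.labels)) - {0}
        if present != set(self.region_ids.tolist()):
            raise ValueError("region_ids do not match labels present in the volume")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("non-finite centroid")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators.

    effect_mask: boolean grid of the planted group effect.
    effect_size: standardized mean difference (Cohen's d).
    coupled_genes: gene symbol -> coupling coefficient rho in [-1, 1].
    specific_genes: cell type -> planted specific gene symbols.
    """

    seed: int
    effect_mask: np.ndarray | None = None
    effect_size: float = 0.0
    coupled_genes: dict[str, float] = field(default_factory=dict)
    specific_genes: dict[str, set[str]] = field(default_factory=dict)


def gen_atlas(
    shape: tuple[int, int, int], n_regions: int = DEFAULT_N_REGIONS, seed: int = 0
) -> ParcellationAtlas:
    """Voronoi parcellation: contiguous regions around random seed voxels.

    Every voxel is assigned to its nearest seed point, so regions are
    convex on the grid, pairwise disjoint, non-empty and cover the volume.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 2 for s in shape):
        raise ValueError("each grid dimension must be >= 2")
    n_vox = int(np.prod(shape))
    if not 1 <= n_regions <= n_vox:
        raise ValueError("n_regions must be in [1, voxel count]")
    rng = np.random.default_rng(seed)
    flat_seeds = rng.choice(n_vox, size=n_regions, replace=False)
    seed_coords = np.column_stack(np.unravel_index(flat_seeds, shape)).astype(float)
    grid = np.column_stack(
        [g.ravel() for g in np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")]
    ).astype(float)
    _, nearest = cKDTree(seed_coords).query(grid)
    labels = (nearest + 1).reshape(shape)
    region_ids = np.arange(1, n_regions + 1)
    centroids = np.array(
        [grid[(labels.ravel() == r)].mean(axis=0) for r in region_ids]
    )
    return ParcellationAtlas(labels, region_ids, centroids)


def gen_cohort(
    atlas: ParcellationAtlas,
    n_per_group: int,
    effect_size: float,
    effect_regions: set[int] | list[int] = (),
    covariate_slopes: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[VoxelCohort, SyntheticTruth]:
    """Two-group voxel cohort with a planted focal effect and covariates.

    Subject volumes are unit-variance Gaussian noise; patients (group 1)
    additionally carry ``effect_size`` inside the voxels of
    ``effect_regions`` (so the planted voxel-wise Cohen's d equals
    effect_size), and age/sex covariate contributions are added everywhere
    with the given slopes (default 0).
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    effect_regions = set(int(r) for r in effect_regions)
    unknown = effect_regions - set(atlas.region_ids.tolist())
    if unknown:
        raise ValueError(f"unknown effect regions: {sorted(unknown)}")
    slopes = {"age": 0.0, "sex": 0.0}
    slopes.update(covariate_slopes or {})
    rng = np.random.default_rng(seed)

    n = 2 * n_per_group
    group = np.repeat([0, 1], n_per_group)
    age = rng.uniform(45.0, 75.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    effect_mask = np.isin(atlas.labels, list(effect_regions)) & atlas.mask

    data = rng.standard_normal((n, *atlas.labels.shape))
    data += effect_size * (group[:, None, None, None] * effect_mask[None])
    drift = slopes["age"] * age + slopes["sex"] * sex
    data += drift[:, None, None, None]

    cohort = VoxelCohort(
        data,
        group,
        np.column_stack([age, sex]),
        atlas.mask,
        covariate_names=("age", "sex"),
    )
    truth = SyntheticTruth(seed=seed, effect_mask=effect_mask, effect_size=effect_size)
    return cohort, truth


def _spatial_noise(
    centroids: np.ndarray, n_draws: int, spatial_range: float, rng: np.random.Generator
) -> np.ndarray:
    """(R x n_draws) zero-mean draws with exponential spatial covariance."""
    d = squareform(pdist(centroids))
    cov = np.exp(-d / spatial_range)
    cov[np.diag_indices_from(cov)] += 1e-8
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((len(centroids), n_draws))


def _zscore(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return (a - a.mean(axis=axis, keepdims=True)) / a.std(
        axis=axis, ddof=1, keepdims=True
    )


def gen_expression(
    atlas: ParcellationAtlas,
    phenotype: RegionalPhenotype,
    n_genes: int,
    coupling: dict[str, float] | None = None,
    spatial_range: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Regions x genes expression with planted phenotype-coupled genes.

    Coupled gene g is rho_g * z(phenotype) + sqrt(1 - rho_g^2) * z(noise_g),
    uncoupled genes are pure noise; all noise fields share an exponential
    spatial covariance exp(-d / spatial_range) on region centroids, so the
    matrix carries the autocorrelation the surrogate nulls must preserve.
    Gene symbols: coupling keys first, then generated fillers, in a
    seed-shuffled column order.
    """
    coupling = dict(coupling or {})
    if n_genes < len(coupling):
        raise ValueError("n_genes smaller than the number of coupled genes")
    if any(abs(r) > 1 for r in coupling.values()):
        raise ValueError("coupling coefficients must satisfy |rho| <= 1")
    if len(phenotype.values) != atlas.n_regions:
        raise ValueError("phenotype not defined on the atlas regions")
    rng = np.random.default_rng(seed)
    n_fill = n_genes - len(coupling)
    symbols = list(coupling) + [f"G{i:05d}" for i in range(n_fill)]
    order = rng.permutation(n_genes)
    symbols = [symbols[i] for i in order]
    rho = np.array([coupling.get(s, 0.0) for s in symbols])

    noise = _zscore(_spatial_noise(atlas.centroids, n_genes, spatial_range, rng))
    zy = _zscore(phenotype.values)[:, None]
    values = rho[None, :] * zy + np.sqrt(1.0 - rho[None, :] ** 2) * noise
    expr = pd.DataFrame(values, index=phenotype.region_ids, columns=symbols)
    expr.index.name = "region"
    truth = SyntheticTruth(seed=seed, coupled_genes=coupling)
    return expr, truth


def gen_celltype_fpkm(
    n_genes: int,
    specific: dict[str, set[str]] | None = None,
    fold: float = 10.0,
    n_samples_per_type: int = 5,
    seed: int = 0,
    n_series: int = 3,
) -> tuple[list[CellTypeTable], SyntheticTruth]:
    """Log-normal FPKM tables for the six cell types, three series.

    Each series draws independent per-gene baselines (log-normal, shared
    across cell types so that between-type fold changes are driven by
    sampling noise alone) and per-sample noise; planted genes have their
    FPKM multiplied by ``fold`` in the samples of their own cell type and
    draw their baseline from the upper part of the expression distribution
    (mean log-FPKM 2 instead of 1), emulating canonical marker panels,
    which are small and robustly expressed.  The series emulate independent
    RNA-seq studies: same gene universe and planted truth, fresh noise.
    """
    specific = {t: set(g) for t, g in (specific or {}).items()}
    unknown = set(specific) - set(CELL_TYPES)
    if unknown:
        raise ValueError(f"unknown cell types: {sorted(unknown)}")
    all_planted: list[str] = [g for s in specific.values() for g in s]
    if len(all_planted) != len(set(all_planted)):
        raise ValueError("planted gene sets overlap across cell types")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    symbols = [f"G{i:05d}" for i in range(n_genes)]
    missing = set(all_planted) - set(symbols)
    if missing:
        raise ValueError(f"planted genes outside the gene universe: {sorted(missing)}")

    root = np.random.default_rng(seed)
    tables = []
    for s in range(n_series):
        rng = np.random.default_rng(root.integers(2**31))
        base = np.exp(rng.normal(1.0, 1.0, size=n_genes))  # per-gene baseline FPKM
        if all_planted:
            planted_idx = [symbols.index(g) for g in all_planted]
            base[planted_idx] = np.exp(rng.normal(2.0, 0.5, size=len(planted_idx)))
        cols, types = [], []
        for t in CELL_TYPES:
            mult = np.ones(n_genes)
            if t in specific and specific[t]:
                idx = [symbols.index(g) for g in sorted(specific[t])]
                mult[idx] = fold
            for j in range(n_samples_per_type):
                noise = np.exp(rng.normal(0.0, 0.5, size=n_genes))
                cols.append(base * mult * noise)
                types.append(t)
        fpkm = pd.DataFrame(
            np.column_stack(cols),
            index=symbols,
            columns=[f"{t}_{i}" for i, t in enumerate(types)],
        )
        tables.append(CellTypeTable(fpkm, tuple(types), series_id=f"series{s + 1}"))
    truth = SyntheticTruth(seed=seed, specific_genes=specific)
    return tables, truth


def gen_genesets(
    truth: SyntheticTruth,
    gene_symbols: list[str],
    n_decoys: int = 50,
    size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> GeneSetCollection:
    """Planted-positive / planted-negative sets plus uniform random decoys.

    The planted sets collect the truth's coupled genes with rho > 0 and
    rho < 0; decoys are drawn uniformly without replacement from the gene
    universe with sizes uniform in ``size_range``.
    """
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(gene_symbols):
        raise ValueError("size_range outside the gene universe")
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {}
    pos = {g for g, r in truth.coupled_genes.items() if r > 0}
    neg = {g for g, r in truth.coupled_genes.items() if r < 0}
    if pos:
        sets["planted_positive"] = pos
    if neg:
        sets["planted_negative"] = neg
    for i in range(n_decoys):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_symbols, size=size, replace=False)
        sets[f"decoy_{i:03d}"] = set(members.tolist())
    desc = {n: ("planted" if n.startswith("planted") else "random decoy") for n in sets}
    return GeneSetCollection(sets, desc, namespace="synthetic")
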