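"""Standard-format I/O: NIfTI volumes, TSV tables, GMT collections, JSON
provenance.  Region and gene identifiers are carried in every table so
downstream joins are by key, never by position."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .gsea import read_gmt, write_gmt  # noqa: F401  (re-exported)
from .synthetic import ParcellationAtlas
from .voxelstats import RegionalPhenotype

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_atlas",
    "load_atlas",
    "write_tsv",
    "read_tsv",
    "write_phenotype",
    "read_phenotype",
    "read_gmt",
    "write_gmt",
    "write_provenance",
]


def save_nifti(volume: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_atlas(atlas: ParcellationAtlas, path) -> None:
    save_nifti(atlas.labels.astype(float), path)


def load_atlas(path) -> ParcellationAtlas:
    labels = np.rint(load_nifti(path)).astype(int)
    region_ids = np.array(sorted(set(np.unique(labels)) - {0}))
    grid = np.column_stack(
        [g.ravel() for g in np.meshgrid(*[np.arange(s) for s in labels.shape], indexing="ij")]
    ).astype(float)
    centroids = np.array(
        [grid[labels.ravel() == r].mean(axis=0) for r in region_ids]
    )
    return ParcellationAtlas(labels, region_ids, centroids)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_tsv(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_phenotype(phenotype: RegionalPhenotype, path) -> None:
    pd.DataFrame(
        {"value": phenotype.values}, index=pd.Index(phenotype.region_ids, name="region")
    ).to_csv(path, sep="\t")


def read_phenotype(path) -> RegionalPhenotype:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RegionalPhenotype(df.index.to_numpy(), df["value"].to_numpy())


def write_provenance(record: dict, path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
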