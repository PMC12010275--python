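"""Shared fixtures: small synthetic study objects and independent naive
oracles (deliberately slow, loop-based re-implementations used to verify
the vectorised production code)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import regiontx as rt


@pytest.fixture(scope="session")
def small_atlas():
    return rt.gen_atlas((12, 12, 12), 10, seed=1)


@pytest.fixture(scope="session")
def recovery_study():
    """One scaled-down study with planted coupled genes, shared by tests.

    Pipeline-derived phenotype (parcellated TFCE map of a focal planted
    effect), 83 regions, 2000 genes with 50+50 genes coupled at rho=+-0.8,
    200 surrogate maps.
    """
    atlas = rt.gen_atlas((16, 16, 16), 83, seed=0)
    cohort, _ = rt.gen_cohort(atlas, 20, 1.5, set(atlas.region_ids[:3].tolist()), seed=50)
    tmap = rt.fit_glm_tmap(cohort)
    tfce = rt.tfce_enhance(tmap, rt.TFCEParams())
    phenotype = rt.parcellate(tfce, atlas)
    coupling = {f"CP{i:03d}": 0.8 for i in range(50)}
    coupling.update({f"CN{i:03d}": -0.8 for i in range(50)})
    expression, truth = rt.gen_expression(atlas, phenotype, 2000, coupling, seed=100)
    surrogates = rt.generate_surrogates(phenotype.values, atlas.centroids, n_null=200, seed=200)
    X = rt.zscore_columns(expression)
    y = rt.zscore_vector(phenotype.values)
    ranking = rt.gene_z_scores(X, y, surrogates, k=1)
    return {
        "atlas": atlas,
        "phenotype": phenotype,
        "expression": expression,
        "truth": truth,
        "coupling": coupling,
        "surrogates": surrogates,
        "X": X,
        "y": y,
        "ranking": ranking,
    }


@pytest.fixture(scope="session")
def tfce_naive():
    """Independent per-component TFCE summation (nested loops)."""

    def compute(values, mask, E, H, dh, connectivity):
        vals = np.where(mask, np.asarray(values, float), 0.0)
        struct = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
        out = np.zeros_like(vals)
        for sign in (1.0, -1.0):
            m = np.clip(sign * vals, 0, None)
            hmax = m.max()
            k = 0
            while (k + 0.5) * dh <= hmax:
                h = (k + 0.5) * dh
                labels, n = ndimage.label(m >= h, structure=struct)
                for comp in range(1, n + 1):
                    sel = labels == comp
                    out += sign * sel * (sel.sum() ** E * h**H * dh)
                k += 1
        return out

    return compute


@pytest.fixture(scope="session")
def es_naive():
    """Independent running-sum enrichment score (plain loop)."""

    def compute(genes, z, gene_set, p_weight):
        n = len(genes)
        hits = np.array([g in gene_set for g in genes])
        w = np.where(hits, np.abs(z) ** p_weight, 0.0)
        total = w.sum()
        dec = 1.0 / (n - hits.sum())
        cur, best = 0.0, 0.0
        for i in range(n):
            cur += w[i] / total if hits[i] else -dec
            if abs(cur) > abs(best):
                best = cur
        return best

    return compute


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ranking(z, genes=None):
    """Build a GeneRanking-shaped table from a z vector (sorted descending)."""
    z = np.asarray(z, dtype=float)
    if genes is None:
        genes = [f"g{i:04d}" for i in range(len(z))]
    order = np.argsort(-z, kind="stable")
    return pd.DataFrame(
        {"z": z[order]}, index=pd.Index(np.asarray(genes)[order], name="gene")
    )
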