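"""PLS-regression gene ranking calibrated against spatial nulls.

The regional phenotype (parcellated TFCE map) is regressed on the regions x
genes expression matrix by univariate-response PLS (NIPALS with deflation;
unit-norm weight vectors per component).  Component weights are
sign-aligned so that a large positive aligned weight means the gene's
expression correlates positively with the phenotype.  Each gene's Z
statistic is its observed aligned weight divided by the standard deviation
of the aligned weights obtained by refitting the PLS against
spatial-autocorrelation-preserving surrogate phenotypes, so the ranking is
calibrated against chance spatial alignment rather than against an
exchangeable null.  A region-resampling bootstrap SD is available as an
alternative denominator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nulls import SurrogateEnsemble

__all__ = [
    "PLSModel",
    "zscore_columns",
    "zscore_vector",
    "plsr_fit",
    "align_weights",
    "gene_z_scores",
    "bootstrap_weight_sd",
    "validate_ranking",
]

logger = logging.getLogger(__name__)


@dataclass
class PLSModel:
    """Univariate-response PLS fit.

    weights: G x K unit-norm weight vectors.  scores: R x K orthogonal
    latent scores.  explained_variance_y/x: per-component fractions of the
    response / predictor variance captured.  score_phenotype_corr: Pearson
    r between each score and the response.
    """

    weights: np.ndarray
    scores: np.ndarray
    y_loadings: np.ndarray
    explained_variance_y: np.ndarray
    explained_variance_x: np.ndarray
    score_phenotype_corr: np.ndarray
    gene_symbols: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


def zscore_columns(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Column-wise z-scoring; zero-variance columns are dropped with a warning."""
    sd = matrix.std(ddof=ddof)
    keep = sd > 0
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(f"dropped {n_drop} zero-variance columns")
        logger.info("zscore_columns: dropped %d zero-variance columns", n_drop)
    kept = matrix.loc[:, keep]
    return (kept - kept.mean()) / kept.std(ddof=ddof)


def zscore_vector(vector: np.ndarray, ddof: int = 1) -> np.ndarray:
    vector = np.asarray(vector, dtype=float)
    sd = vector.std(ddof=ddof)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (vector - vector.mean()) / sd


def plsr_fit(X: pd.DataFrame | np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """NIPALS PLS regression with a univariate response.

    Per component: w = X'y / ||X'y|| (for component 1 this makes the weight
    vector proportional to the vector of gene-phenotype covariances), score
    t = Xw, then X and y are deflated by the rank-one score regression.
    Explained response variance per component is q_k^2 ||t_k||^2 / ||y||^2
    (scores are mutually orthogonal, so the increments add up to the
    cumulative R^2).
    """
    if isinstance(X, pd.DataFrame):
        symbols = np.asarray(X.columns)
        Xc = X.to_numpy(dtype=float).copy()
    else:
        Xc = np.array(X, dtype=float)
        symbols = np.array([f"G{i:05d}" for i in range(Xc.shape[1])])
    y = np.asarray(y, dtype=float)
    r, g = Xc.shape
    if not 1 <= n_components <= min(r - 1, g):
        raise ValueError("n_components must be in [1, min(R-1, G)]")
    Xc = Xc - Xc.mean(axis=0)
    yc = y - y.mean()
    y0 = yc.copy()
    ss_y = float(y0 @ y0)
    ss_x = float(np.sum(Xc**2))

    W = np.empty((g, n_components))
    T = np.empty((r, n_components))
    Q = np.empty(n_components)
    ev_y = np.empty(n_components)
    ev_x = np.empty(n_components)
    corr = np.empty(n_components)
    for k in range(n_components):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(f"response fully deflated before component {k + 1}")
        w /= norm
        t = Xc @ w
        tt = float(t @ t)
        p = Xc.T @ t / tt
        q = float(yc @ t) / tt
        W[:, k], T[:, k], Q[k] = w, t, q
        ev_y[k] = q**2 * tt / ss_y
        ev_x[k] = tt * float(p @ p) / ss_x
        corr[k] = float(np.corrcoef(t, y0)[0, 1])
        Xc -= np.outer(t, p)
        yc = yc - q * t
    return PLSModel(W, T, Q, ev_y, ev_x, corr, symbols)


def align_weights(model: PLSModel, y: np.ndarray, k: int = 1) -> np.ndarray:
    """Sign-align component-k weights with the phenotype.

    The NIPALS weight sign is arbitrary for deflated components, so the
    aligned weights flip sign whenever the component scores correlate
    negatively with the phenotype.  After alignment a large positive weight
    marks a gene whose expression rises with the phenotype, which is the
    convention the top/bottom-gene validation checks.
    """
    if not 1 <= k <= model.n_components:
        raise ValueError(f"component {k} outside 1..{model.n_components}")
    r = float(np.corrcoef(model.scores[:, k - 1], np.asarray(y, float))[0, 1])
    if r == 0 or not np.isfinite(r):
        warnings.warn("score-phenotype correlation is zero; weight sign kept")
        return model.weights[:, k - 1].copy()
    return np.sign(r) * model.weights[:, k - 1]


def _aligned_component_weights(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    model = plsr_fit(X, y, k)
    return align_weights(model, y, k)


def gene_z_scores(
    X: pd.DataFrame,
    y: np.ndarray,
    surrogates: SurrogateEnsemble,
    k: int = 1,
) -> pd.DataFrame:
    """Null-calibrated gene ranking from PLS component k.

    The PLS is refitted against every surrogate phenotype map; each gene's
    Z is its observed aligned weight divided by the SD of its aligned
    weights across surrogates.  Genes whose null SD is zero are excluded
    (logged).  The table is ordered by descending Z (ties broken by gene
    symbol) and carries columns aligned_weight, z, rank.
    """
    if surrogates.maps.shape[1] != X.shape[0]:
        raise ValueError("surrogates not defined on the expression regions")
    Xv = X.to_numpy(dtype=float)
    symbols = np.asarray(X.columns)
    w_obs = _aligned_component_weights(Xv, np.asarray(y, float), k)
    null_w = np.empty((surrogates.n_null, Xv.shape[1]))
    for i in range(surrogates.n_null):
        null_w[i] = _aligned_component_weights(Xv, surrogates.maps[i], k)
    sd = null_w.std(axis=0, ddof=1)
    bad = sd == 0
    if bad.any():
        logger.warning("excluding %d genes with zero null SD", int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bad, np.nan, w_obs / sd)
    out = pd.DataFrame(
        {"aligned_weight": w_obs, "z": z}, index=pd.Index(symbols, name="gene")
    )
    out = out[~bad]
    # descending Z; deterministic tie-break by gene symbol
    order = np.lexsort((out.index.to_numpy(), -out["z"].to_numpy()))
    out = out.iloc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def bootstrap_weight_sd(
    X: pd.DataFrame, y: np.ndarray, k: int = 1, n_boot: int = 1000, seed: int = 0
) -> np.ndarray:
    """Region-resampling bootstrap SD of the aligned component-k weights.

    Alternative Z denominator; resamples regions with replacement.
    """
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, float)
    r = Xv.shape[0]
    w = np.empty((n_boot, Xv.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, r, size=r)
        while len(np.unique(idx)) < 3 or np.std(y[idx]) == 0:
            idx = rng.integers(0, r, size=r)
        w[b] = _aligned_component_weights(Xv[idx], y[idx], k)
    return w.std(axis=0, ddof=1)


def validate_ranking(
    X_raw: pd.DataFrame, y: np.ndarray, ranking: pd.DataFrame, k_top: int = 5
) -> pd.DataFrame:
    """Univariate regression check of the extreme-ranked genes.

    Regresses each of the top-k and bottom-k genes' expression on the
    phenotype; on a sound ranking the top genes have positive slopes and
    the bottom genes negative ones.
    """
    genes = ranking.index.to_numpy()
    if 2 * k_top > X_raw.shape[1]:
        raise ValueError("k_top exceeds half the gene universe")
    y = np.asarray(y, dtype=float)
    rows = []
    for end, selected in (("top", genes[:k_top]), ("bottom", genes[-k_top:])):
        for gene in selected:
            fit = stats.linregress(y, X_raw[gene].to_numpy(dtype=float))
            rows.append(
                {"gene": gene, "end": end, "slope": fit.slope, "r": fit.rvalue}
            )
    return pd.DataFrame(rows).set_index("gene")
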