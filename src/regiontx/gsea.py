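"""Preranked gene-set enrichment: weighted running-sum ES, NES, permutation
p-values, the GSEA-style NES-based FDR, leading-edge extraction and
Jaccard-overlap redundancy pruning.

The ranking statistic is the null-calibrated per-gene Z from
:mod:`regiontx.pls`.  Hits climb the running sum by |Z|^p / sum |Z|^p and
misses descend by 1/(N - |S|); the enrichment score is the signed maximum
deviation.  The permutation unit is gene labels (preranked mode): a null set
of the same size is drawn uniformly from the ranked universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "enrichment_score",
    "gsea_preranked",
    "prune_redundant",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions and a namespace tag."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    namespace: str = "synthetic"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            self.sets[name] = set(genes)
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB gene ...).

    Duplicate genes within a set are removed; sets left empty are skipped
    with a warning; a line with fewer than 3 fields is a parse error.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            genes = {g for g in fields[2:] if g}
            if not genes:
                warnings.warn(f"{path}: line {lineno}: empty set {name!r} skipped")
                continue
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def _running_sum(
    hits: np.ndarray, weights: np.ndarray, p_weight: float
) -> np.ndarray:
    """Running enrichment statistic over the ranked list."""
    n = len(hits)
    n_hit = int(hits.sum())
    w = np.abs(weights) ** p_weight
    w = np.where(hits, w, 0.0)
    total = w.sum()
    if total > 0:
        inc = w / total
    else:  # degenerate all-zero weights: unweighted hits
        inc = hits / n_hit
    dec = 1.0 / (n - n_hit)
    return np.cumsum(np.where(hits, inc, -dec))


def enrichment_score(
    ranking: pd.DataFrame, gene_set: set[str], p_weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """ES, running sum and leading edge of one gene set on a ranking.

    ``ranking`` is the GeneRanking table (index = gene symbols in rank
    order, column ``z``).  The leading edge ("core enrichment") is the hit
    genes at or before the running-sum extremum (after it for negative ES).
    """
    genes = np.asarray(ranking.index)
    z = ranking["z"].to_numpy()
    hits = np.isin(genes, list(gene_set))
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if n_hit == len(genes):
        raise ValueError("gene set equals the ranked universe")
    running = _running_sum(hits, z, p_weight)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = genes[: i_ext + 1][hits[: i_ext + 1]]
    else:
        leading = genes[i_ext:][hits[i_ext:]]
    return es, running, list(leading)


def _null_es(
    z: np.ndarray, size: int, n_perm: int, p_weight: float, rng: np.random.Generator
) -> np.ndarray:
    """Null ES for random same-size gene sets (vectorised over permutations).

    Exploits that the running-sum extremum can only occur at a hit position
    (maximum) or immediately before one (minimum).
    """
    n = len(z)
    w_all = np.abs(z) ** p_weight
    # random hit positions: first `size` entries of a random permutation
    pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :size]
    pos.sort(axis=1)
    w = w_all[pos]
    totals = w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    cum_inc = np.cumsum(w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cum_inc = cum_inc / totals
    if zero.any():
        cum_inc[zero] = (np.arange(1, size + 1) / size)[None, :]
    dec = 1.0 / (n - size)
    idx = np.arange(size)
    # value just after hit i (0-based): cum_inc_i - (pos_i - i) * dec
    after = cum_inc - (pos - idx) * dec
    # value just before hit i: cum_inc_{i-1} - (pos_i - i) * dec
    before = np.concatenate([np.zeros((n_perm, 1)), cum_inc[:, :-1]], axis=1)
    before = before - (pos - idx) * dec
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def gsea_preranked(
    ranking: pd.DataFrame,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 500,
    p_weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    For every set within [min_size, max_size] after intersection with the
    ranked universe: observed ES; a gene-label permutation null of the same
    size; NES = ES / mean(|null ES| of the same sign); p from the same-sign
    null tail; FDR q by the standard NES-based procedure (pooled normalised
    null, ratio of tail fractions, monotonised within each sign class).

    Returns a table indexed by set name with columns
    size, es, nes, p, q, leading_edge.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    universe = set(ranking.index)
    z = ranking["z"].to_numpy()

    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name in collection.sets:
        members = collection.sets[name] & universe
        if not members:
            continue
        if not (min_size <= len(members) <= max_size) or len(members) == len(universe):
            continue
        es, _, leading = enrichment_score(ranking, members, p_weight)
        null = _null_es(z, len(members), n_perm, p_weight, rng)
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        same = null >= 0 if es >= 0 else null < 0
        n_same = int(same.sum())
        if n_same > 0:
            p = (1.0 + np.sum(np.abs(null[same]) >= abs(es))) / (n_same + 1.0)
        else:
            p = 1.0 / (n_perm + 1.0)
        denom = pos_mean if es >= 0 else neg_mean
        nes = es / denom if np.isfinite(denom) and denom > 0 else np.nan
        # normalised null for the pooled FDR reference
        nn = np.where(null >= 0, null / pos_mean, null / neg_mean)
        null_nes_pool.append(nn[np.isfinite(nn)])
        rows.append(
            {"name": name, "size": len(members), "es": es, "nes": nes,
             "p": p, "leading_edge": leading}
        )

    if not rows:
        warnings.warn("no gene set within the size limits; empty result")
        return pd.DataFrame(
            columns=["size", "es", "nes", "p", "q", "leading_edge"]
        )

    res = pd.DataFrame(rows).set_index("name")
    pool = np.concatenate(null_nes_pool)
    obs = res["nes"].to_numpy()
    q = np.full(len(res), np.nan)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            q[i] = 1.0
            continue
        if nes >= 0:
            null_tail = np.mean(pool[pool >= 0] >= nes) if (pool >= 0).any() else 0.0
            obs_tail = np.mean(obs[obs >= 0] >= nes)
        else:
            null_tail = np.mean(pool[pool < 0] <= nes) if (pool < 0).any() else 0.0
            obs_tail = np.mean(obs[obs < 0] <= nes)
        q[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
    res["q"] = q
    return res[["size", "es", "nes", "p", "q", "leading_edge"]].sort_values(
        ["p", "q"], kind="stable"
    )


def prune_redundant(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    jaccard_threshold: float = 0.7,
) -> pd.DataFrame:
    """Greedy redundancy pruning of enrichment results by gene overlap.

    Sets are visited from most to least significant (p, then |NES|); a set
    is dropped when its Jaccard index with an already-kept set exceeds the
    threshold, so each cluster of near-identical terms keeps one
    representative.  threshold 1.0 disables pruning.
    """
    if not 0 <= jaccard_threshold <= 1:
        raise ValueError("jaccard_threshold must be in [0, 1]")
    order = results.assign(_a=-results["nes"].abs()).sort_values(
        ["p", "_a"], kind="stable"
    ).index
    kept: list[str] = []
    for name in order:
        genes = collection.sets[name]
        redundant = False
        for other in kept:
            o = collection.sets[other]
            jac = len(genes & o) / len(genes | o)
            if jac > jaccard_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(name)
    return results.loc[[n for n in results.index if n in set(kept)]]
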