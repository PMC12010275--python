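"""Voxel-based group analysis: GLM t-maps, TFCE, permutation FWE, parcellation.

The group contrast throughout is "patient > control" (group coded 1 vs 0);
the opposite contrast is obtained by negating the subject volumes or the
resulting maps.  TFCE is applied two-sidedly as two one-sided passes with
signs restored, and family-wise error is controlled with the permutation
distribution of the maximum absolute TFCE statistic under Freedman–Lane
residual permutation (covariates stay in the model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelCohort",
    "TFCEParams",
    "StatMap",
    "RegionalPhenotype",
    "DesignError",
    "smooth_gaussian",
    "fit_glm_tmap",
    "tfce_enhance",
    "permutation_fwe",
    "parcellate",
    "voxel_analysis",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class DesignError(ValueError):
    """Raised when the GLM design matrix is rank deficient."""


@dataclass
class VoxelCohort:
    """Stacked subject volumes with group labels and nuisance covariates.

    data: (n_subjects, *grid) phenotype values (arbitrary units).
    group: binary label per subject (1 = patient, 0 = control).
    covariates: (n_subjects, n_cov) numeric matrix (e.g. age, sex 0/1).
    covariate_names: column labels for ``covariates``.
    mask: boolean analysis grid (the gray-matter mask stand-in).
    """

    data: np.ndarray
    group: np.ndarray
    covariates: np.ndarray
    mask: np.ndarray
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.group = np.asarray(self.group)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape[1:] != self.mask.shape:
            raise ValueError("subject volumes and mask shapes differ")
        if not self.mask.any():
            raise ValueError("analysis mask is empty")
        if len(np.unique(self.group)) < 2:
            raise ValueError("group must contain both levels")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape


@dataclass
class TFCEParams:
    """TFCE and permutation-inference settings.

    E, H are the extent and height exponents; the integration step is
    max|t|/n_steps (so the enhancement is invariant to rescaling the input
    up to the discretisation).  connectivity selects the 6/18/26
    neighbourhood.  n_perm defaults to 5000 permutations.
    """

    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100
    connectivity: int = 26
    n_perm: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @property
    def structure(self) -> np.ndarray:
        order = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, order)


@dataclass
class StatMap:
    """A statistic volume (t, TFCE or FWE-corrected p) with its mask."""

    values: np.ndarray
    kind: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.kind not in ("t", "tfce", "p_fwe"):
            raise ValueError(f"unknown map kind {self.kind!r}")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite statistic inside mask")


@dataclass
class RegionalPhenotype:
    """One statistic per atlas region (the parcellated map)."""

    region_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.region_ids = np.asarray(self.region_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.region_ids) != len(self.values):
            raise ValueError("region_ids and values length mismatch")


def smooth_gaussian(
    volume: np.ndarray,
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float = 1.0,
) -> np.ndarray:
    """Mask-renormalised separable Gaussian smoothing.

    The volume is zeroed outside the mask, smoothed, and divided by the
    smoothed mask so that edge voxels are not diluted by out-of-mask zeros.
    sigma = fwhm / (2*sqrt(2*ln 2)) / voxel size.  fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if fwhm_mm == 0:
        out = volume.copy()
        out[~mask] = 0.0
        return out
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    num = ndimage.gaussian_filter(np.where(mask, volume, 0.0), sigma, mode="constant")
    den = ndimage.gaussian_filter(mask.astype(float), sigma, mode="constant")
    out = np.zeros_like(volume)
    np.divide(num, den, out=out, where=den > 0)
    out[~mask] = 0.0
    return out


def _design_matrix(cohort: VoxelCohort) -> np.ndarray:
    X = np.column_stack(
        [np.ones(cohort.n_subjects), cohort.group.astype(float), cohort.covariates]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix (intercept, group, covariates) is rank deficient")
    return X


def _glm_t(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """t statistic of the group column (column 1) per column of Y."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    cvar = np.linalg.inv(X.T @ X)[1, 1]
    se = np.sqrt(sigma2 * cvar)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    return t


def fit_glm_tmap(cohort: VoxelCohort) -> StatMap:
    """Per-voxel OLS t statistic for the group contrast, adjusting covariates.

    The design is [intercept, group, covariates]; the reported statistic is
    the t of the group coefficient (patient minus control).
    """
    X = _design_matrix(cohort)
    flat = cohort.data.reshape(cohort.n_subjects, -1)
    inside = cohort.mask.ravel()
    t = np.zeros(flat.shape[1])
    t[inside] = _glm_t(X, flat[:, inside])
    return StatMap(t.reshape(cohort.shape), "t", cohort.mask)


def _tfce_one_sided(m: np.ndarray, params: TFCEParams, dh: float) -> np.ndarray:
    """Midpoint-rule TFCE integral of a non-negative map at step dh."""
    out = np.zeros_like(m)
    hmax = float(m.max())
    if hmax <= 0 or dh <= 0:
        return out
    struct = params.structure
    n_steps = int(np.ceil(hmax / dh))
    for k in range(n_steps):
        h = (k + 0.5) * dh
        labels, n = ndimage.label(m >= h, structure=struct)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        inc = sizes.astype(float) ** params.E * (h**params.H * dh)
        inc[0] = 0.0
        out += inc[labels]
    return out


def tfce_enhance(stat: StatMap, params: TFCEParams, dh: float | None = None) -> StatMap:
    """Threshold-free cluster enhancement, TFCE(v) = sum_h e_h(v)^E h^H dh.

    e_h(v) is the size of the connected component containing v after
    thresholding at h.  Positive and negative parts are enhanced separately
    and recombined with their signs, so the output is an odd function of the
    input.  By default dh = max|t| / n_steps.
    """
    values = np.where(stat.mask, stat.values, 0.0)
    if dh is None:
        peak = float(np.abs(values).max())
        if peak == 0:
            return StatMap(np.zeros_like(values), "tfce", stat.mask)
        dh = peak / params.n_steps
    if dh <= 0:
        raise ValueError("dh must be positive")
    pos = _tfce_one_sided(np.clip(values, 0, None), params, dh)
    neg = _tfce_one_sided(np.clip(-values, 0, None), params, dh)
    return StatMap(pos - neg, "tfce", stat.mask)


def permutation_fwe(
    cohort: VoxelCohort, params: TFCEParams
) -> tuple[StatMap, StatMap, StatMap]:
    """Permutation FWE inference on the TFCE map (max-statistic method).

    Covariates are residualised out (Freedman–Lane): the reduced model
    [intercept, covariates] is fitted once, its residuals are row-permuted,
    re-added to the reduced fit, and the full-model group t is recomputed for
    each permutation.  The null is the distribution of the maximum |TFCE|
    over the mask; p_fwe(v) = (1 + #{perm max >= |TFCE_obs(v)|}) / (n_perm+1).

    Returns (t map, TFCE map, FWE-corrected p map).
    """
    X = _design_matrix(cohort)
    rng = np.random.default_rng(params.seed)
    flat = cohort.data.reshape(cohort.n_subjects, -1)
    inside = cohort.mask.ravel()
    Y = flat[:, inside]

    t_obs = np.zeros(flat.shape[1])
    t_obs[inside] = _glm_t(X, Y)
    tmap = StatMap(t_obs.reshape(cohort.shape), "t", cohort.mask)
    tfce_obs = tfce_enhance(tmap, params)

    # reduced model: everything but the group column
    Z = np.delete(X, 1, axis=1)
    fitted = Z @ (np.linalg.pinv(Z) @ Y)
    resid = Y - fitted

    shape = cohort.shape
    abs_obs = np.abs(tfce_obs.values)
    max_null = np.empty(params.n_perm)
    t_perm = np.zeros(flat.shape[1])
    for b in range(params.n_perm):
        order = rng.permutation(cohort.n_subjects)
        t_perm[inside] = _glm_t(X, fitted + resid[order])
        tfce_b = tfce_enhance(
            StatMap(t_perm.reshape(shape), "t", cohort.mask), params
        )
        max_null[b] = np.abs(tfce_b.values).max()

    exceed = (max_null[None, :] >= abs_obs.ravel()[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (params.n_perm + 1.0)
    p = p.reshape(shape)
    p[~cohort.mask] = 1.0
    return tmap, tfce_obs, StatMap(p, "p_fwe", cohort.mask)


def parcellate(stat: StatMap, atlas) -> RegionalPhenotype:
    """Mean statistic over the in-mask voxels of each atlas region.

    Background label 0 is ignored.  A region with no in-mask voxels gets a
    missing (NaN) value and a warning.
    """
    if stat.values.shape != atlas.labels.shape:
        raise ValueError("statistic map and atlas shapes differ")
    labels = atlas.labels.ravel()
    ok = stat.mask.ravel() & (labels > 0)
    nmax = int(atlas.region_ids.max())
    sums = np.bincount(labels[ok], weights=stat.values.ravel()[ok], minlength=nmax + 1)
    counts = np.bincount(labels[ok], minlength=nmax + 1)
    values = np.full(len(atlas.region_ids), np.nan)
    for i, rid in enumerate(atlas.region_ids):
        if counts[rid] > 0:
            values[i] = sums[rid] / counts[rid]
    if np.isnan(values).any():
        empty = [int(r) for r, v in zip(atlas.region_ids, values) if np.isnan(v)]
        warnings.warn(f"regions with no in-mask voxels set to missing: {empty}")
    return RegionalPhenotype(np.asarray(atlas.region_ids), values)


def voxel_analysis(
    cohort: VoxelCohort, params: TFCEParams, fwhm_mm: float = 3.0
) -> dict[str, StatMap]:
    """Smoothing + GLM + TFCE + permutation FWE in one call."""
    if fwhm_mm > 0:
        data = np.stack(
            [smooth_gaussian(v, cohort.mask, fwhm_mm) for v in cohort.data]
        )
        cohort = VoxelCohort(
            data, cohort.group, cohort.covariates, cohort.mask, cohort.covariate_names
        )
    tmap, tfce, p = permutation_fwe(cohort, params)
    return {"t": tmap, "tfce": tfce, "p_fwe": p}
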