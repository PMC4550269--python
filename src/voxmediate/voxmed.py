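"""Voxel-wise three-step mediation mapping with cluster-extent correction.

At every grey-matter voxel the causal-steps logic of Baron & Kenny (in the
Wen et al. variant used for imaging data) is applied with the gene score X
as independent variable, the voxel's ReHo value M as mediator, the trait
score Y as outcome, and gender as covariate in every equation:

  step 1 (once):      Y ~ X + gender          -> c,  p_c
  step 2 (per voxel): M ~ X + gender          -> a,  p_a
  step 3 (per voxel): Y ~ M + X + gender      -> b,  p_b

All coefficients are standardized regression weights.  A voxel is declared
significant when all three steps reach p < alpha (default 0.05), giving a
nominal joint voxel-level rate of alpha^3 = 0.000125 under the null; the
mediation (or suppression) effect is the product a*b.

Two cluster-extent calibrations are provided: a Monte-Carlo simulation of
smooth Gaussian fields (the AlphaSim/3dClustSim approach) and a permutation
scheme that rebuilds gene scores from randomly drawn loci and records the
maximal significant cluster per permutation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MediationMap",
    "standardized_ols",
    "mediation_scan",
    "label_clusters",
    "cluster_threshold_mc",
    "cluster_threshold_perm",
    "compact_mask",
]


def _zscore(v: np.ndarray, name: str = "variable") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{name} has zero variance")
    return (v - v.mean()) / sd


def standardized_ols(
    y: np.ndarray,
    x_of_interest: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Standardized OLS coefficient of ``x_of_interest`` and its p-value.

    All variables are z-scored; the model is fit with statsmodels OLS
    including an intercept.  Returns ``(beta_std, p_two_sided)``.
    """
    y = _zscore(y, "y")
    x = _zscore(x_of_interest, "x")
    cols = [x]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] == 1 and covariates.shape[1] == y.shape[0]:
            covariates = covariates.T
        for j in range(covariates.shape[1]):
            cols.append(_zscore(covariates[:, j], f"covariate {j}"))
    design = sm.add_constant(np.column_stack(cols))
    n, p = design.shape
    if n <= p:
        raise ValueError("not enough observations for the design")
    if np.linalg.matrix_rank(design) < p:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(y, design).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


@dataclass
class MediationMap:
    """Per-voxel mediation results on a flat in-mask voxel axis.

    ``a``/``b`` are standardized coefficients of steps 2 and 3, ``ab`` their
    product; ``sig`` marks voxels passing the three-way conjunction at
    ``alpha``.  ``c``/``p_c`` record the single step-1 (total effect) test.
    """

    a: np.ndarray
    p_a: np.ndarray
    b: np.ndarray
    p_b: np.ndarray
    ab: np.ndarray
    sig: np.ndarray
    c: float
    p_c: float
    alpha: float
    n: int

    def to_volume(self, mask: np.ndarray, which: str = "ab") -> np.ndarray:
        """Scatter a per-voxel field back onto the 3-D grid (0 outside mask)."""
        mask = np.asarray(mask, dtype=bool)
        out = np.zeros(mask.shape, dtype=float)
        out[mask] = getattr(self, which)
        return out


def mediation_scan(
    X: np.ndarray,
    Y: np.ndarray,
    gender: np.ndarray,
    reho_stack: np.ndarray,
    alpha: float = 0.05,
) -> MediationMap:
    """Three-step mediation test at every voxel of a subjects x voxels stack.

    Closed-form vectorised OLS: step 2 fits all voxels against the common
    design ``[1, X, gender]``; step 3 uses Frisch-Waugh partialling of
    ``[1, X, gender]`` out of both Y and each voxel's M, which yields the
    exact multiple-regression coefficient of M.  Constant voxels are marked
    non-significant with zero coefficients and logged.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    gender = np.asarray(gender, dtype=float)
    M = np.asarray(reho_stack, dtype=float)
    n = X.shape[0]
    if M.ndim != 2 or M.shape[0] != n or Y.shape[0] != n or gender.shape[0] != n:
        raise ValueError("inputs must share the subject axis")
    V = M.shape[1]
    if n < 6:
        raise ValueError("too few subjects")

    x_z = _zscore(X, "gene score")
    y_z = _zscore(Y, "outcome")
    g_z = _zscore(gender, "gender")

    sd = M.std(axis=0, ddof=1)
    ok = sd > 0
    if not ok.all():
        logger.warning("%d constant voxels marked non-significant", (~ok).sum())
    M_z = np.zeros_like(M)
    M_z[:, ok] = (M[:, ok] - M[:, ok].mean(axis=0)) / sd[ok]

    D = np.column_stack([np.ones(n), x_z, g_z])
    DtD_inv = np.linalg.inv(D.T @ D)
    P = DtD_inv @ D.T  # 3 x n

    # step 1 (global): c from Y ~ X + gender
    beta_c = P @ y_z
    resid_c = y_z - D @ beta_c
    df_c = n - 3
    se_c = np.sqrt(resid_c @ resid_c / df_c * DtD_inv[1, 1])
    c = float(beta_c[1])
    t_c = c / se_c
    p_c = float(2.0 * stats.t.sf(abs(t_c), df_c))

    # step 2 (per voxel): a from M ~ X + gender
    B = P @ M_z  # 3 x V
    a = B[1]
    resid_a = M_z - D @ B
    rss_a = (resid_a**2).sum(axis=0)
    df_a = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        se_a = np.sqrt(rss_a / df_a * DtD_inv[1, 1])
        t_a = np.where(se_a > 0, a / se_a, 0.0)
    p_a = 2.0 * stats.t.sf(np.abs(t_a), df_a)

    # step 3 (per voxel): b from Y ~ M + X + gender via partialling
    y_r = y_z - D @ (P @ y_z)
    M_r = resid_a  # M partialled on the same design
    mm = (M_r**2).sum(axis=0)
    my = M_r.T @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(mm > 0, my / mm, 0.0)
    resid_full = y_r[:, None] - M_r * b[None, :]
    rss_b = (resid_full**2).sum(axis=0)
    df_b = n - 4
    with np.errstate(divide="ignore", invalid="ignore"):
        se_b = np.where(mm > 0, np.sqrt(rss_b / df_b / mm), np.inf)
        t_b = np.where(np.isfinite(se_b) & (se_b > 0), b / se_b, 0.0)
    p_b = 2.0 * stats.t.sf(np.abs(t_b), df_b)

    a = np.where(ok, a, 0.0)
    b = np.where(ok, b, 0.0)
    p_a = np.where(ok, p_a, 1.0)
    p_b = np.where(ok, p_b, 1.0)
    sig = (p_c < alpha) & (p_a < alpha) & (p_b < alpha) & ok
    return MediationMap(
        a=a, p_a=p_a, b=b, p_b=p_b, ab=a * b, sig=sig,
        c=c, p_c=p_c, alpha=alpha, n=n,
    )


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_clusters(
    sig_mask: np.ndarray,
    ab_map: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    connectivity: int = 26,
    voxel_volume_mm3: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Connected components of a significance mask.

    Returns ``(table, labels)`` where the table has one row per cluster with
    size in voxels (and mm^3 when the voxel volume is known), the peak voxel
    (member maximising |ab|, or the first member when no ab map is given),
    its MNI coordinate when an affine is given, and the member voxel list.
    An empty mask yields an empty table.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    sig_mask = np.asarray(sig_mask, dtype=bool)
    labels, n_lab = ndimage.label(sig_mask, structure=_STRUCTS[connectivity])
    rows = []
    for lab in range(1, n_lab + 1):
        members = np.argwhere(labels == lab)
        if ab_map is not None:
            vals = ab_map[tuple(members.T)]
            peak = members[np.argmax(np.abs(vals))]
            peak_ab = float(ab_map[tuple(peak)])
        else:
            peak = members[0]
            peak_ab = np.nan
        row = {
            "cluster_id": lab,
            "size_vox": len(members),
            "peak_i": int(peak[0]),
            "peak_j": int(peak[1]),
            "peak_k": int(peak[2]),
            "peak_ab": peak_ab,
            "members": [tuple(m) for m in members],
        }
        if voxel_volume_mm3 is not None:
            row["size_mm3"] = len(members) * voxel_volume_mm3
        if affine is not None:
            xyz = (np.asarray(affine) @ np.append(peak, 1.0))[:3]
            row["peak_x"], row["peak_y"], row["peak_z"] = map(float, xyz)
        rows.append(row)
    cols = ["cluster_id", "size_vox", "peak_i", "peak_j", "peak_k", "peak_ab",
            "members"]
    if voxel_volume_mm3 is not None:
        cols.append("size_mm3")
    if affine is not None:
        cols += ["peak_x", "peak_y", "peak_z"]
    table = pd.DataFrame(rows, columns=cols)
    if not table.empty:
        table = table.sort_values("size_vox", ascending=False).reset_index(drop=True)
    return table, labels


def compact_mask(mask_size: int, grid: tuple[int, int, int] | None = None) -> np.ndarray:
    """Compact quasi-spherical mask of exactly ``mask_size`` voxels.

    Voxels are taken in order of distance from the grid centre.  Used by the
    Monte-Carlo calibration when the true analysis-mask geometry is not
    available; a compact stand-in slightly overestimates cluster extents
    relative to a convoluted grey-matter sheet.
    """
    if mask_size < 1:
        raise ValueError("mask_size must be >= 1")
    if grid is None:
        r = (3.0 * mask_size / (4.0 * np.pi)) ** (1.0 / 3.0)
        side = int(2 * np.ceil(r) + 6)
        grid = (side, side, side)
    if mask_size > np.prod(grid):
        raise ValueError("mask_size exceeds grid capacity")
    centre = (np.asarray(grid) - 1) / 2.0
    idx = np.indices(grid)
    d2 = sum((idx[ax] - centre[ax]) ** 2 for ax in range(3))
    order = np.argsort(d2, axis=None, kind="stable")[:mask_size]
    mask = np.zeros(grid, dtype=bool)
    mask.ravel()[order] = True
    return mask


def cluster_threshold_mc(
    mask_size: int,
    fwhm: tuple[float, float, float],
    voxel_size: float = 3.0,
    voxel_p: float = 0.000125,
    alpha: float = 0.05,
    n_iter: int = 1000,
    connectivity: int = 26,
    grid: tuple[int, int, int] | None = None,
    seed: int | np.random.Generator | None = None,
    return_distribution: bool = False,
):
    """Cluster-extent threshold by Monte-Carlo simulation of smooth noise.

    Each iteration draws a white Gaussian field on the grid, smooths it to
    the target FWHM (periodic convolution), standardizes it by its
    empirical in-mask mean and SD, thresholds |z| two-sided at ``voxel_p``
    within a compact mask of ``mask_size`` voxels, and records the largest
    suprathreshold cluster.  The returned threshold is the smallest extent
    k with ``P(max cluster >= k) <= alpha`` (capped at ``mask_size``).
    """
    if not (0.0 < voxel_p <= 1.0):
        raise ValueError("voxel_p must be in (0, 1]")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    fwhm = np.broadcast_to(np.asarray(fwhm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ValueError("fwhm must be >= 0")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)

    mask = compact_mask(mask_size, grid)
    grid_dims = mask.shape
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    sigma_vox = fwhm / vs / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    zthr = stats.norm.isf(voxel_p / 2.0) if voxel_p < 1.0 else 0.0
    struct = _STRUCTS[connectivity]

    max_sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        f = rng.standard_normal(grid_dims)
        if np.any(sigma_vox > 0):
            f = ndimage.gaussian_filter(f, sigma_vox, mode="wrap")
        v = f[mask]
        z = (f - v.mean()) / v.std()
        supra = (np.abs(z) >= zthr) & mask
        if supra.any():
            labels, _ = ndimage.label(supra, structure=struct)
            max_sizes[it] = np.bincount(labels.ravel())[1:].max()

    threshold = mask_size
    for k in range(1, int(max_sizes.max()) + 2):
        if np.mean(max_sizes >= k) <= alpha:
            threshold = min(k, mask_size)
            break
    if return_distribution:
        return threshold, max_sizes
    return threshold


def _permutation_weights(
    codes: np.ndarray, Y: np.ndarray, policy: str, weights: np.ndarray | None
) -> np.ndarray:
    if policy == "reestimate":
        design = np.column_stack([np.ones(codes.shape[0]), codes])
        beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
        return beta[1:]
    if policy == "unit":
        return np.ones(codes.shape[1])
    if policy == "reuse":
        if weights is None:
            raise ValueError("policy 'reuse' needs explicit weights")
        return np.asarray(weights, dtype=float)
    raise ValueError(f"unknown weight policy {policy!r}")


def cluster_threshold_perm(
    pool_codes: np.ndarray | pd.DataFrame,
    Y: np.ndarray,
    gender: np.ndarray,
    reho_stack: np.ndarray,
    mask: np.ndarray,
    n_select: int = 10,
    n_perm: int = 1000,
    alpha: float = 0.05,
    alpha_voxel: float = 0.05,
    weight_policy: str = "reestimate",
    weights: np.ndarray | None = None,
    connectivity: int = 26,
    seed: int | np.random.Generator | None = None,
    return_distribution: bool = False,
):
    """Cluster-extent threshold from random-gene-score permutations.

    Each permutation draws ``n_select`` loci without replacement from the
    pool, builds a gene score from them (weights re-estimated by multiple
    regression of Y on the drawn codes by default, mirroring how the real
    score's weights were obtained), reruns the full three-step voxel scan,
    and records the maximal significant cluster (0 when none).  The
    threshold is the ceil(0.95 * (n_perm + 1))-th order statistic of that
    max-size distribution (more generally ``ceil((1 - alpha)(n_perm + 1))``).
    """
    codes_all = np.asarray(pool_codes, dtype=float)
    n, pool = codes_all.shape
    if pool < n_select:
        raise ValueError(f"pool has {pool} loci; need at least {n_select}")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable tail quantile", stacklevel=2)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() != reho_stack.shape[1]:
        raise ValueError("mask voxel count does not match reho_stack columns")
    rng = np.random.default_rng(seed)

    max_sizes = np.zeros(n_perm, dtype=int)
    for it in range(n_perm):
        loci = rng.choice(pool, size=n_select, replace=False)
        codes = codes_all[:, loci]
        w = _permutation_weights(codes, np.asarray(Y, float), weight_policy, weights)
        score = codes @ w
        if score.std(ddof=1) == 0:
            continue  # degenerate draw: no variance, no clusters
        mm = mediation_scan(score, Y, gender, reho_stack, alpha=alpha_voxel)
        if mm.sig.any():
            sig_vol = np.zeros(mask.shape, dtype=bool)
            sig_vol[mask] = mm.sig
            labels, n_lab = ndimage.label(sig_vol, structure=_STRUCTS[connectivity])
            if n_lab:
                max_sizes[it] = np.bincount(labels.ravel())[1:].max()

    order = np.sort(max_sizes)
    rank = int(np.ceil((1.0 - alpha) * (n_perm + 1)))
    if rank < 1:
        threshold = 0
    else:
        threshold = int(order[min(rank, n_perm) - 1])
    if return_distribution:
        return threshold, max_sizes
    return threshold
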