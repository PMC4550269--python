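"""Regional homogeneity (ReHo): Kendall's coefficient of concordance maps.

ReHo measures the temporal coherence of spontaneous activity by computing
Kendall's W across the time-series ranks of a voxel and its 26 nearest
neighbours (the 3x3x3 cube, centre included).  W lies in [0, 1]: 1 for
perfectly concordant rankings, values near 1/K for independent series.

Neighbourhoods are clipped to the analysis mask (and the grid), with the
number of concordant series K adjusted per voxel, matching REST/DPARSF
behaviour rather than requiring complete 27-voxel cubes.  Ties receive
average ranks; by default no tie-correction term enters the denominator
(again the REST convention), with the corrected denominator available as an
option.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "kendalls_w",
    "reho_map",
    "normalize_reho",
    "gaussian_smooth",
    "estimate_fwhm",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _tie_term(series: np.ndarray) -> float:
    """Sum over tie groups of (t^3 - t) for one series."""
    _, counts = np.unique(series, return_counts=True)
    counts = counts[counts > 1]
    return float((counts.astype(float) ** 3 - counts).sum())


def kendalls_w(series: np.ndarray, tie_correction: bool = False) -> float:
    """Kendall's coefficient of concordance over K series of n time points.

    Each series is ranked over time (average ranks for ties); with column
    rank sums ``R_i``, ``W = 12 * sum_i (R_i - mean R)^2 / (K^2 (n^3 - n))``.
    A zero-variance series contributes constant (all-tied) ranks.

    Parameters
    ----------
    series : ndarray, shape (K, n)
    tie_correction : bool
        If True, subtract ``K * sum_j T_j`` from the denominator, where
        ``T_j`` sums ``t^3 - t`` over tie groups of series j.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a (K, n) array")
    K, n = series.shape
    if K < 2:
        raise ValueError("need at least 2 series")
    if n < 2:
        raise ValueError("need at least 2 time points")
    ranks = rankdata(series, axis=-1)
    R = ranks.sum(axis=0)
    S = float(((R - R.mean()) ** 2).sum())
    denom = K**2 * (n**3 - n)
    if tie_correction:
        denom -= K * sum(_tie_term(s) for s in series)
    if denom <= 0:
        return 0.0
    return 12.0 * S / denom


def _ranks_along_time(series2d: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis, with an ordinal fast path.

    Rows without ties get ranks from a double argsort; only tied rows pay
    for full midrank computation.
    """
    order = np.argsort(series2d, axis=-1, kind="stable")
    n = series2d.shape[-1]
    ranks = np.empty(series2d.shape, dtype=float)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(1.0, n + 1.0), series2d.shape), axis=-1
    )
    srt = np.take_along_axis(series2d, order, axis=-1)
    tied_rows = np.flatnonzero((srt[:, 1:] == srt[:, :-1]).any(axis=-1))
    if tied_rows.size:
        ranks[tied_rows] = rankdata(series2d[tied_rows], axis=-1)
    return ranks


def _neighbour_sum(arr: np.ndarray) -> np.ndarray:
    """Separable 3x3x3 box sum over the first three axes, zero outside grid."""
    w = np.array([1.0, 1.0, 1.0])
    out = arr
    for ax in range(3):
        out = ndimage.correlate1d(out, w, axis=ax, mode="constant", cval=0.0)
    return out


def reho_map(
    data: np.ndarray,
    mask: np.ndarray,
    tie_correction: bool = False,
) -> np.ndarray:
    """Voxel-wise Kendall's W over 3x3x3 in-mask neighbourhoods.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, T)
    mask : boolean ndarray, shape (nx, ny, nz)
        Analysis mask; neighbourhoods are intersected with it and K set to
        the in-mask cube count per voxel.
    tie_correction : bool
        Use the tie-corrected denominator (slower; per-voxel tie terms).

    Returns
    -------
    ndarray (nx, ny, nz): W inside the mask, 0 outside.  Voxels whose
    in-mask neighbourhood has fewer than 2 members get 0 and are logged.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data.ndim != 4:
        raise ValueError("data must be 4-D")
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape must match the grid")
    if not mask.any():
        raise ValueError("mask is empty")
    T = data.shape[-1]
    if T < 2:
        raise ValueError("need at least 2 time points")

    ranks = np.zeros(data.shape, dtype=float)
    ranks[mask] = _ranks_along_time(data[mask])

    R = _neighbour_sum(ranks)
    K = np.round(_neighbour_sum(mask.astype(float)))
    Rbar = K * (T + 1) / 2.0
    S = ((R - Rbar[..., None]) ** 2).sum(axis=-1)

    denom = K**2 * (T**3 - T)
    if tie_correction:
        tie = np.zeros(mask.shape)
        tie[mask] = [_tie_term(s) for s in data[mask]]
        denom = denom - K * _neighbour_sum(tie * mask)

    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(denom > 0, 12.0 * S / denom, 0.0)
    W[~mask] = 0.0
    lonely = mask & (K < 2)
    if lonely.any():
        logger.warning("%d in-mask voxels have K < 2 neighbours; set to 0", lonely.sum())
        W[lonely] = 0.0
    return W


def normalize_reho(reho: np.ndarray, mask: np.ndarray, mode: str = "subtract") -> np.ndarray:
    """Demean a ReHo map over the mask.

    ``subtract`` (default) removes the in-mask mean; ``divide`` scales by it
    (the DPARSF "mReHo" convention).  Either is an affine per-subject
    transform, so across-subject correlations are unchanged in subtract
    mode.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    mu = float(reho[mask].mean())
    out = np.zeros_like(np.asarray(reho, dtype=float))
    if mode == "subtract":
        out[mask] = reho[mask] - mu
    elif mode == "divide":
        if mu == 0.0:
            raise ValueError("in-mask mean is zero; cannot divide")
        out[mask] = reho[mask] / mu
    else:
        raise ValueError(f"unknown demean mode {mode!r}")
    return out


def gaussian_smooth(
    img: np.ndarray,
    fwhm: float = 4.0,
    voxel_size: float | tuple[float, float, float] = 3.0,
) -> np.ndarray:
    """Separable Gaussian smoothing with kernel width given as FWHM in mm.

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis, converted to voxels by the
    voxel size.  Smoothing runs over the whole grid (not mask-restricted).
    ``fwhm = 0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return np.asarray(img, dtype=float).copy()
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    sigma_vox = (fwhm / _FWHM_PER_SIGMA) / vs
    return ndimage.gaussian_filter(np.asarray(img, dtype=float), sigma_vox)


def estimate_fwhm(
    maps: list[np.ndarray] | np.ndarray,
    mask: np.ndarray,
    voxel_size: float | tuple[float, float, float] = 3.0,
) -> tuple[float, float, float]:
    """Per-axis spatial smoothness (FWHM, mm) of residual maps.

    Classic AFNI first-difference estimator: along each axis, with
    ``s2_diff`` the variance of differences between in-mask neighbours and
    ``s2`` the in-mask variance,

        FWHM = dx * sqrt(-2 ln 2 / ln(1 - s2_diff / (2 s2)))

    Maps rougher than white noise along an axis report 0 for that axis.
    Estimates are averaged over maps.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if isinstance(maps, np.ndarray) and maps.ndim == 3:
        maps = [maps]
    if len(maps) == 0:
        raise ValueError("need at least one map")
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))

    per_map = []
    for m in maps:
        m = np.asarray(m, dtype=float)
        vals = m[mask]
        m = m - vals.mean()
        s2 = vals.var()
        est = []
        for ax in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(None, -1)
            sl_hi[ax] = slice(1, None)
            pair = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
            if pair.sum() < 2 or s2 <= 0:
                est.append(0.0)
                continue
            d = (m[tuple(sl_hi)] - m[tuple(sl_lo)])[pair]
            s2_diff = d.var()
            arg = 1.0 - s2_diff / (2.0 * s2)
            if arg <= 0.0 or arg >= 1.0:
                est.append(0.0)
            else:
                est.append(float(vs[ax] * np.sqrt(-2.0 * np.log(2.0) / np.log(arg))))
        per_map.append(est)
    fx, fy, fz = np.mean(per_map, axis=0)
    return float(fx), float(fy), float(fz)
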