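"""Temporal preprocessing of 4-D resting-state volumes and head-motion summaries.

The temporal chain, applied in fixed order after spatial preprocessing has
produced normalised volumes, is: discard initial frames -> linear detrend ->
band-pass filter (0.01-0.08 Hz, ideal rectangular DFT filter) -> nuisance
regression (six rigid-body motion parameters, global mean, white-matter and
CSF mean signals).  Nuisance regression follows filtering, matching the
published order of operations.

Motion traces follow the SPM ``rp_*.txt`` convention: per frame, three
translations in mm and three rotations in radians, relative to the
reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "Bold4D",
    "discard_initial",
    "detrend_linear",
    "bandpass_filter",
    "regress_nuisance",
    "motion_summary",
    "framewise_displacement",
    "max_motion_check",
    "temporal_pipeline",
]

DEG2RAD = np.pi / 180.0


@dataclass
class Bold4D:
    """A 4-D BOLD time series on a regular voxel grid.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz, T)
    affine : ndarray, shape (4, 4)
        Voxel-index -> MNI mm transform.
    tr : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got shape {self.data.shape}")
        if self.data.shape[-1] < 2:
            raise ValueError("need at least 2 time points")
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in volume")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)


def discard_initial(vol: Bold4D, n_discard: int, motion: np.ndarray | None = None):
    """Drop the first ``n_discard`` frames from volume (and motion trace).

    Returns the trimmed ``Bold4D`` or, if a motion trace is given, a
    ``(Bold4D, motion)`` pair trimmed consistently.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if vol.n_timepoints <= n_discard:
        raise ValueError(
            f"cannot discard {n_discard} of {vol.n_timepoints} frames"
        )
    out = replace(vol, data=vol.data[..., n_discard:].copy())
    if motion is None:
        return out
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != vol.n_timepoints:
        raise ValueError("motion trace length does not match volume")
    return out, motion[n_discard:].copy()


def detrend_linear(vol: Bold4D) -> Bold4D:
    """Remove the per-voxel least-squares line (intercept + slope vs frame)."""
    if vol.n_timepoints < 3:
        raise ValueError("need at least 3 time points to detrend")
    data = sp_signal.detrend(vol.data, axis=-1, type="linear")
    return replace(vol, data=data)


def bandpass_filter(vol: Bold4D, low: float = 0.01, high: float = 0.08) -> Bold4D:
    """Ideal rectangular frequency-domain band-pass filter.

    Discrete-Fourier components with frequency in ``[low, high]`` (inclusive
    edges) are retained, all others — including DC — are zeroed.  This is the
    REST/DPARSF filter, not a Butterworth design.
    """
    nyq = vol.nyquist()
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) must satisfy 0 < low < high < Nyquist={nyq}"
        )
    T = vol.n_timepoints
    freqs = np.fft.rfftfreq(T, d=vol.tr)
    keep = (freqs >= low) & (freqs <= high)
    spec = np.fft.rfft(vol.data, axis=-1)
    spec[..., ~keep] = 0.0
    return replace(vol, data=np.fft.irfft(spec, n=T, axis=-1))


def _mask_mean_series(data: np.ndarray, mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError(f"{name} mask shape {mask.shape} != grid {data.shape[:3]}")
    if not mask.any():
        raise ValueError(f"{name} mask is empty")
    return data[mask].mean(axis=0)


def regress_nuisance(
    vol: Bold4D,
    motion: np.ndarray,
    global_mask: np.ndarray,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
) -> Bold4D:
    """Regress out nuisance signals per voxel, returning OLS residuals.

    The design matrix holds an intercept, the six motion parameters, and the
    mean time series within the global, white-matter and CSF masks.
    Residuals are orthogonal to every regressor.
    """
    motion = np.asarray(motion, dtype=float)
    T = vol.n_timepoints
    if motion.shape != (T, 6):
        raise ValueError(f"motion must be (T, 6) = ({T}, 6), got {motion.shape}")
    cols = [np.ones(T)]
    names = ["intercept"]
    for i in range(6):
        cols.append(motion[:, i])
        names.append(f"motion{i + 1}")
    for mask, nm in ((global_mask, "global"), (wm_mask, "wm"), (csf_mask, "csf")):
        cols.append(_mask_mean_series(vol.data, mask, nm))
        names.append(nm)
    design = np.column_stack(cols)

    if np.linalg.matrix_rank(design) < design.shape[1]:
        # identify offending columns by rank increments
        bad = []
        kept = design[:, :1]
        for j in range(1, design.shape[1]):
            cand = np.column_stack([kept, design[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(names[j])
            else:
                kept = cand
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")

    flat = vol.data.reshape(-1, T).T  # T x V
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    return replace(vol, data=resid.T.reshape(vol.data.shape))


def motion_summary(motion: np.ndarray) -> dict:
    """Per-frame Euclidean norms of translation and rotation, aggregated.

    ``trans_index``/``rot_index`` are the means over frames of
    ``sqrt(dx^2+dy^2+dz^2)`` and ``sqrt(rx^2+ry^2+rz^2)``; the maxima are
    reported alongside because the aggregation of this index is not uniquely
    fixed in the literature.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise ValueError("motion must be (T>=2, 6)")
    trans = np.sqrt((motion[:, :3] ** 2).sum(axis=1))
    rot = np.sqrt((motion[:, 3:] ** 2).sum(axis=1))
    return {
        "trans_index": float(trans.mean()),
        "rot_index": float(rot.mean()),
        "trans_max": float(trans.max()),
        "rot_max": float(rot.max()),
    }


def framewise_displacement(motion: np.ndarray, radius: float = 50.0):
    """Framewise displacement (Power): sum of absolute backward differences.

    ``FD_t = |d dx| + |d dy| + |d dz| + radius * (|d rx| + |d ry| + |d rz|)``
    with rotations converted to arc length on a sphere of ``radius`` mm;
    ``FD_1 = 0``.

    Returns ``(fd, mean_fd)``.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise ValueError("motion must be (T>=2, 6)")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + radius * d[:, 3:].sum(axis=1)
    return fd, float(fd.mean())


def max_motion_check(
    motion: np.ndarray,
    max_trans_mm: float = 2.0,
    max_rot_deg: float = 2.0,
) -> bool:
    """Pass/fail inclusion check on peak head motion.

    Fails if any per-axis displacement exceeds ``max_trans_mm`` or any
    rotation exceeds ``max_rot_deg`` (converted to radians) at any frame.
    Returns True when the trace passes.
    """
    motion = np.asarray(motion, dtype=float)
    max_rot_rad = max_rot_deg * DEG2RAD
    trans_ok = np.all(np.abs(motion[:, :3]) <= max_trans_mm)
    rot_ok = np.all(np.abs(motion[:, 3:]) <= max_rot_rad)
    return bool(trans_ok and rot_ok)


def temporal_pipeline(
    vol: Bold4D,
    motion: np.ndarray,
    global_mask: np.ndarray,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    n_discard: int = 10,
    low: float = 0.01,
    high: float = 0.08,
) -> Bold4D:
    """Full temporal chain in the fixed published order.

    discard -> detrend -> band-pass -> nuisance regression.
    """
    vol, motion = discard_initial(vol, n_discard, motion)
    vol = detrend_linear(vol)
    vol = bandpass_filter(vol, low=low, high=high)
    return regress_nuisance(vol, motion, global_mask, wm_mask, csf_mask)
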