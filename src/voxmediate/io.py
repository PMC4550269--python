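"""Readers and writers: NIfTI-1 volumes, TSV tables, motion text files.

All tabular I/O is tab-separated with a header row and ``NA`` as the
missing-value token.  Motion files are whitespace-delimited T x 6 text in
the SPM ``rp_*.txt`` convention (translations mm, rotations radians; a flag
converts from degrees).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import DEG2RAD, Bold4D

__all__ = [
    "read_volume",
    "write_volume",
    "read_map",
    "write_map",
    "read_mask",
    "read_motion",
    "write_motion",
    "read_table",
    "write_table",
]


def read_volume(path, tr: float | None = None) -> Bold4D:
    """Load a 4-D NIfTI volume.

    The repetition time is taken from the header (``pixdim[4]``) unless a
    positive ``tr`` override is given; a header TR of 0 without an override
    is an error.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - rewrap with the path
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got shape {data.shape}")
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if tr <= 0:
            raise ValueError(f"{path}: TR absent from header and not configured")
    return Bold4D(data=data, affine=np.asarray(img.affine), tr=float(tr))


def write_volume(vol: Bold4D, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header["pixdim"][4] = vol.tr
    nib.save(img, str(path))


def read_map(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3-D map; returns ``(data, affine)``."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D map, got shape {data.shape}")
    return data, np.asarray(img.affine)


def write_map(data: np.ndarray, affine: np.ndarray, path, description: str = "") -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    """Binary mask from NIfTI: nonzero means in-mask."""
    data, _ = read_map(path)
    return data != 0


def read_motion(path, degrees: bool = False) -> np.ndarray:
    """Whitespace-delimited T x 6 motion trace; optionally convert rotations
    from degrees to radians."""
    trace = np.loadtxt(str(path), dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(f"{path}: expected T x 6 motion parameters")
    if degrees:
        trace = trace.copy()
        trace[:, 3:] *= DEG2RAD
    return trace


def write_motion(trace: np.ndarray, path) -> None:
    np.savetxt(str(path), np.asarray(trace, dtype=float), fmt="%.8f")


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", index_col=index_col, na_values=["NA"])


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(str(path), sep="\t", index=index, na_rep="NA")
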