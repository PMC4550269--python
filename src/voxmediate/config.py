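"""Run configuration: file paths, numeric settings, mode switches.

Configurations live in YAML key-value files and round-trip losslessly.
Numeric defaults mirror the analysis conditions: alpha 0.05 per mediation
step (joint voxel threshold 0.05^3 = 0.000125), band 0.01-0.08 Hz, 4 mm
smoothing, 10 discarded frames, 1000 permutations, 5000 bootstrap
resamples, 26-connectivity clusters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # input paths
    genotypes: str = ""
    pool_genotypes: str = ""
    weights: str = ""
    phenotypes: str = ""
    manifest: str = ""          # TSV: subject_id, volume, motion
    grey_mask: str = ""
    global_mask: str = ""
    wm_mask: str = ""
    csf_mask: str = ""

    # numeric settings
    alpha: float = 0.05
    n_discard: int = 10
    band_low: float = 0.01
    band_high: float = 0.08
    fwhm_smooth: float = 4.0
    tr_override: float | None = None
    n_mc_iter: int = 1000
    n_perm: int = 1000
    n_boot: int = 5000
    connectivity: int = 26
    seed: int = 0

    # mode switches
    demean_mode: str = "subtract"          # or "divide"
    perm_weight_policy: str = "reestimate"  # or "unit" / "reuse"
    tie_correction: bool = False
    motion_degrees: bool = False
    ci_method: str = "percentile"

    @property
    def voxel_p(self) -> float:
        """Joint voxel-level threshold: alpha per step over three steps."""
        return self.alpha**3

    def validate(self, require_paths: bool = True) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.band_low < self.band_high):
            raise ValueError("invalid band-pass band")
        if self.fwhm_smooth < 0:
            raise ValueError("fwhm_smooth must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.demean_mode not in ("subtract", "divide"):
            raise ValueError("demean_mode must be 'subtract' or 'divide'")
        if self.perm_weight_policy not in ("reestimate", "unit", "reuse"):
            raise ValueError("unknown permutation weight policy")
        if self.n_discard < 0 or self.n_mc_iter < 1 or self.n_boot < 0:
            raise ValueError("counts must be non-negative (n_mc_iter >= 1)")
        if require_paths:
            for name in (
                "genotypes", "pool_genotypes", "weights", "phenotypes",
                "manifest", "grey_mask", "global_mask", "wm_mask", "csf_mask",
            ):
                p = getattr(self, name)
                if not p or not Path(p).exists():
                    raise FileNotFoundError(f"config path {name!r} missing: {p!r}")

    # YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
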