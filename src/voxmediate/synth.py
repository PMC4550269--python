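"""Synthetic cohorts with the gene -> brain -> trait suppression structure.

The generator emulates the statistical structure the analysis assumes, so
the whole pipeline is testable without any subject data:

* genotypes at Hardy-Weinberg equilibrium for 10 scored loci plus a
  98-locus pool for the permutation correction;
* a latent structural model on standardized variables,
  ``M = a*X + gamma*g + noise`` and ``Y* = c'*X + b*M + gamma*g + noise``,
  whose default coefficients are the suppression pattern reported for the
  dopamine-score / precuneus-ReHo / sensory-processing-sensitivity system
  (a = -0.176, b = +0.139, c' ~ 0.40): the indirect and direct effects have
  opposite signs, so the mediator suppresses the total effect;
* 4-D BOLD volumes in which the temporal coherence of a planted voxel
  cluster increases monotonically with the subject's latent mediator, via a
  shared band-limited (0.01-0.08 Hz) signal mixed at weight
  ``lambda = logistic(k * M)``;
* random-walk six-parameter head-motion traces.

Residual SDs default to the values that give the latent variables unit
population variance, so the generating coefficients are recovered directly
as standardized regression weights.  The trait score is rescaled to the
27-189 questionnaire range with mean 122.4 and SD 15.77.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .genescore import compute_gene_score
from .preprocess import Bold4D

__all__ = [
    "SyntheticConfig",
    "gen_genotypes",
    "gen_genotype_pool",
    "gen_subjects",
    "gen_bold",
    "gen_motion",
    "cluster_mask",
    "default_affine",
]

# real rs numbers of the ten scored dopamine-system loci (TH, DBH, SLC6A3,
# DRD2, NLN, NTSR1, NTSR2); the synthetic MAFs and weights attached to them
# are generator choices, not published values
DEFAULT_LOCI = (
    "rs3842748", "rs4929966", "rs1611123", "rs2975292", "rs7131056",
    "rs2561196", "rs895379", "rs16894446", "rs6062460", "rs12612207",
)
DEFAULT_MAFS = (0.18, 0.33, 0.45, 0.25, 0.40, 0.10, 0.22, 0.37, 0.48, 0.29)
DEFAULT_WEIGHTS = (3.1, -2.4, 2.0, 2.7, -1.8, 2.2, -1.5, 1.9, 1.6, -1.2)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the cohort/model conditions above."""

    n_subjects: int = 298
    mafs: tuple = DEFAULT_MAFS
    weights: tuple = DEFAULT_WEIGHTS
    locus_ids: tuple = DEFAULT_LOCI
    pool_size: int = 98
    pool_maf_range: tuple = (0.05, 0.5)
    path_a: float = -0.176
    path_b: float = 0.139
    path_c_prime: float = 0.399
    gender_effect: float = -0.205
    male_fraction: float = 0.32
    noise_sd_m: float | None = None
    noise_sd_y: float | None = None
    sps_mean: float = 122.4
    sps_sd: float = 15.77
    sps_range: tuple = (27.0, 189.0)
    grid_dims: tuple = (20, 20, 20)
    voxel_size: float = 3.0
    n_timepoints: int = 240
    tr: float = 2.0
    cluster_voxels: np.ndarray | None = None
    coupling_k: float = 1.0
    bold_baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        mafs = np.asarray(self.mafs, dtype=float)
        if np.any(mafs <= 0) or np.any(mafs > 0.5):
            raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
        if len(self.weights) != len(self.mafs) != len(self.locus_ids):
            raise ValueError("mafs, weights and locus_ids must align")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_timepoints < 20:
            raise ValueError("need at least 20 time points")
        if self.noise_sd_m is not None and self.noise_sd_m <= 0:
            raise ValueError("noise_sd_m must be > 0")
        if self.noise_sd_y is not None and self.noise_sd_y <= 0:
            raise ValueError("noise_sd_y must be > 0")
        if self.cluster_voxels is None:
            c = np.asarray(self.grid_dims) // 2
            offs = np.stack(
                np.meshgrid(*[np.arange(-1, 2)] * 3, indexing="ij"), axis=-1
            ).reshape(-1, 3)
            self.cluster_voxels = c[None, :] + offs
        self.cluster_voxels = np.asarray(self.cluster_voxels, dtype=int)
        dims = np.asarray(self.grid_dims)
        if np.any(self.cluster_voxels < 0) or np.any(self.cluster_voxels >= dims):
            raise ValueError("cluster voxels fall outside the grid")

    # residual SDs giving unit-variance latents -------------------------------
    @property
    def _sigma_g2(self) -> float:
        p = self.male_fraction
        return p * (1.0 - p)

    def resolved_noise_sd_m(self) -> float:
        if self.noise_sd_m is not None:
            return self.noise_sd_m
        var = 1.0 - self.path_a**2 - self.gender_effect**2 * self._sigma_g2
        if var <= 0:
            raise ValueError("path coefficients leave no residual variance for M")
        return float(np.sqrt(var))

    def resolved_noise_sd_y(self) -> float:
        if self.noise_sd_y is not None:
            return self.noise_sd_y
        a, b, cp, g = self.path_a, self.path_b, self.path_c_prime, self.gender_effect
        var = (
            1.0
            - cp**2
            - b**2
            - 2.0 * a * b * cp
            - g**2 * self._sigma_g2 * (1.0 + 2.0 * b)
        )
        if var <= 0:
            raise ValueError("path coefficients leave no residual variance for Y")
        return float(np.sqrt(var))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_codes(n: int, mafs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """HWE genotype codes: two independent Bernoulli(maf) alleles per locus."""
    alleles = rng.random((2, n, len(mafs))) < mafs[None, None, :]
    return 1 + alleles.sum(axis=0)


def gen_genotypes(config: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Scored-locus genotype codes (subjects x 10), HWE at the config MAFs."""
    rng = _as_rng(config.seed if rng is None else rng)
    mafs = np.asarray(config.mafs, dtype=float)
    codes = _draw_codes(config.n_subjects, mafs, rng)
    index = [f"sub{i + 1:04d}" for i in range(config.n_subjects)]
    return pd.DataFrame(codes, index=index, columns=list(config.locus_ids))


def gen_genotype_pool(config: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Pool genotypes (subjects x pool_size) for the permutation correction.

    Pool MAFs are drawn uniformly from ``config.pool_maf_range``.
    """
    rng = _as_rng(config.seed + 1 if rng is None else rng)
    lo, hi = config.pool_maf_range
    mafs = rng.uniform(lo, hi, size=config.pool_size)
    codes = _draw_codes(config.n_subjects, mafs, rng)
    index = [f"sub{i + 1:04d}" for i in range(config.n_subjects)]
    cols = [f"pool{j + 1:03d}" for j in range(config.pool_size)]
    return pd.DataFrame(codes, index=index, columns=cols)


def gen_subjects(
    config: SyntheticConfig,
    genotypes: pd.DataFrame,
    rng=None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Subject table (gender, gene score, trait score) plus the latent mediator.

    The gene score is computed from the genotype codes with the config
    weights, standardized to X; the latent cluster-ReHo mediator M and the
    standardized outcome follow the structural equations in the module
    docstring.  The trait score is an affine rescaling of the standardized
    outcome to the questionnaire scale, clipped to its admissible range.
    """
    rng = _as_rng(config.seed + 2 if rng is None else rng)
    weights = pd.Series(config.weights, index=list(config.locus_ids), dtype=float)
    score = compute_gene_score(genotypes, weights)
    if score.std(ddof=1) == 0:
        raise ValueError("gene score is constant; cannot standardize")
    x = (score - score.mean()) / score.std(ddof=1)
    n = config.n_subjects
    if len(x) != n:
        raise ValueError("genotype table does not match n_subjects")

    g = (rng.random(n) < config.male_fraction).astype(float)
    sd_m = config.resolved_noise_sd_m()
    sd_y = config.resolved_noise_sd_y()
    m = config.path_a * x.to_numpy() + config.gender_effect * g
    m = m + rng.normal(0.0, sd_m, size=n)
    y_star = (
        config.path_c_prime * x.to_numpy()
        + config.path_b * m
        + config.gender_effect * g
        + rng.normal(0.0, sd_y, size=n)
    )
    sps = config.sps_mean + config.sps_sd * y_star
    sps = np.clip(sps, *config.sps_range)

    table = pd.DataFrame(
        {
            "subject_id": genotypes.index,
            "gender": g.astype(int),
            "gene_score": score.to_numpy(),
            "sps": sps,
        }
    ).set_index("subject_id")
    return table, m


def cluster_mask(config: SyntheticConfig) -> np.ndarray:
    """Boolean grid marking the planted coherent cluster."""
    mask = np.zeros(config.grid_dims, dtype=bool)
    mask[tuple(config.cluster_voxels.T)] = True
    return mask


def default_affine(config: SyntheticConfig) -> np.ndarray:
    """Grid-centred affine with isotropic voxels of ``config.voxel_size`` mm."""
    vs = float(config.voxel_size)
    aff = np.diag([vs, vs, vs, 1.0])
    aff[:3, 3] = -vs * (np.asarray(config.grid_dims) - 1) / 2.0
    return aff


def _bandlimited_signal(T: int, tr: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance series with spectrum restricted to 0.01-0.08 Hz."""
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= 0.01) & (freqs <= 0.08)
    if not keep.any():
        raise ValueError("run too short: no DFT bin inside the 0.01-0.08 Hz band")
    spec = np.fft.rfft(rng.standard_normal(T))
    spec[~keep] = 0.0
    s = np.fft.irfft(spec, n=T)
    sd = s.std()
    if sd == 0:
        raise ValueError("degenerate band-limited signal")
    return s / sd


def gen_bold(config: SyntheticConfig, m_value: float, rng=None) -> Bold4D:
    """One subject's 4-D volume with cluster coherence coupled to the mediator.

    In-cluster voxels mix a shared band-limited signal and voxel-private
    white noise at weight ``lambda = logistic(coupling_k * M)``; lambda is
    monotone increasing in M and stays in (0, 1).  Out-of-cluster voxels
    are pure white noise.
    """
    rng = _as_rng(rng if rng is not None else config.seed + 3)
    T = config.n_timepoints
    data = rng.standard_normal(config.grid_dims + (T,))
    shared = _bandlimited_signal(T, config.tr, rng)
    lam = float(expit(config.coupling_k * m_value))
    idx = tuple(config.cluster_voxels.T)
    private = rng.standard_normal((config.cluster_voxels.shape[0], T))
    data[idx] = lam * shared[None, :] + (1.0 - lam) * private
    data += config.bold_baseline
    return Bold4D(data=data, affine=default_affine(config), tr=config.tr)


def gen_motion(
    n_timepoints: int,
    step_sd_trans: float = 0.02,
    step_sd_rot: float = 4e-4,
    rng=None,
) -> np.ndarray:
    """Random-walk six-parameter motion trace (T x 6).

    Columns 1-3 are translations in mm, 4-6 rotations in radians; the first
    frame is the zero reference.  Expected per-frame displacement scales
    linearly with the step SD.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    rng = _as_rng(rng)
    steps = np.column_stack(
        [
            rng.normal(0.0, step_sd_trans, size=(n_timepoints - 1, 3)),
            rng.normal(0.0, step_sd_rot, size=(n_timepoints - 1, 3)),
        ]
    )
    trace = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    return trace
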