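"""Synthetic reference datasets.

The ROI-level analysis of the original cohort is fully determined by a
per-subject table of gender, gene score, ROI-mean ReHo and trait score.
That table is not redistributable here, so this module constructs a
*synthetic* stand-in with the published summary structure planted exactly
in the sample: the construction orthogonalises random vectors so that the
sample standardized path coefficients equal the published point estimates
to machine precision, rather than merely in expectation.

Quantities that are functions of the planted coefficients (total effect,
suppression ratio, trait mean/SD, gender group means) are therefore exact;
derived quantities that additionally depend on unpublished features of the
real data (outcome R^2 with the gender path included, leave-one-out r)
land close to, but not exactly at, the published values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["synthetic_s1_table"]

# published ROI-level summary structure of the n=298 cohort
N_SUBJECTS = 298
N_MALE = 96
PATH_A = -0.176
PATH_B = 0.139
SUPPRESSION_PCT = -6.53          # 100 * ab / c
SPS_MEAN = 122.40
SPS_SD = 15.77
SPS_MEAN_MALE = 120.25
SPS_MEAN_FEMALE = 123.49


def _unit_columns(n: int, k: int, anchor: np.ndarray, rng: np.random.Generator):
    """k random columns orthogonal to [1, anchor] and orthonormal, scaled to
    zero mean and unit sample variance (ddof=1)."""
    base = np.column_stack([np.ones(n), anchor, rng.standard_normal((n, k))])
    q, _ = np.linalg.qr(base)
    cols = q[:, 2 : 2 + k] * np.sqrt(n - 1)
    return [cols[:, j] for j in range(k)]


def synthetic_s1_table(seed: int = 20150826) -> pd.DataFrame:
    """Synthetic stand-in for the per-subject ROI-analysis table.

    Returns a DataFrame with columns ``gender`` (1 = male, 96 of 298),
    ``gene_score`` (standardized), ``roi_reho`` (demeaned ReHo scale) and
    ``sps``, built so that the standardized three-equation path model fit
    on it reproduces the published coefficients exactly:

    * a = -0.176, b = 0.139, with c' chosen so the suppression ratio
      100*ab/c equals -6.53% (c' = 0.3991);
    * trait mean 122.40 and SD 15.77 exactly (continuous scores);
    * a male-female difference matching the published group means.

    The construction is deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = N_SUBJECTS

    g = np.zeros(n)
    g[rng.permutation(n)[:N_MALE]] = 1.0
    sd_g = g.std(ddof=1)
    g_u = (g - g.mean()) / sd_g

    x_u, em_u, ey_u = _unit_columns(n, 3, g_u, rng)

    a, b = PATH_A, PATH_B
    ab = a * b
    c = ab / (SUPPRESSION_PCT / 100.0)
    c_prime = c - ab

    # standardized gender path on the trait, from the published group means
    diff_std = (SPS_MEAN_MALE - SPS_MEAN_FEMALE) / SPS_SD
    gamma_y = diff_std * sd_g
    gamma_m = 0.0

    s_m = np.sqrt(1.0 - a**2 - gamma_m**2)
    m = a * x_u + gamma_m * g_u + s_m * em_u

    var_struct = (
        c_prime**2
        + b**2
        + 2.0 * a * b * c_prime
        + gamma_y**2
        + 2.0 * b * gamma_y * gamma_m
    )
    s_y = np.sqrt(1.0 - var_struct)
    y_std = c_prime * x_u + b * m + gamma_y * g_u + s_y * ey_u
    y_std = (y_std - y_std.mean()) / y_std.std(ddof=1)

    return pd.DataFrame(
        {
            "subject_id": [f"sub{i + 1:04d}" for i in range(n)],
            "gender": g.astype(int),
            "gene_score": x_u,
            "roi_reho": 0.05 * m,
            "sps": SPS_MEAN + SPS_SD * y_std,
        }
    ).set_index("subject_id")
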