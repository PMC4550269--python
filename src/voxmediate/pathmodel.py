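"""ROI-level path (mediation/suppression) model with bootstrap and LOO.

The model is the standard three-equation mediation system on standardized
variables, with gender as covariate throughout:

    M ~ X + gender            -> a        (gene score -> ROI ReHo)
    Y ~ X + M + gender        -> c', b    (direct effect; ReHo -> trait)
    Y ~ X + gender            -> c        (total effect)

The indirect effect is ab = a*b, and c = c' + ab holds exactly for OLS on a
common covariate set.  When ab and c' have opposite signs the mediator is a
*suppressor*: adding it strengthens the X->Y association instead of
explaining it.  The suppression is quantified as 100*ab/c percent of the
total effect.

Confidence intervals come from nonparametric case resampling of subjects
(percentile by default, bias-corrected optionally).  Out-of-sample validity
is checked by leave-one-out prediction from the unstandardized outcome
equation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "PathMediationModel",
    "fit_path_model",
    "bootstrap_paths",
    "loo_validate",
    "classify_effect",
    "describe_phenotype",
    "extract_roi_mean",
]


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{name} has zero variance")
    return (v - v.mean()) / sd


def _ols(design: np.ndarray, y: np.ndarray):
    """Coefficients, two-sided p-values, and R^2 for one OLS fit."""
    n, p = design.shape
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    df = n - p
    cov = np.linalg.inv(design.T @ design) * (rss / df)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return beta, pvals, r2


class PathMediationModel(BaseEstimator):
    """Three-equation mediation/suppression path model.

    Parameters
    ----------
    n_boot : int
        Bootstrap resamples for confidence intervals (0 disables).
    ci_level : float
        Nominal coverage of the intervals.
    ci_method : {"percentile", "bc"}
        Percentile or bias-corrected percentile intervals.
    alpha : float
        Significance level used by :func:`classify_effect`.
    random_state : int or Generator, optional
        Seed for the bootstrap; fixed seed gives identical intervals.

    Attributes (after ``fit``)
    --------------------------
    a_, b_, c_, c_prime_ : standardized path coefficients
    gender_m_, gender_y_ : standardized gender paths of the two equations
    p_a_, p_b_, p_c_, p_c_prime_ : two-sided p-values
    ab_ : indirect effect a*b
    suppression_pct_ : 100 * ab / c
    r2_y_ : R^2 of the full outcome equation
    ci_ : dict of (lower, upper) per path and for ``ab``
    boot_ : dict of bootstrap replicate arrays (when ``n_boot > 0``)
    n_ : number of subjects
    """

    def __init__(
        self,
        n_boot: int = 5000,
        ci_level: float = 0.95,
        ci_method: str = "percentile",
        alpha: float = 0.05,
        random_state=None,
    ):
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.ci_method = ci_method
        self.alpha = alpha
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, M, Y, gender):
        X = np.asarray(X, dtype=float)
        M = np.asarray(M, dtype=float)
        Y = np.asarray(Y, dtype=float)
        gender = np.asarray(gender, dtype=float)
        n = X.shape[0]
        if not (M.shape[0] == Y.shape[0] == gender.shape[0] == n):
            raise ValueError("X, M, Y, gender must have equal length")
        if n < 10:
            raise ValueError("need at least 10 subjects")
        if np.isnan(np.concatenate([X, M, Y, gender])).any():
            raise ValueError("missing values are not supported")

        x_z = _zscore(X, "X")
        m_z = _zscore(M, "M")
        y_z = _zscore(Y, "Y")
        g_z = _zscore(gender, "gender")
        ones = np.ones(n)

        D_xg = np.column_stack([ones, x_z, g_z])
        D_full = np.column_stack([ones, x_z, m_z, g_z])

        beta_m, p_m, _ = _ols(D_xg, m_z)
        self.a_, self.gender_m_ = float(beta_m[1]), float(beta_m[2])
        self.p_a_ = float(p_m[1])

        beta_y, p_y, r2 = _ols(D_full, y_z)
        self.c_prime_, self.b_, self.gender_y_ = map(float, beta_y[1:4])
        self.p_c_prime_, self.p_b_ = float(p_y[1]), float(p_y[2])
        self.r2_y_ = float(r2)

        beta_c, p_c, _ = _ols(D_xg, y_z)
        self.c_ = float(beta_c[1])
        self.p_c_ = float(p_c[1])

        self.ab_ = self.a_ * self.b_
        self.suppression_pct_ = (
            100.0 * self.ab_ / self.c_ if self.c_ != 0 else np.nan
        )
        self.n_ = n

        # unstandardized outcome equation, for prediction
        A = np.column_stack([ones, X, M, gender])
        self.outcome_coef_, *_ = np.linalg.lstsq(A, Y, rcond=None)

        if self.n_boot > 0:
            self._bootstrap(X, M, Y, gender)
        else:
            self.ci_ = {}
            self.boot_ = {}
        return self

    # ------------------------------------------------------------------
    def _bootstrap(self, X, M, Y, gender):
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        B = self.n_boot
        data = np.column_stack([X, M, Y, gender])

        idx = rng.integers(0, n, size=(B, n))
        n_redraw = 0
        for _ in range(100):
            res = data[idx]  # B x n x 4
            sds = res.std(axis=1, ddof=1)
            bad = (sds == 0).any(axis=1)
            if not bad.any():
                break
            n_redraw += int(bad.sum())
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
        else:
            raise RuntimeError("could not draw non-degenerate bootstrap samples")
        if n_redraw > 0.01 * B:
            warnings.warn(
                f"{n_redraw} degenerate bootstrap draws redrawn (> 1%)",
                stacklevel=2,
            )

        zb = (res - res.mean(axis=1, keepdims=True)) / sds[:, None, :]
        xb, mb, yb, gb = (zb[..., j] for j in range(4))
        ones = np.ones_like(xb)

        def batch_solve(cols, target):
            D = np.stack(cols, axis=-1)  # B x n x p
            DtD = np.einsum("bni,bnj->bij", D, D)
            Dty = np.einsum("bni,bn->bi", D, target)
            return np.linalg.solve(DtD, Dty[..., None])[..., 0]

        beta_m = batch_solve([ones, xb, gb], mb)
        a_b = beta_m[:, 1]
        beta_y = batch_solve([ones, xb, mb, gb], yb)
        cprime_b, b_b, gy_b = beta_y[:, 1], beta_y[:, 2], beta_y[:, 3]
        beta_c = batch_solve([ones, xb, gb], yb)
        c_b = beta_c[:, 1]

        self.boot_ = {
            "a": a_b,
            "b": b_b,
            "c": c_b,
            "c_prime": cprime_b,
            "gender_y": gy_b,
            "ab": a_b * b_b,
        }
        point = {
            "a": self.a_,
            "b": self.b_,
            "c": self.c_,
            "c_prime": self.c_prime_,
            "gender_y": self.gender_y_,
            "ab": self.ab_,
        }
        self.ci_ = {
            k: self._ci_from_boot(v, point[k]) for k, v in self.boot_.items()
        }
        self.n_boot_redrawn_ = n_redraw

    def _ci_from_boot(self, boot: np.ndarray, theta: float):
        lo_q = (1.0 - self.ci_level) / 2.0
        hi_q = 1.0 - lo_q
        if self.ci_method == "percentile":
            lo, hi = np.quantile(boot, [lo_q, hi_q])
        elif self.ci_method == "bc":
            frac = np.clip(np.mean(boot < theta), 1e-8, 1 - 1e-8)
            z0 = stats.norm.ppf(frac)
            zlo, zhi = stats.norm.ppf([lo_q, hi_q])
            lo, hi = np.quantile(
                boot, stats.norm.cdf([2 * z0 + zlo, 2 * z0 + zhi])
            )
        else:
            raise ValueError(f"unknown ci_method {self.ci_method!r}")
        return float(lo), float(hi)

    # ------------------------------------------------------------------
    def predict(self, X, M, gender) -> np.ndarray:
        """Predict the outcome from the unstandardized outcome equation."""
        if not hasattr(self, "outcome_coef_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        A = np.column_stack([np.ones(X.shape[0]), X, np.asarray(M, float),
                             np.asarray(gender, float)])
        return A @ self.outcome_coef_


def fit_path_model(X, M, Y, gender, **kwargs) -> PathMediationModel:
    """Fit a :class:`PathMediationModel`; keyword args pass to the estimator."""
    return PathMediationModel(**kwargs).fit(X, M, Y, gender)


def bootstrap_paths(
    X, M, Y, gender,
    n_boot: int = 5000,
    ci_level: float = 0.95,
    ci_method: str = "percentile",
    seed=None,
) -> dict:
    """Bootstrap confidence intervals per path and for the indirect effect."""
    model = PathMediationModel(
        n_boot=n_boot, ci_level=ci_level, ci_method=ci_method, random_state=seed
    ).fit(X, M, Y, gender)
    return model.ci_


def classify_effect(model: PathMediationModel, alpha: float | None = None) -> str:
    """Classify a fitted path model as mediation, suppression, or none.

    Both the X->M and M->Y|X paths must be significant at ``alpha``;
    otherwise the verdict is ``"none"``.  With significant paths, opposite
    signs of ab and c' (|total| < |direct|) mean suppression; matching signs
    mean mediation.
    """
    if alpha is None:
        alpha = model.alpha
    if model.p_a_ >= alpha or model.p_b_ >= alpha:
        return "none"
    if model.ab_ * model.c_prime_ < 0:
        return "suppression"
    return "mediation"


def loo_validate(X, M, Y, gender):
    """Leave-one-out prediction of the outcome and predicted-observed r.

    For each subject the unstandardized outcome equation
    ``Y ~ 1 + X + M + gender`` is fit on the remaining subjects and used to
    predict the held-out score.  For OLS this equals the hat-matrix
    identity ``yhat_(-i) = y_i - e_i / (1 - h_ii)``, which is used here.

    Returns ``(predicted, r)`` with r the Pearson correlation between
    predicted and observed scores.
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    gender = np.asarray(gender, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 subjects")
    A = np.column_stack([np.ones(n), X, M, gender])
    beta, *_ = np.linalg.lstsq(A, Y, rcond=None)
    resid = Y - A @ beta
    G = np.linalg.inv(A.T @ A)
    h = np.einsum("ij,jk,ik->i", A, G, A)
    if np.any(h >= 1.0):
        raise ValueError("leverage 1 encountered; LOO undefined")
    pred = Y - resid / (1.0 - h)
    r = float(np.corrcoef(pred, Y)[0, 1])
    return pred, r


def _ks_normal(vals: np.ndarray):
    """Classical one-sample KS vs Normal(sample mean, sample sd), as Z.

    Parameters are estimated from the sample (the SPSS legacy convention);
    the resulting p-value is conservative relative to Lilliefors.
    """
    n = len(vals)
    mu, sd = vals.mean(), vals.std(ddof=1)
    d = stats.kstest(vals, "norm", args=(mu, sd)).statistic
    z = float(np.sqrt(n) * d)
    p = float(stats.kstwobign.sf(z))
    return z, p


def describe_phenotype(Y, gender, corrected: bool = True) -> dict:
    """Descriptive statistics of the trait score, overall and per gender.

    Skewness and excess kurtosis use the small-sample-corrected estimators
    G1/G2 by default (set ``corrected=False`` for the uncorrected moment
    ratios).  Normality is summarised by the one-sample KS statistic
    against a normal with sample-estimated parameters, reported as
    ``Z = sqrt(n) * D``.  Includes a two-sample t-test across gender when
    both groups are present.
    """
    Y = np.asarray(Y, dtype=float)
    gender = np.asarray(gender)
    out: dict = {"overall": {
        "n": int(len(Y)),
        "mean": float(Y.mean()),
        "sd": float(Y.std(ddof=1)),
    }}
    groups = {}
    for gval in np.unique(gender):
        vals = Y[gender == gval]
        if len(vals) < 2:
            continue
        z, p = _ks_normal(vals)
        groups[str(gval)] = {
            "n": int(len(vals)),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "skewness": float(stats.skew(vals, bias=not corrected)),
            "kurtosis": float(stats.kurtosis(vals, bias=not corrected)),
            "ks_z": z,
            "ks_p": p,
        }
    out["by_gender"] = groups
    if len(groups) >= 2:
        keys = list(groups)
        g0 = Y[gender == np.unique(gender)[0]]
        g1 = Y[gender == np.unique(gender)[1]]
        t, p = stats.ttest_ind(g0, g1)
        out["gender_t"] = float(t)
        out["gender_t_p"] = float(p)
    else:
        warnings.warn("single-gender input; t-test omitted", stacklevel=2)
    return out


def extract_roi_mean(map_stack: np.ndarray, cluster_mask: np.ndarray) -> np.ndarray:
    """Mean over member voxels, per subject.

    ``map_stack`` is subjects x voxels (flattened over the analysis mask);
    ``cluster_mask`` is a boolean selector or index array over that voxel
    axis.
    """
    map_stack = np.asarray(map_stack, dtype=float)
    cluster_mask = np.asarray(cluster_mask)
    if cluster_mask.dtype == bool:
        if cluster_mask.shape[0] != map_stack.shape[1]:
            raise ValueError("cluster mask does not match voxel axis")
        if not cluster_mask.any():
            raise ValueError("empty cluster mask")
        sel = cluster_mask
    else:
        if cluster_mask.size == 0:
            raise ValueError("empty cluster mask")
        sel = cluster_mask.astype(int)
    return map_stack[:, sel].mean(axis=1)
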