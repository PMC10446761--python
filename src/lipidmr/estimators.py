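"""Univariable two-sample MR estimators and diagnostics.

Estimators operate on a harmonized instrument set (per-allele exposure and
outcome effects with standard errors).  Implemented here:

* Wald ratio — single-instrument base case, beta_Y / beta_X.
* IVW — zero-intercept weighted regression of outcome on exposure effects
  with weights 1/se_Y².  Fixed-effects SE, or multiplicative random-effects
  SE (fixed-effects SE scaled by sqrt(Q/(k-1)), floored at 1).  ``auto``
  mode applies the heterogeneity switching rule: random effects when
  Cochran's Q has p < 0.05, fixed effects otherwise.
* Cochran's Q heterogeneity statistic.
* MR-Egger — weighted regression with a free intercept; a non-zero
  intercept indicates directional pleiotropy.  Instruments are oriented to
  non-negative exposure effects before fitting.
* A PRESSO-style parametric-bootstrap global heterogeneity test with
  per-variant outlier flagging.
* Bonferroni significance labelling across exposures × outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .harmonize import HarmonizedRecord, HarmonizedSet
from .sumstats import Z_95

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "egger",
    "detect_outliers",
    "PressoResult",
    "significance_label",
]


@dataclass
class MREstimate:
    """One method's causal estimate with heterogeneity/pleiotropy diagnostics.

    ``beta`` is the causal effect on the outcome's additive scale per unit
    (per SD for continuous exposures); ``or_`` = exp(beta) with a 95% CI.
    Egger-specific fields are ``None`` for other methods.
    """

    method: str
    k_snps: int
    beta: float
    se: float
    pvalue: float
    q: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    label: str | None = None
    exposure: str | None = None
    outcome: str | None = None

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z_95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z_95 * self.se))

    def as_dict(self) -> dict:
        d = asdict(self)
        d["or"] = self.or_
        d["ci_low"] = self.ci_low
        d["ci_high"] = self.ci_high
        return d


def _arrays(h: HarmonizedSet):
    df = h.df
    return (df["beta_X"].to_numpy(float), df["se_X"].to_numpy(float),
            df["beta_Y"].to_numpy(float), df["se_Y"].to_numpy(float))


def wald_ratio(rec: HarmonizedRecord) -> MREstimate:
    """Single-instrument causal estimate beta_Y / beta_X.

    First-order SE: se_Y / |beta_X| (exposure-side uncertainty ignored, the
    standard leading-order approximation).
    """
    if rec.beta_X == 0:
        raise ValueError(f"{rec.rsid}: beta_X must be nonzero for a Wald ratio")
    beta = rec.beta_Y / rec.beta_X
    se = rec.se_Y / abs(rec.beta_X)
    p = 2 * stats.norm.sf(abs(beta / se))
    return MREstimate(method="wald", k_snps=1, beta=float(beta), se=float(se),
                      pvalue=float(p))


def cochran_q(h: HarmonizedSet, beta_hat: float):
    """Cochran's Q about a fitted slope: Σ (beta_Y − beta_hat·beta_X)²/se_Y².

    Returns ``(q, df, p)`` with df = k−1 and p from the upper chi-square tail.
    """
    x, _, y, sy = _arrays(h)
    k = len(x)
    if k < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    q = float(np.sum((y - beta_hat * x) ** 2 / sy**2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def ivw(h: HarmonizedSet, mode: str = "auto") -> MREstimate:
    """Inverse-variance weighted estimate.

    Zero-intercept weighted regression of beta_Y on beta_X, weights 1/se_Y².
    ``mode="fe"`` uses the fixed-effects SE 1/sqrt(Σ w·beta_X²);
    ``mode="re"`` scales it by max(1, sqrt(Q/(k−1))) (multiplicative random
    effects); ``mode="auto"`` picks RE when the Q test has p < 0.05 and FE
    otherwise.  With a single instrument the estimate reduces to the Wald
    ratio.
    """
    if mode not in ("fe", "re", "auto"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    x, _, y, sy = _arrays(h)
    k = len(x)
    if k == 1:
        return wald_ratio(h.records[0])
    if k < 2:
        raise ValueError("IVW requires at least 2 instruments")
    if np.all(x == 0):
        raise ValueError("all exposure effects are zero; IVW undefined")
    w = 1.0 / sy**2
    sxx = float(np.sum(w * x * x))
    beta = float(np.sum(w * x * y) / sxx)
    se_fe = sxx**-0.5
    q, q_df, q_p = cochran_q(h, beta)
    scale = max(1.0, np.sqrt(q / q_df))
    if mode == "fe":
        se, method = se_fe, "ivw_fe"
    elif mode == "re":
        se, method = se_fe * scale, "ivw_re"
    else:
        if q_p < 0.05:
            se, method = se_fe * scale, "ivw_re"
        else:
            se, method = se_fe, "ivw_fe"
    p = 2 * stats.norm.sf(abs(beta / se))
    return MREstimate(method=method, k_snps=k, beta=beta, se=float(se),
                      pvalue=float(p), q=q, q_df=q_df, q_pvalue=q_p,
                      exposure=h.exposure_id, outcome=h.outcome_id)


def egger(h: HarmonizedSet, pvalue_dist: str = "t") -> MREstimate:
    """MR-Egger regression: weighted fit with a free pleiotropy intercept.

    Instruments are oriented internally so all exposure effects are
    non-negative (the InSIDE convention); the input is not mutated.  Both
    the slope and intercept SEs carry the multiplicative scaling
    max(1, sqrt(Q_egger/(k−2))).  p-values use a t distribution with k−2 df
    by default (``pvalue_dist="normal"`` switches to the normal).
    """
    x, _, y, sy = _arrays(h)
    k = len(x)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    sgn = np.where(x < 0, -1.0, 1.0)
    x = x * sgn
    y = y * sgn
    w = 1.0 / sy**2
    # Weighted normal equations for y = a + b x.
    sw, swx, swxx = np.sum(w), np.sum(w * x), np.sum(w * x * x)
    swy, swxy = np.sum(w * y), np.sum(w * x * y)
    det = sw * swxx - swx**2
    if det <= 0:
        raise ValueError("degenerate design: exposure effects not identifiable")
    a = (swxx * swy - swx * swxy) / det
    b = (sw * swxy - swx * swy) / det
    resid = y - a - b * x
    q = float(np.sum(w * resid**2))
    q_df = k - 2
    scale = max(1.0, np.sqrt(q / q_df)) if q_df > 0 else 1.0
    se_a = np.sqrt(swxx / det) * scale
    se_b = np.sqrt(sw / det) * scale
    if pvalue_dist == "t":
        p_b = 2 * stats.t.sf(abs(b / se_b), q_df)
        p_a = 2 * stats.t.sf(abs(a / se_a), q_df)
    else:
        p_b = 2 * stats.norm.sf(abs(b / se_b))
        p_a = 2 * stats.norm.sf(abs(a / se_a))
    return MREstimate(method="egger", k_snps=k, beta=float(b), se=float(se_b),
                      pvalue=float(p_b), q=q, q_df=q_df,
                      q_pvalue=float(stats.chi2.sf(q, q_df)),
                      egger_intercept=float(a), egger_intercept_se=float(se_a),
                      egger_intercept_p=float(p_a),
                      exposure=h.exposure_id, outcome=h.outcome_id)


@dataclass
class PressoResult:
    """Outcome of the PRESSO-style global test and outlier search."""

    global_rss: float
    global_p: float
    outliers: list[str] = field(default_factory=list)
    outlier_p: dict = field(default_factory=dict)
    estimate_corrected: MREstimate | None = None


def detect_outliers(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
                    alpha: float = 0.05, rerun: bool = True) -> PressoResult:
    """Parametric-bootstrap heterogeneity test with per-variant outlier flags.

    For each instrument j a leave-one-out IVW slope θ̂(−j) is computed; the
    observed statistic is RSS = Σ_j w_j (beta_Yj − θ̂(−j)·beta_Xj)².  Under
    the no-pleiotropy null, ``n_sim`` datasets are simulated with
    beta*_Xj ~ N(beta_Xj, se_Xj²) and beta*_Yj ~ N(θ̂(−j)·beta_Xj, se_Yj²),
    and the same statistic (including re-computed leave-one-out slopes) gives
    the reference distribution.  The global p is the fraction of simulated
    RSS ≥ observed.  Per-variant outlier p-values compare each observed
    squared weighted residual with its simulated distribution and are
    Bonferroni-corrected across the k instruments; flagged variants are
    removed and the corrected IVW estimate reported.  Fully deterministic
    given ``seed``.
    """
    x, sx, y, sy = _arrays(h)
    k = len(x)
    if k < 4:
        raise ValueError("outlier detection needs >= 4 instruments; "
                         "use Cochran's Q diagnostics for smaller sets")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000 for stable tail estimates")
    rng = np.random.default_rng(seed)

    w = 1.0 / sy**2

    def loo_slopes(xm, ym):
        # Vectorized leave-one-out IVW slopes for rows of (n, k) matrices.
        sxy = np.sum(w * xm * ym, axis=-1, keepdims=True)
        sxx = np.sum(w * xm * xm, axis=-1, keepdims=True)
        return (sxy - w * xm * ym) / (sxx - w * xm * xm)

    theta_loo = loo_slopes(x[None, :], y[None, :])[0]
    obs_res2 = w * (y - theta_loo * x) ** 2
    rss_obs = float(np.sum(obs_res2))

    xs = rng.normal(x, sx, size=(n_sim, k))
    ys = rng.normal(theta_loo * x, sy, size=(n_sim, k))
    sim_theta = loo_slopes(xs, ys)
    sim_res2 = w * (ys - sim_theta * xs) ** 2
    sim_rss = np.sum(sim_res2, axis=1)

    global_p = float(np.mean(sim_rss >= rss_obs))
    per_p = np.mean(sim_res2 >= obs_res2[None, :], axis=0)
    corrected = np.minimum(1.0, per_p * k)
    rsids = h.df["rsid"].tolist()
    outliers = [r for r, p in zip(rsids, corrected) if p < alpha]
    outlier_p = dict(zip(rsids, corrected))

    result = PressoResult(global_rss=rss_obs, global_p=global_p,
                          outliers=outliers, outlier_p=outlier_p)
    if outliers and rerun:
        kept = [r for r in rsids if r not in set(outliers)]
        if len(kept) >= 2:
            result.estimate_corrected = ivw(h.subset(kept), mode="auto")
    return result


def significance_label(p: float, x: int, y: int, alpha: float = 0.05) -> str:
    """Bonferroni evidence label across ``x`` exposures and ``y`` outcomes.

    ``strong`` for p < alpha/x/y, ``suggestive`` for alpha/x/y ≤ p < alpha,
    ``null`` otherwise.
    """
    if x < 1 or y < 1:
        raise ValueError("x and y must be >= 1")
    strong = alpha / x / y
    if p < strong:
        return "strong"
    if p < alpha:
        return "suggestive"
    return "null"
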