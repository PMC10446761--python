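"""Multivariable MR: joint direct effects of several exposures.

For exposures measured on the same instrument panel (here the HDL-C /
LDL-C / TG union of genome-wide-significant variants), the multivariable
IVW estimator regresses outcome effects on the K columns of exposure
effects through the origin with weights 1/se_Y².  Conditional instrument
strength quantifies how much signal each exposure's instruments carry
beyond the other exposures.  MR-Lasso adds per-variant intercepts with an
L1 penalty to identify invalid (pleiotropic) instruments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate
from .harmonize import HarmonizedSet

__all__ = ["MVHarmonizedSet", "build_mv_set", "mvmr_ivw", "conditional_f",
           "mr_lasso", "LassoResult"]


@dataclass
class MVHarmonizedSet:
    """Per-variant effects on K exposures and one outcome, on a common allele."""

    exposure_ids: list[str]
    rsids: list[str]
    beta_X: np.ndarray  # (L, K)
    se_X: np.ndarray    # (L, K)
    beta_Y: np.ndarray  # (L,)
    se_Y: np.ndarray    # (L,)
    outcome_id: str = ""

    def __post_init__(self) -> None:
        self.beta_X = np.atleast_2d(np.asarray(self.beta_X, float))
        self.se_X = np.atleast_2d(np.asarray(self.se_X, float))
        self.beta_Y = np.asarray(self.beta_Y, float)
        self.se_Y = np.asarray(self.se_Y, float)
        L, K = self.beta_X.shape
        if len(self.exposure_ids) != K:
            raise ValueError("exposure_ids length must match beta_X columns")
        if self.se_X.shape != (L, K) or self.beta_Y.shape != (L,) or \
                self.se_Y.shape != (L,):
            raise ValueError("inconsistent array shapes")
        if len(set(self.rsids)) != L:
            raise ValueError("rsids must be unique and match row count")
        if np.any(self.se_X <= 0) or np.any(self.se_Y <= 0):
            raise ValueError("standard errors must be > 0")

    @property
    def L(self) -> int:
        return self.beta_X.shape[0]

    @property
    def K(self) -> int:
        return self.beta_X.shape[1]

    def subset(self, rsids) -> "MVHarmonizedSet":
        keep = [i for i, r in enumerate(self.rsids) if r in set(rsids)]
        return MVHarmonizedSet(
            exposure_ids=self.exposure_ids,
            rsids=[self.rsids[i] for i in keep],
            beta_X=self.beta_X[keep], se_X=self.se_X[keep],
            beta_Y=self.beta_Y[keep], se_Y=self.se_Y[keep],
            outcome_id=self.outcome_id)


def build_mv_set(harmonized: list[HarmonizedSet]) -> MVHarmonizedSet:
    """Assemble an MV set from per-exposure harmonized sets vs one outcome.

    All sets must target the same outcome; the instrument panel is the
    intersection of rsids (every exposure effect must be available per
    variant).  Alignment to the outcome allele was already done per set, so
    outcome effects agree across sets by construction.
    """
    if not harmonized:
        raise ValueError("need at least one harmonized set")
    outcome = harmonized[0].outcome_id
    if any(h.outcome_id != outcome for h in harmonized):
        raise ValueError("all harmonized sets must share one outcome")
    frames = []
    for h in harmonized:
        f = h.df.set_index("rsid")[["beta_X", "se_X", "beta_Y", "se_Y",
                                    "aligned_allele"]]
        frames.append(f)
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    common = sorted(common)
    if not common:
        raise ValueError("no common instruments across exposures")
    # Exposure effects must refer to the same allele per variant; re-sign
    # any set aligned to the opposite allele relative to the first.
    ref = frames[0].loc[common]
    bX, sX = [], []
    for h, f in zip(harmonized, frames):
        sub = f.loc[common]
        sign = np.where(sub["aligned_allele"].to_numpy() ==
                        ref["aligned_allele"].to_numpy(), 1.0, -1.0)
        bX.append(sub["beta_X"].to_numpy(float) * sign)
        sX.append(sub["se_X"].to_numpy(float))
    return MVHarmonizedSet(
        exposure_ids=[h.exposure_id for h in harmonized],
        rsids=list(common),
        beta_X=np.column_stack(bX), se_X=np.column_stack(sX),
        beta_Y=ref["beta_Y"].to_numpy(float), se_Y=ref["se_Y"].to_numpy(float),
        outcome_id=outcome)


def _check_rank(m: MVHarmonizedSet) -> None:
    X = m.beta_X
    if np.linalg.matrix_rank(X) < m.K:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [(m.exposure_ids[i], m.exposure_ids[j])
                 for i in range(m.K) for j in range(i + 1, m.K)
                 if abs(corr[i, j]) > 0.999]
        raise ValueError(f"rank-deficient exposure design; collinear: {pairs}")


def mvmr_ivw(m: MVHarmonizedSet) -> list[MREstimate]:
    """Multivariable IVW: weighted zero-intercept multiple regression.

    Solves (XᵀWX)θ = XᵀWy with W = diag(1/se_Y²); per-exposure SEs come
    from the inverse weighted normal equations.  Q uses df = L − K.  With
    K = 1 this is exactly the univariable fixed-effects IVW.
    """
    if m.L <= m.K:
        raise ValueError("need more instruments than exposures")
    _check_rank(m)
    X, y, w = m.beta_X, m.beta_Y, 1.0 / m.se_Y**2
    XtW = X.T * w
    A = XtW @ X
    theta = np.linalg.solve(A, XtW @ y)
    cov = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    resid = y - X @ theta
    q = float(np.sum(w * resid**2))
    q_df = m.L - m.K
    q_p = float(stats.chi2.sf(q, q_df))
    out = []
    for j, trait in enumerate(m.exposure_ids):
        p = 2 * stats.norm.sf(abs(theta[j] / se[j]))
        out.append(MREstimate(method="mvmr_ivw", k_snps=m.L,
                              beta=float(theta[j]), se=float(se[j]),
                              pvalue=float(p), q=q, q_df=q_df, q_pvalue=q_p,
                              exposure=trait, outcome=m.outcome_id))
    return out


def conditional_f(m: MVHarmonizedSet, k: int) -> float:
    """Conditional instrument strength of exposure ``k`` given the others.

    Regress exposure k's instrument effects on the other exposures' effects
    with weights 1/se_Xk², form the weighted residual sum of squares Q_x and
    return Q_x/(L − K + 1) — the mean weighted squared residual rescaled by
    L/(L − K + 1).  With K = 1 this is the unconditional mean per-variant F.
    A value above ~10 indicates adequate conditional strength.
    """
    if not 0 <= k < m.K:
        raise IndexError("exposure index out of range")
    xk = m.beta_X[:, k]
    w = 1.0 / m.se_X[:, k] ** 2
    if m.K == 1:
        return float(np.mean(xk**2 * w))
    if m.L <= m.K:
        raise ValueError("need more instruments than exposures")
    Z = np.delete(m.beta_X, k, axis=1)
    ZtW = Z.T * w
    coef, *_ = np.linalg.lstsq(ZtW @ Z, ZtW @ xk, rcond=None)
    resid = xk - Z @ coef
    q_x = float(np.sum(w * resid**2))
    return q_x / (m.L - m.K + 1)


@dataclass
class LassoResult:
    """MR-Lasso output: post-selection estimates and flagged invalid variants."""

    estimates: list[MREstimate]
    invalid: list[str]
    lambda_selected: float
    converged: bool
    heterogeneity_ok: bool


def _lasso_fit(m: MVHarmonizedSet, lam: float, tol: float = 1e-8,
               max_iter: int = 10_000):
    """Alternating minimisation of the per-variant-intercept lasso objective.

    Objective: Σ_j (beta_Yj − α_j − θᵀbeta_Xj)²/se_Yj² + λ Σ_j |α_j|.
    Given θ, each α_j has the closed-form soft-threshold update
    α_j = S(r_j, λ se_Yj²/2); given α, θ is the weighted LS fit to
    beta_Y − α.
    """
    X, y, w = m.beta_X, m.beta_Y, 1.0 / m.se_Y**2
    alpha = np.zeros(m.L)
    theta = np.zeros(m.K)
    thresh = lam * m.se_Y**2 / 2.0
    converged = False
    for _ in range(max_iter):
        XtW = X.T * w
        theta_new = np.linalg.solve(XtW @ X, XtW @ (y - alpha))
        r = y - X @ theta_new
        alpha_new = np.sign(r) * np.maximum(0.0, np.abs(r) - thresh)
        delta = max(np.max(np.abs(theta_new - theta)),
                    np.max(np.abs(alpha_new - alpha)) if m.L else 0.0)
        scale = max(1.0, np.max(np.abs(theta_new)), np.max(np.abs(alpha_new)))
        theta, alpha = theta_new, alpha_new
        if delta / scale < tol:
            converged = True
            break
    return theta, alpha, converged


def mr_lasso(m: MVHarmonizedSet, lambda_grid=None) -> LassoResult:
    """MR-Lasso: L1-penalised per-variant intercepts flag invalid instruments.

    The penalty λ is chosen as the largest grid value whose post-selection
    Cochran's Q — computed on variants with zero fitted intercept — has
    p ≥ 0.05; the causal estimates are then re-fit by multivariable IVW on
    those valid variants.  If no λ on the grid satisfies the criterion the
    largest λ is used and the result flagged.  λ = 0 is rejected (one free
    intercept per variant is unidentifiable).
    """
    if m.L <= m.K + 1:
        raise ValueError("need at least K + 2 instruments for MR-Lasso")
    if lambda_grid is None:
        # Scale grid to the spread of weighted residuals about the IVW fit.
        base = mvmr_ivw(m)
        theta0 = np.array([e.beta for e in base])
        r = (m.beta_Y - m.beta_X @ theta0) / m.se_Y**2
        scale = max(np.median(np.abs(r)), 1e-8)
        lambda_grid = scale * np.logspace(-2, 2, 50)
    lambda_grid = np.asarray(sorted(lambda_grid), dtype=float)
    if np.any(lambda_grid <= 0):
        raise ValueError("lambda values must be > 0 (per-variant intercepts "
                         "are unidentifiable at lambda = 0)")

    chosen = None
    fits = {}
    for lam in lambda_grid[::-1]:  # largest first
        theta, alpha, conv = _lasso_fit(m, lam)
        valid = [r for r, a in zip(m.rsids, alpha) if a == 0.0]
        fits[lam] = (valid, conv)
        if len(valid) <= m.K:
            continue
        sub = m.subset(valid)
        est = mvmr_ivw(sub)
        if est[0].q_pvalue >= 0.05:
            chosen = (lam, valid, conv, est)
            break
    if chosen is None:
        lam = float(lambda_grid[-1])
        valid, conv = fits[lam]
        if len(valid) <= m.K:
            valid = list(m.rsids)
        est = mvmr_ivw(m.subset(valid))
        warnings.warn("mr_lasso: no lambda met the heterogeneity criterion; "
                      "returning the largest-lambda fit")
        hetero_ok = False
    else:
        lam, valid, conv, est = chosen
        hetero_ok = True
    invalid = [r for r in m.rsids if r not in set(valid)]
    for e in est:
        e.method = "mr_lasso"
    return LassoResult(estimates=est, invalid=invalid,
                       lambda_selected=float(lam), converged=conv,
                       heterogeneity_ok=hetero_ok)
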