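"""Two-step MR mediation and drug-scale conventions.

The total causal effect of an exposure on the outcome is decomposed into an
indirect path through a mediator and a direct remainder:

* indirect: product of coefficients, beta = beta1 · beta2, with the
  delta-method SE sqrt(beta1² se2² + beta2² se1² + se1² se2²);
* direct: total − indirect (so total = direct + indirect exactly);
* proportion mediated: indirect / total, flagged inconsistent when the two
  effects have opposite signs.

All arithmetic is on the additive (log-odds / per-SD) scale; odds ratios
are converted at the boundary.  For drug-target MR proxied by LDL-C, a
fitted OR per SD *increase* in LDL-C is re-expressed on the drug
(lipid-lowering) scale as its reciprocal (1/OR); HDL-C-proxied CETP
estimates already point in the pharmacological direction and are left
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import ivw
from .harmonize import harmonize
from .instruments import select_by_pvalue, clump, filter_by_f

__all__ = ["MediationInput", "MediationResult", "drug_scale_or",
           "indirect_effect", "direct_effect", "proportion_mediated",
           "run_mediation"]


@dataclass(frozen=True)
class MediationInput:
    """The three MR legs feeding a mediation decomposition.

    beta1/se1: exposure→mediator; beta2/se2: mediator→outcome;
    beta_total/se_total: exposure→outcome.
    """

    beta1: float
    se1: float
    beta2: float
    se2: float
    beta_total: float
    se_total: float

    def __post_init__(self) -> None:
        if not (self.se1 > 0 and self.se2 > 0 and self.se_total > 0):
            raise ValueError("all standard errors must be > 0")


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition with delta-method uncertainty."""

    beta_indirect: float
    se_indirect: float
    p_indirect: float
    beta_direct: float
    beta_total: float
    proportion_mediated: float
    inconsistent: bool


def drug_scale_or(fitted_or: float, proxy: str = "LDL-C") -> float:
    """Re-express a per-SD-increase OR on the lipid-lowering drug scale.

    LDL-C-proxied drug targets model the drug as *lowering* LDL-C, so the
    pharmacological OR is the reciprocal of the fitted per-SD-increase OR.
    HDL-C-proxied CETP inhibition raises HDL-C, already the drug direction,
    so the OR passes through unchanged.
    """
    if fitted_or <= 0:
        raise ValueError("odds ratio must be > 0")
    if proxy.upper().startswith("HDL"):
        return float(fitted_or)
    return 1.0 / float(fitted_or)


def indirect_effect(mi: MediationInput):
    """Product-of-coefficients indirect effect with delta-method SE.

    beta = beta1·beta2; se = sqrt(beta1² se2² + beta2² se1² + se1² se2²);
    two-sided normal p.
    """
    beta = mi.beta1 * mi.beta2
    se = np.sqrt(mi.beta1**2 * mi.se2**2 + mi.beta2**2 * mi.se1**2 +
                 mi.se1**2 * mi.se2**2)
    p = 2 * stats.norm.sf(abs(beta / se))
    return float(beta), float(se), float(p)


def direct_effect(mi: MediationInput, indirect_beta: float) -> float:
    """Direct effect by subtraction: total − indirect."""
    return mi.beta_total - indirect_beta


def proportion_mediated(indirect: float, total: float):
    """Share of the total effect carried by the mediator, as a percentage.

    Returns ``(percent, inconsistent)``; ``inconsistent`` is True when the
    indirect and total effects have opposite signs (the ratio is then not a
    proportion in the usual sense).
    """
    if total == 0:
        raise ValueError("total effect must be nonzero")
    frac = indirect / total
    return 100.0 * frac, (indirect * total) < 0


def decompose(mi: MediationInput) -> MediationResult:
    """Assemble the full decomposition from the three MR legs."""
    b_ind, se_ind, p_ind = indirect_effect(mi)
    b_dir = direct_effect(mi, b_ind)
    pct, inconsistent = proportion_mediated(b_ind, mi.beta_total)
    return MediationResult(beta_indirect=b_ind, se_indirect=se_ind,
                           p_indirect=p_ind, beta_direct=b_dir,
                           beta_total=mi.beta_total,
                           proportion_mediated=pct, inconsistent=inconsistent)


def run_mediation(exposure_instruments, mediator_ss, outcome_ss, config=None
                  ) -> MediationResult:
    """Two-step MR mediation from summary statistics.

    Three univariable MR fits: exposure→outcome (total; using the supplied
    exposure instruments), exposure→mediator (same instruments), and
    mediator→outcome (instruments selected from the mediator GWAS by p
    threshold, optional clumping and F filtering).  ``config`` keys:
    ``p_threshold`` (default 5e-8), ``f_min`` (10), ``ld`` (LDMatrix for
    mediator clumping), ``clump_r2`` (0.001), ``clump_window_kb`` (10000),
    ``palindrome_policy`` ("drop").
    """
    cfg = dict(p_threshold=5e-8, f_min=10.0, ld=None, clump_r2=0.001,
               clump_window_kb=10_000, palindrome_policy="drop")
    cfg.update(config or {})
    policy = cfg["palindrome_policy"]

    def fit(instr, target, stage):
        h = harmonize(instr, target, policy=policy)
        if len(h) < 2:
            raise ValueError(f"mediation stage {stage!r}: fewer than 2 "
                             f"harmonized instruments")
        return ivw(h, mode="auto")

    total = fit(exposure_instruments, outcome_ss, "exposure->outcome")
    leg1 = fit(exposure_instruments, mediator_ss, "exposure->mediator")

    med_instr = select_by_pvalue(mediator_ss, cfg["p_threshold"])
    # The mediator->outcome leg uses the mediator's own instruments; the
    # exposure's instruments (e.g. the drug locus) are excluded so the leg
    # is not re-weighted toward the exposure pathway.
    exp_rsids = set(exposure_instruments.rsids)
    med_instr = med_instr.replace(
        med_instr.df[~med_instr.df["rsid"].isin(exp_rsids)])
    if cfg["ld"] is not None:
        med_instr = clump(med_instr, cfg["ld"], cfg["clump_r2"],
                          cfg["clump_window_kb"])
    med_instr = filter_by_f(med_instr, cfg["f_min"])
    leg2 = fit(med_instr, outcome_ss, "mediator->outcome")

    mi = MediationInput(beta1=leg1.beta, se1=leg1.se,
                        beta2=leg2.beta, se2=leg2.se,
                        beta_total=total.beta, se_total=total.se)
    return decompose(mi)
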