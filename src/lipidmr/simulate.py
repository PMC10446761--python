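"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the inputs of a lipid→sepsis MR study: an exposure
GWAS (continuous trait, per-SD effects), a binary-outcome GWAS (log-odds
effects), an optional mediator GWAS, and a pairwise r² matrix over the
variant panel.  The causal graph is

    exposure --theta--> outcome
    exposure --alpha_med--> mediator --beta_med--> outcome
    variant ---delta_j (pleiotropy)---> outcome

Per-variant true exposure effects γ_j are normal with SD
``exposure_effect_sd`` for a ``prop_instruments`` fraction of variants and
zero otherwise.  Mediator effects are alpha_med·γ_j; outcome effects are
(theta + alpha_med·beta_med)·γ_j + δ_j with δ_j ~ N(pleiotropy_mean,
pleiotropy_sd²) (directional pleiotropy when the mean is nonzero).  LD
blocks impose a compound-symmetric correlation sqrt(r²) within each block,
applied both to the marginal true effects (marginal = C γ) and to the
estimation noise; the two GWAS samples draw independent noise.  Observed
standard errors follow the standard GWAS approximation
SE = 1/sqrt(2·maf·(1−maf)·n).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import GeneRegion
from .sumstats import LDMatrix, SummaryStats

__all__ = ["CausalModel", "SimulatedStudy", "simulate_sumstats",
           "simulate_drug_locus", "simulate_mv_set"]

_NONPALINDROMIC = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                   ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class CausalModel:
    """Generative truth for the two-sample GWAS simulator.

    Defaults emulate a well-powered lipid-GWAS setting: a few hundred
    candidate variants, common alleles, strong per-variant effects relative
    to the sampling error at biobank-scale n, no pleiotropy and no
    mediation unless switched on.
    """

    m_variants: int = 200
    maf_range: tuple = (0.05, 0.5)
    ld_blocks: tuple = ()            # ((size, within-block r²), ...)
    prop_instruments: float = 1.0
    exposure_effect_sd: float = 0.03
    theta: float = 0.0
    alpha_med: float = 0.0
    beta_med: float = 0.0
    prop_mediator_instruments: float = 0.0
    mediator_effect_sd: float = 0.03
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exposure: int = 500_000
    n_outcome: int = 460_000
    n_mediator: int = 330_000
    prop_palindromic: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_instruments", "prop_palindromic",
                     "prop_mediator_instruments"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("n_exposure", "n_outcome", "n_mediator"):
            if getattr(self, name) < 1000:
                raise ValueError(f"{name} must be >= 1000")
        if sum(s for s, _ in self.ld_blocks) > self.m_variants:
            raise ValueError("ld_blocks sizes must sum to <= m_variants")


@dataclass
class SimulatedStudy:
    """Simulator output bundle: three GWAS, the LD matrix and latent truth."""

    exposure: SummaryStats
    outcome: SummaryStats
    mediator: SummaryStats
    ld: LDMatrix
    truth: pd.DataFrame


def _block_structure(model: CausalModel):
    """Per-variant block id and the block-diagonal correlation matrix C."""
    m = model.m_variants
    block_id = np.arange(m)  # singletons by default
    C = np.eye(m)
    pos = 0
    for b, (size, r2) in enumerate(model.ld_blocks):
        idx = np.arange(pos, pos + size)
        block_id[idx] = m + b  # distinct ids for declared blocks
        C[np.ix_(idx, idx)] = np.sqrt(r2)
        C[idx, idx] = 1.0
        pos += size
    return block_id, C


def _observed(rng, truth_marginal, se, C_chol):
    """Truth + correlated estimation noise (one independent GWAS sample)."""
    z = rng.standard_normal(len(se))
    eps = se * (C_chol @ z)
    return truth_marginal + eps


def _build_ss(trait_id, unit, rsids, chrom, pos, a1, a2, eaf, beta, se, n):
    z = beta / se
    p = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    df = pd.DataFrame({
        "rsid": rsids, "chrom": chrom, "pos": pos,
        "effect_allele": a1, "other_allele": a2, "eaf": eaf,
        "beta": beta, "se": se, "pvalue": p, "n": float(n),
    })
    return SummaryStats(trait_id=trait_id, df=df, trait_unit=unit)


def simulate_sumstats(model: CausalModel, chrom: str = "1",
                      pos_start: int = 1_000_000, pos_step: int = 20_000,
                      rsid_prefix: str = "rs") -> SimulatedStudy:
    """Draw one synthetic two-sample (plus mediator) GWAS study.

    Fully reproducible from ``model.seed``.  The truth frame records, per
    variant, the instrument flag, the direct exposure effect γ, the
    pleiotropic effect δ, the marginal (LD-convolved) true effects for all
    three traits, and the block id.
    """
    rng = np.random.default_rng(model.seed)
    m = model.m_variants
    rsids = [f"{rsid_prefix}{i + 1}" for i in range(m)]
    pos = pos_start + pos_step * np.arange(m)
    mafs = rng.uniform(*model.maf_range, size=m)

    n_pal = int(round(model.prop_palindromic * m))
    pal_mask = np.zeros(m, bool)
    pal_mask[rng.choice(m, size=n_pal, replace=False)] = True
    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    for i in range(m):
        pool = _PALINDROMIC if pal_mask[i] else _NONPALINDROMIC
        a1[i], a2[i] = pool[rng.integers(len(pool))]

    n_instr = int(round(model.prop_instruments * m))
    instr = np.zeros(m, bool)
    instr[rng.choice(m, size=n_instr, replace=False)] = True
    gamma = np.where(instr, rng.normal(0.0, model.exposure_effect_sd, m), 0.0)
    # Directional pleiotropy is defined relative to the exposure-increasing
    # allele (the orientation Egger regression uses), so the mean direct
    # effect is signed along gamma.
    orient = np.where(gamma >= 0, 1.0, -1.0)
    delta = orient * model.pleiotropy_mean + rng.normal(
        0.0, model.pleiotropy_sd, m)

    # Mediator-specific genetic effects, placed on non-exposure-instrument
    # variants where possible so the two traits have distinct instruments.
    n_med = int(round(model.prop_mediator_instruments * m))
    med_instr = np.zeros(m, bool)
    free = np.flatnonzero(~instr)
    take = min(n_med, len(free))
    if take:
        med_instr[rng.choice(free, size=take, replace=False)] = True
    if n_med > take:
        extra = rng.choice(np.flatnonzero(instr), size=n_med - take,
                           replace=False)
        med_instr[extra] = True
    gamma_med = np.where(med_instr,
                         rng.normal(0.0, model.mediator_effect_sd, m), 0.0)

    block_id, C = _block_structure(model)
    C_chol = np.linalg.cholesky(C)

    g_exp = C @ gamma
    g_med = C @ (model.alpha_med * gamma + gamma_med)
    g_out = C @ ((model.theta + model.alpha_med * model.beta_med) * gamma
                 + model.beta_med * gamma_med + delta)

    def se_for(n):
        return 1.0 / np.sqrt(2 * mafs * (1 - mafs) * n)

    se_x = se_for(model.n_exposure)
    se_y = se_for(model.n_outcome)
    se_m = se_for(model.n_mediator)
    bx = _observed(rng, g_exp, se_x, C_chol)
    by = _observed(rng, g_out, se_y, C_chol)
    bm = _observed(rng, g_med, se_m, C_chol)

    eaf = mafs  # effect allele taken as the minor allele
    exposure = _build_ss("exposure", "sd", rsids, chrom, pos, a1, a2, eaf,
                         bx, se_x, model.n_exposure)
    outcome = _build_ss("outcome", "logOR", rsids, chrom, pos, a1, a2, eaf,
                        by, se_y, model.n_outcome)
    mediator = _build_ss("mediator", "sd", rsids, chrom, pos, a1, a2, eaf,
                         bm, se_m, model.n_mediator)

    ld = LDMatrix(rsids=rsids, r2=C**2)
    truth = pd.DataFrame({
        "rsid": rsids, "chrom": chrom, "pos": pos, "maf": mafs,
        "is_instrument": instr, "is_mediator_instrument": med_instr,
        "gamma": gamma, "gamma_med": gamma_med, "delta": delta,
        "g_exposure": g_exp, "g_outcome": g_out, "g_mediator": g_med,
        "block": block_id, "palindromic": pal_mask,
        "theta": model.theta, "alpha_med": model.alpha_med,
        "beta_med": model.beta_med,
    })
    return SimulatedStudy(exposure=exposure, outcome=outcome,
                          mediator=mediator, ld=ld, truth=truth)


def simulate_drug_locus(model: CausalModel, region: GeneRegion,
                        n_locus: int = 20, locus_r2: float = 0.05,
                        locus_effect_sd: float = 0.05) -> SimulatedStudy:
    """Add a cis block of strong instruments inside a drug-target gene region.

    ``n_locus`` variants are placed between the gene's start and end on the
    gene's chromosome, with within-block r² ``locus_r2`` and exposure
    effects drawn with SD ``locus_effect_sd`` (every locus variant is an
    instrument).  The causal effect theta and mediation paths apply to the
    locus exactly as to the genome-wide background, so restricting to the
    region and clumping yields cis instruments whose IVW estimate recovers
    theta.  The truth frame marks locus variants with ``in_locus``.
    """
    span = region.end - region.start
    spacing = max(span // max(n_locus, 1), 1)
    if span < n_locus:
        raise ValueError(f"region {region.symbol} too small for {n_locus} variants")

    base = simulate_sumstats(model, chrom="2" if region.chrom == "1" else "1")
    locus_model = replace(
        model,
        m_variants=n_locus,
        ld_blocks=((n_locus, locus_r2),),
        prop_instruments=1.0,
        exposure_effect_sd=locus_effect_sd,
        prop_palindromic=0.0,
        seed=model.seed + 1_000_003,
    )
    locus = simulate_sumstats(locus_model, chrom=str(region.chrom),
                              pos_start=region.start, pos_step=spacing,
                              rsid_prefix="rs_cis")

    def cat(a: SummaryStats, b: SummaryStats) -> SummaryStats:
        return SummaryStats(trait_id=a.trait_id,
                            df=pd.concat([a.df, b.df], ignore_index=True),
                            trait_unit=a.trait_unit, build=a.build)

    m_all = base.ld.r2.shape[0] + n_locus
    r2 = np.eye(m_all)
    r2[:base.ld.r2.shape[0], :base.ld.r2.shape[0]] = base.ld.r2
    r2[base.ld.r2.shape[0]:, base.ld.r2.shape[0]:] = locus.ld.r2
    ld = LDMatrix(rsids=base.ld.rsids + locus.ld.rsids, r2=r2)

    truth = pd.concat([base.truth.assign(in_locus=False),
                       locus.truth.assign(in_locus=True)], ignore_index=True)
    return SimulatedStudy(exposure=cat(base.exposure, locus.exposure),
                          outcome=cat(base.outcome, locus.outcome),
                          mediator=cat(base.mediator, locus.mediator),
                          ld=ld, truth=truth)


def simulate_mv_set(direct_effects, L: int = 100, effect_sd: float = 0.03,
                    exposure_corr: float = 0.3, n_exposure: int = 500_000,
                    n_outcome: int = 460_000, maf: float = 0.25,
                    invalid: int = 0, invalid_effect: float = 0.0,
                    seed: int = 0, exposure_ids=None):
    """Synthetic multivariable harmonized set with known direct effects.

    Per-variant true effects on the K exposures are jointly normal with SD
    ``effect_sd`` and pairwise correlation ``exposure_corr`` (lipid traits
    share variants, so correlated instrument effects are the realistic
    case).  The outcome truth is the linear combination with coefficients
    ``direct_effects``; the first ``invalid`` variants additionally carry a
    direct (pleiotropic) outcome effect ``invalid_effect``.  Observed
    effects add independent noise with the standard GWAS SEs at the given
    sample sizes.  Returns ``(MVHarmonizedSet, truth dict)``.
    """
    from .mvmr import MVHarmonizedSet

    rng = np.random.default_rng(seed)
    theta = np.asarray(direct_effects, dtype=float)
    K = len(theta)
    cov = np.full((K, K), exposure_corr) + (1 - exposure_corr) * np.eye(K)
    cov *= effect_sd**2
    gx = rng.multivariate_normal(np.zeros(K), cov, size=L)
    se_x = np.full((L, K), 1.0 / np.sqrt(2 * maf * (1 - maf) * n_exposure))
    se_y = np.full(L, 1.0 / np.sqrt(2 * maf * (1 - maf) * n_outcome))
    delta = np.zeros(L)
    delta[:invalid] = invalid_effect
    gy = gx @ theta + delta
    bx = gx + rng.normal(0.0, se_x)
    by = gy + rng.normal(0.0, se_y)
    rsids = [f"rs_mv{i + 1}" for i in range(L)]
    m = MVHarmonizedSet(
        exposure_ids=list(exposure_ids or [f"X{k + 1}" for k in range(K)]),
        rsids=rsids, beta_X=bx, se_X=se_x, beta_Y=by, se_Y=se_y,
        outcome_id="outcome")
    truth = {"theta": theta, "gx": gx, "delta": delta,
             "invalid_rsids": rsids[:invalid]}
    return m, truth
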