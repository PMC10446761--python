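"""Configuration-driven orchestration of the MR analysis phases.

Five phases mirror a full lipid→sepsis study: forward two-sample MR
(TSMR), reverse MR (outcome as exposure), multivariable MR over jointly
modelled lipid exposures, drug-target (cis) MR per gene region with the
reciprocal-OR drug-scale convention, and two-step mediation.  Each phase
logs stage-by-stage instrument counts and writes a forest-table TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import instruments as instr_mod
from .estimators import detect_outliers, egger, ivw, significance_label
from .harmonize import harmonize
from .instruments import (DRUG_TARGET_REGIONS, GeneRegion, clump, filter_by_f,
                          restrict_to_region, screen_confounders,
                          select_by_pvalue)
from .mediation import drug_scale_or, run_mediation
from .mvmr import build_mv_set, conditional_f, mr_lasso, mvmr_ivw
from .sumstats import LDMatrix, SummaryStats, read_sumstats, write_report

__all__ = ["AnalysisConfig", "PhaseReport", "select_instruments",
           "run_tsmr", "run_reverse", "run_mvmr", "run_drug_target",
           "run_mediation_phase", "run_all"]

log = logging.getLogger("lipidmr.pipeline")


@dataclass
class AnalysisConfig:
    """Declarative settings for one analysis run.

    Thresholds default to the standard instrument-selection rules:
    genome-wide significance 5e-8 (fallback 5e-6 when fewer than
    ``min_instruments`` survive), clumping r² < 0.001 within 10,000 kb,
    drug-target clumping r² < 0.1 within a ±100 kb gene flank, F > 10,
    palindromes dropped.
    """

    exposure_path: str | None = None
    outcome_path: str | None = None
    mediator_path: str | None = None
    ld_path: str | None = None
    confounder_path: str | None = None
    exposure_dialect: str = "generic"
    outcome_dialect: str = "generic"

    p_threshold: float = 5e-8
    p_threshold_fallback: float = 5e-6
    min_instruments: int = 2
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    drug_r2: float = 0.1
    drug_flank_kb: int = 100
    f_min: float = 10.0
    confounder_p: float = 5e-8
    palindrome_policy: str = "drop"
    alpha: float = 0.05
    n_exposures: int = 1
    n_outcomes: int = 1
    presso_nsim: int = 1000
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("p_threshold", "p_threshold_fallback", "clump_r2",
                     "drug_r2", "alpha", "confounder_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            log.warning("ignoring unknown config keys: %s", sorted(unknown))
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PhaseReport:
    """One phase's estimates plus stage-by-stage instrument accounting."""

    phase: str
    estimates: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_dict() for e in self.estimates])


def select_instruments(exposure: SummaryStats, ld: LDMatrix | None,
                       cfg: AnalysisConfig, confounders: pd.DataFrame | None,
                       region: GeneRegion | None = None) -> tuple[SummaryStats, dict]:
    """Run the full selection chain, returning instruments + stage counts."""
    counts = {"candidates": len(exposure)}
    ss = select_by_pvalue(exposure, cfg.p_threshold)
    counts["p_threshold_used"] = cfg.p_threshold
    if len(ss) < cfg.min_instruments:
        ss = select_by_pvalue(exposure, cfg.p_threshold_fallback)
        counts["p_threshold_used"] = cfg.p_threshold_fallback
        log.info("fell back to p < %g (%d instruments)",
                 cfg.p_threshold_fallback, len(ss))
    counts["after_pvalue"] = len(ss)
    if region is not None:
        ss = restrict_to_region(ss, region)
        counts["after_region"] = len(ss)
    if ld is not None and len(ss) > 1:
        r2_max = cfg.drug_r2 if region is not None else cfg.clump_r2
        ss = clump(ss, ld, r2_max=r2_max, window_kb=cfg.clump_window_kb)
        counts["after_clump"] = len(ss)
    if confounders is not None:
        ss, removal_log = screen_confounders(ss, confounders, cfg.confounder_p)
        counts["after_confounder_screen"] = len(ss)
        counts["confounder_removals"] = len(removal_log)
    ss = filter_by_f(ss, cfg.f_min)
    counts["after_f_filter"] = len(ss)
    for row in [f"{k}={v}" for k, v in counts.items()]:
        log.info("selection: %s", row)
    return ss, counts


def _fit_phase(instruments: SummaryStats, outcome: SummaryStats,
               cfg: AnalysisConfig, phase: str, counts: dict) -> PhaseReport:
    h = harmonize(instruments, outcome, policy=cfg.palindrome_policy)
    counts.update(h.provenance)
    if len(h) == 0:
        raise RuntimeError(f"{phase}: no instruments survive harmonization "
                           f"(provenance: {h.provenance})")
    report = PhaseReport(phase=phase, counts=counts)
    est = ivw(h, mode="auto")
    est.label = significance_label(est.pvalue, cfg.n_exposures,
                                   cfg.n_outcomes, cfg.alpha)
    report.estimates.append(est)
    if len(h) >= 3:
        eg = egger(h)
        eg.label = significance_label(eg.pvalue, cfg.n_exposures,
                                      cfg.n_outcomes, cfg.alpha)
        report.estimates.append(eg)
    if len(h) >= 4:
        presso = detect_outliers(h, n_sim=cfg.presso_nsim, seed=cfg.seed)
        report.extra["presso_global_p"] = presso.global_p
        report.extra["presso_outliers"] = presso.outliers
        if presso.estimate_corrected is not None:
            corrected = presso.estimate_corrected
            corrected.method += "_outlier_corrected"
            corrected.label = significance_label(
                corrected.pvalue, cfg.n_exposures, cfg.n_outcomes, cfg.alpha)
            report.estimates.append(corrected)
    return report


def run_tsmr(exposure: SummaryStats, outcome: SummaryStats,
             ld: LDMatrix | None, cfg: AnalysisConfig,
             confounders: pd.DataFrame | None = None,
             phase: str = "tsmr") -> PhaseReport:
    """Forward two-sample MR: selection chain, IVW(auto), Egger, PRESSO."""
    sel, counts = select_instruments(exposure, ld, cfg, confounders)
    if len(sel) == 0:
        raise RuntimeError(f"{phase}: no instruments survive selection "
                           f"(counts: {counts})")
    return _fit_phase(sel, outcome, cfg, phase, counts)


def run_reverse(exposure: SummaryStats, outcome: SummaryStats,
                ld: LDMatrix | None, cfg: AnalysisConfig) -> PhaseReport:
    """Reverse MR: the outcome trait instruments the original exposure."""
    return run_tsmr(outcome, exposure, ld, cfg, phase="reverse")


def run_mvmr(exposures: list[SummaryStats], outcome: SummaryStats,
             ld: LDMatrix | None, cfg: AnalysisConfig) -> PhaseReport:
    """Multivariable MR on the union of each exposure's instruments."""
    union: list[str] = []
    for ss in exposures:
        sel = select_by_pvalue(ss, cfg.p_threshold)
        union.extend(r for r in sel.rsids if r not in union)
    counts = {"union_candidates": len(union)}
    panel = exposures[0].subset(union)
    if ld is not None and len(panel) > 1:
        panel = clump(panel, ld, r2_max=cfg.clump_r2,
                      window_kb=cfg.clump_window_kb)
    counts["after_clump"] = len(panel)
    keep = set(panel.rsids)
    hsets = [harmonize(ss.subset(keep), outcome, policy=cfg.palindrome_policy)
             for ss in exposures]
    m = build_mv_set(hsets)
    counts["harmonized"] = m.L
    report = PhaseReport(phase="mvmr", counts=counts)
    ests = mvmr_ivw(m)
    for e in ests:
        e.label = significance_label(e.pvalue, max(cfg.n_exposures, m.K),
                                     cfg.n_outcomes, cfg.alpha)
    report.estimates.extend(ests)
    report.extra["conditional_f"] = {
        m.exposure_ids[k]: conditional_f(m, k) for k in range(m.K)}
    if ests[0].q_pvalue is not None and ests[0].q_pvalue < 0.05:
        lasso = mr_lasso(m)
        for e in lasso.estimates:
            e.label = significance_label(e.pvalue, max(cfg.n_exposures, m.K),
                                         cfg.n_outcomes, cfg.alpha)
        report.estimates.extend(lasso.estimates)
        report.extra["lasso_invalid"] = lasso.invalid
    return report


def run_drug_target(exposure: SummaryStats, outcome: SummaryStats,
                    ld: LDMatrix | None, cfg: AnalysisConfig,
                    region: GeneRegion, proxy: str = "LDL-C",
                    confounders: pd.DataFrame | None = None) -> PhaseReport:
    """Drug-target (cis) MR with the reciprocal-OR drug-scale convention.

    Instruments are restricted to ``region`` (±flank) before clumping at the
    drug r² threshold.  The report carries both the fitted per-SD OR and the
    drug-scale OR: the reciprocal for LDL-C-proxied targets, unchanged for
    HDL-C-proxied CETP.
    """
    region = GeneRegion(region.symbol, region.chrom, region.start, region.end,
                        flank_kb=cfg.drug_flank_kb)
    sel, counts = select_instruments(exposure, ld, cfg, confounders,
                                     region=region)
    if len(sel) == 0:
        raise RuntimeError(f"drug-target {region.symbol}: no cis instruments "
                           f"(counts: {counts})")
    report = _fit_phase(sel, outcome, cfg, f"drug:{region.symbol}", counts)
    inverted = not proxy.upper().startswith("HDL")
    report.extra["proxy"] = proxy
    report.extra["or_inverted_to_drug_scale"] = inverted
    report.extra["drug_scale_or"] = {
        e.method: drug_scale_or(e.or_, proxy=proxy) for e in report.estimates}
    return report


def run_mediation_phase(exposure_instruments: SummaryStats,
                        mediator: SummaryStats, outcome: SummaryStats,
                        cfg: AnalysisConfig,
                        ld: LDMatrix | None = None) -> PhaseReport:
    """Two-step mediation via three univariable MR fits."""
    res = run_mediation(exposure_instruments, mediator, outcome,
                        config={"p_threshold": cfg.p_threshold,
                                "f_min": cfg.f_min, "ld": ld,
                                "clump_r2": cfg.clump_r2,
                                "clump_window_kb": cfg.clump_window_kb,
                                "palindrome_policy": cfg.palindrome_policy})
    report = PhaseReport(phase="mediation")
    report.extra["mediation"] = res
    return report


def run_all(cfg: AnalysisConfig, data: dict | None = None,
            regions: dict[str, GeneRegion] | None = None) -> dict:
    """Execute every phase; per-phase failures are isolated.

    ``data`` may supply in-memory objects (keys ``exposure``, ``outcome``,
    ``mediator``, ``ld``, ``confounders``, ``mv_exposures``); otherwise the
    paths in ``cfg`` are loaded.  Returns {phase: PhaseReport | error str}
    and writes one forest TSV per phase plus a combined summary table under
    ``cfg.out_dir``.
    """
    data = dict(data or {})
    if "exposure" not in data and cfg.exposure_path:
        data["exposure"] = read_sumstats(cfg.exposure_path, cfg.exposure_dialect,
                                         trait_id="exposure")
    if "outcome" not in data and cfg.outcome_path:
        data["outcome"] = read_sumstats(cfg.outcome_path, cfg.outcome_dialect,
                                        trait_id="outcome", trait_unit="logOR")
    if "mediator" not in data and cfg.mediator_path:
        data["mediator"] = read_sumstats(cfg.mediator_path, trait_id="mediator")
    if "ld" not in data and cfg.ld_path:
        data["ld"] = LDMatrix.from_tsv(cfg.ld_path)
    if "confounders" not in data and cfg.confounder_path:
        data["confounders"] = pd.read_csv(cfg.confounder_path, sep="\t")

    exposure, outcome = data["exposure"], data["outcome"]
    ld = data.get("ld")
    confounders = data.get("confounders")
    regions = regions or {}

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, object] = {}

    def attempt(name, fn):
        try:
            reports[name] = fn()
        except Exception as exc:  # phase isolation: others still run
            log.warning("phase %s failed: %s", name, exc)
            reports[name] = f"failed: {exc}"

    attempt("tsmr", lambda: run_tsmr(exposure, outcome, ld, cfg, confounders))
    attempt("reverse", lambda: run_reverse(exposure, outcome, ld, cfg))
    mv_exposures = data.get("mv_exposures")
    if mv_exposures:
        attempt("mvmr", lambda: run_mvmr(mv_exposures, outcome, ld, cfg))
    for symbol, region in regions.items():
        attempt(f"drug:{symbol}",
                lambda r=region: run_drug_target(exposure, outcome, ld, cfg, r,
                                                 confounders=confounders))
    if data.get("mediator") is not None:
        sel, _ = select_instruments(exposure, ld, cfg, confounders)
        attempt("mediation",
                lambda: run_mediation_phase(sel, data["mediator"], outcome,
                                            cfg, ld))
    else:
        log.warning("mediator data missing; mediation phase skipped")

    summary_rows = []
    for name, rep in reports.items():
        if not isinstance(rep, PhaseReport):
            continue
        if rep.estimates:
            write_report(rep.estimates,
                         out_dir / f"{name.replace(':', '_')}.tsv")
        for e in rep.estimates:
            summary_rows.append({"phase": name, **e.as_dict()})
    if summary_rows:
        pd.DataFrame(summary_rows).to_csv(out_dir / "summary.tsv", sep="\t",
                                          index=False, float_format="%.6g")
    return reports
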