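"""Genetic instrument selection.

The selection chain for two-sample MR: genome-wide significance filtering
(p < 5e-8, relaxed to 5e-6 when too few variants survive), greedy LD
clumping (r² < 0.001 within a 10,000 kb window), instrument-strength
filtering (F = beta²/SE² > 10), restriction to a drug-target gene window
(±100 kb) for cis instruments, and removal of variants associated with
known confounders (p < 5e-8 in an annotation table standing in for a
PhenoScanner lookup).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import LDMatrix, SummaryStats

__all__ = [
    "GeneRegion",
    "DRUG_TARGET_REGIONS",
    "select_by_pvalue",
    "clump",
    "f_statistic",
    "filter_by_f",
    "restrict_to_region",
    "screen_confounders",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRegion:
    """A drug-target gene with a flanking window for cis-instrument selection."""

    symbol: str
    chrom: str
    start: int
    end: int
    flank_kb: int = 100

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.symbol}: start must not exceed end")
        if self.flank_kb < 0:
            raise ValueError(f"{self.symbol}: flank_kb must be >= 0")

    @property
    def window(self) -> tuple[int, int]:
        """Inclusive base-pair bounds of the region extended by the flank."""
        return self.start - self.flank_kb * 1000, self.end + self.flank_kb * 1000


#: Lipid-lowering drug-target genes (GRCh37 transcription bounds).
DRUG_TARGET_REGIONS: dict[str, GeneRegion] = {
    "HMGCR": GeneRegion("HMGCR", "5", 74632154, 74657929),
    "PCSK9": GeneRegion("PCSK9", "1", 55505221, 55530525),
    "CETP": GeneRegion("CETP", "16", 56995762, 57017757),
    "NPC1L1": GeneRegion("NPC1L1", "7", 44552134, 44580914),
}


def select_by_pvalue(ss: SummaryStats, threshold: float) -> SummaryStats:
    """Keep variants with association p strictly below ``threshold``."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    out = ss.replace(ss.df[ss.df["pvalue"] < threshold])
    if len(out) == 0:
        log.warning("select_by_pvalue: no variants pass p < %g for %s",
                    threshold, ss.trait_id)
    return out


def clump(candidates: SummaryStats, ld: LDMatrix, r2_max: float = 0.001,
          window_kb: float = 10_000) -> SummaryStats:
    """Greedy LD clumping of significance-filtered candidates.

    Candidates are visited in ascending p (ties broken by rsid); each is kept
    iff its r² with every already-kept variant on the same chromosome within
    ``window_kb`` kilobases is strictly below ``r2_max``.  The result is
    order-invariant in the input and a fixed point of re-clumping.
    """
    missing = [r for r in candidates.rsids if r not in ld]
    if missing:
        raise KeyError(f"candidates missing from LD matrix: {missing}")
    df = candidates.df.sort_values(["pvalue", "rsid"], kind="mergesort")
    kept: list[tuple[str, str, int]] = []  # (rsid, chrom, pos)
    keep_ids = []
    window_bp = window_kb * 1000
    for row in df.itertuples(index=False):
        ok = True
        for krsid, kchrom, kpos in kept:
            if str(row.chrom) != kchrom:
                continue
            if abs(int(row.pos) - kpos) > window_bp:
                continue
            if ld.pair_r2(row.rsid, krsid) >= r2_max:
                ok = False
                break
        if ok:
            kept.append((row.rsid, str(row.chrom), int(row.pos)))
            keep_ids.append(row.rsid)
    return candidates.subset(keep_ids)


def f_statistic(beta, se):
    """Single-instrument strength F = beta² / SE²."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    out = beta**2 / se**2
    return float(out) if out.ndim == 0 else out


def filter_by_f(ss: SummaryStats, min_f: float = 10.0) -> SummaryStats:
    """Keep instruments with F strictly greater than ``min_f``."""
    if len(ss) == 0:
        return ss
    f = f_statistic(ss.df["beta"].to_numpy(), ss.df["se"].to_numpy())
    return ss.replace(ss.df[f > min_f])


def restrict_to_region(ss: SummaryStats, region: GeneRegion) -> SummaryStats:
    """Keep variants inside the gene region extended by its flank (cis window)."""
    lo, hi = region.window
    df = ss.df
    keep = (df["chrom"].astype(str) == str(region.chrom)) & \
           (df["pos"] >= lo) & (df["pos"] <= hi)
    return ss.replace(df[keep])


def screen_confounders(ss: SummaryStats, annot: pd.DataFrame,
                       p_threshold: float = 5e-8):
    """Drop instruments associated with a known confounder.

    ``annot`` has columns (rsid, trait, pvalue) — a desk stand-in for a
    PhenoScanner query.  A variant is removed if any of its annotations has
    p strictly below ``p_threshold``.  Returns ``(kept, removal_log)`` where
    the log lists (rsid, trait, pvalue) for each removal.
    """
    if annot is None or len(annot) == 0:
        return ss, pd.DataFrame(columns=["rsid", "trait", "pvalue"])
    hits = annot[(annot["pvalue"] < p_threshold) & annot["rsid"].isin(ss.rsids)]
    removed = set(hits["rsid"])
    kept = ss.replace(ss.df[~ss.df["rsid"].isin(removed)])
    return kept, hits[["rsid", "trait", "pvalue"]].reset_index(drop=True)
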