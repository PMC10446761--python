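"""Allele harmonization between exposure instruments and outcome records.

Two-sample MR needs the exposure and outcome effects of every instrument
expressed per copy of the same allele.  Matching is by rsid; alleles are
reconciled by swap (negate the outcome beta) and/or strand complement.
Palindromic variants (A/T or C/G) cannot be resolved from alleles alone and
are dropped by default; an optional frequency-inference mode keeps them when
both effect-allele frequencies are clearly away from 0.5 and concordant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .sumstats import SummaryStats, SumstatsError

__all__ = ["HarmonizedRecord", "HarmonizedSet", "harmonize", "is_palindromic"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Effect-allele frequencies outside (EAF_AMBIGUOUS, 1-EAF_AMBIGUOUS) are
#: considered informative for palindromic-strand inference.
EAF_AMBIGUOUS = 0.3


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G variants (strand-ambiguous allele pairs)."""
    return _COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class HarmonizedRecord:
    """Exposure/outcome effect pair aligned to a common effect allele."""

    rsid: str
    beta_X: float
    se_X: float
    beta_Y: float
    se_Y: float
    aligned_allele: str

    def __post_init__(self) -> None:
        if not (self.se_X > 0 and self.se_Y > 0):
            raise ValueError(f"{self.rsid}: standard errors must be > 0")


@dataclass
class HarmonizedSet:
    """Harmonized instrument set with provenance accounting.

    ``provenance`` counts where every candidate instrument went:
    matched (kept as-is or after flips), palindromic-dropped, unmatched
    (absent from the outcome) or allele-incompatible.  The counts partition
    the candidates.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame  # rsid, beta_X, se_X, beta_Y, se_Y, aligned_allele
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[HarmonizedRecord]:
        return [HarmonizedRecord(**row) for row in self.df.to_dict("records")]

    def subset(self, rsids) -> "HarmonizedSet":
        keep = set(rsids)
        df = self.df[self.df["rsid"].isin(keep)].reset_index(drop=True)
        prov = dict(self.provenance)
        prov["n_matched"] = len(df)
        return HarmonizedSet(self.exposure_id, self.outcome_id, df, prov)


def _orient(exp_a1, exp_a2, out_a1, out_a2):
    """Classify outcome alleles relative to exposure alleles.

    Returns one of ``"same"``, ``"swap"``, ``"strand"``, ``"strand_swap"``
    or ``None`` (incompatible).
    """
    if (out_a1, out_a2) == (exp_a1, exp_a2):
        return "same"
    if (out_a1, out_a2) == (exp_a2, exp_a1):
        return "swap"
    c1, c2 = _COMPLEMENT[out_a1], _COMPLEMENT[out_a2]
    if (c1, c2) == (exp_a1, exp_a2):
        return "strand"
    if (c1, c2) == (exp_a2, exp_a1):
        return "strand_swap"
    return None


def harmonize(instruments: SummaryStats, outcome: SummaryStats,
              policy: str = "drop") -> HarmonizedSet:
    """Align exposure instruments and outcome records to a common allele.

    ``policy="drop"`` (default) removes every palindromic variant.
    ``policy="infer"`` keeps a palindromic variant when both EAFs are known,
    both lie outside [0.3, 0.7], and they agree on which allele is minor;
    discordant frequencies imply the outcome file reports the complementary
    strand, so the outcome beta is negated.
    """
    if policy not in ("drop", "infer"):
        raise ValueError(f"unknown palindrome policy {policy!r}")
    out_idx = {}
    for rec in outcome.df.itertuples(index=False):
        if rec.rsid in out_idx:
            raise SumstatsError(f"duplicate rsid in outcome: {rec.rsid}")
        out_idx[rec.rsid] = rec

    counts = dict(n_matched=0, n_flipped=0, n_strand_flipped=0,
                  n_palindromic_dropped=0, n_unmatched=0, n_incompatible=0)
    rows = []
    seen = set()
    for exp in instruments.df.itertuples(index=False):
        if exp.rsid in seen:
            raise SumstatsError(f"duplicate rsid in instruments: {exp.rsid}")
        seen.add(exp.rsid)
        out = out_idx.get(exp.rsid)
        if out is None:
            counts["n_unmatched"] += 1
            continue
        if is_palindromic(exp.effect_allele, exp.other_allele):
            keep, flip = _resolve_palindrome(exp, out, policy)
            if not keep:
                counts["n_palindromic_dropped"] += 1
                continue
            beta_y = -out.beta if flip else out.beta
        else:
            orient = _orient(exp.effect_allele, exp.other_allele,
                             out.effect_allele, out.other_allele)
            if orient is None:
                counts["n_incompatible"] += 1
                continue
            flip = orient in ("swap", "strand_swap")
            if orient in ("strand", "strand_swap"):
                counts["n_strand_flipped"] += 1
            if flip:
                counts["n_flipped"] += 1
            beta_y = -out.beta if flip else out.beta
        rows.append(dict(rsid=exp.rsid, beta_X=float(exp.beta), se_X=float(exp.se),
                         beta_Y=float(beta_y), se_Y=float(out.se),
                         aligned_allele=exp.effect_allele))
    counts["n_matched"] = len(rows)
    df = pd.DataFrame(rows, columns=["rsid", "beta_X", "se_X", "beta_Y",
                                     "se_Y", "aligned_allele"])
    return HarmonizedSet(exposure_id=instruments.trait_id,
                         outcome_id=outcome.trait_id, df=df, provenance=counts)


def _resolve_palindrome(exp, out, policy):
    """Decide whether to keep a palindromic variant and whether to flip beta_Y."""
    if policy == "drop":
        return False, False
    eaf_x, eaf_y = exp.eaf, out.eaf
    if pd.isna(eaf_x) or pd.isna(eaf_y):
        return False, False
    if not (_informative(eaf_x) and _informative(eaf_y)):
        return False, False
    # For a palindrome the listed allele order carries no strand information:
    # only frequency concordance can orient the pair.  Same side of 0.5 means
    # the outcome's effect allele is the exposure's effect allele; opposite
    # sides mean it is the other allele, so the outcome beta is negated.
    same_side = (eaf_x < 0.5) == (eaf_y < 0.5)
    return True, not same_side


def _informative(eaf: float) -> bool:
    return eaf < EAF_AMBIGUOUS or eaf > 1 - EAF_AMBIGUOUS
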