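"""GWAS summary statistics: data model, TSV I/O and scale conversions.

Summary statistics are per-variant association records (rsid, alleles,
effect-allele frequency, beta, SE, p, N).  Continuous traits are assumed to
be on the per-SD scale; binary traits (e.g. sepsis) on the log-odds scale.
Odds-ratio/confidence-interval presentations are converted to beta/SE on
load so every downstream estimator works on a single additive scale.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Z_95",
    "VariantAssociation",
    "SummaryStats",
    "LDMatrix",
    "LoadReport",
    "DIALECTS",
    "read_sumstats",
    "write_sumstats",
    "or_to_beta",
    "ci_to_se",
    "write_report",
    "read_report",
]

#: Normal quantile used for every 95% interval.  Fixed at six digits (rather
#: than the rounded 1.96) so p-values recomputed from printed CIs agree with
#: printed p-values at three decimals.
Z_95 = 1.959964

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column order of the internal frame and of written TSVs.
COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]


class SumstatsError(ValueError):
    """Malformed summary-statistics input (missing columns, duplicates...)."""


@dataclass(frozen=True)
class VariantAssociation:
    """A single variant's association with one trait."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _BASES or self.other_allele not in _BASES:
            raise SumstatsError(f"{self.rsid}: alleles must be single bases A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise SumstatsError(f"{self.rsid}: alleles must differ")
        if not self.se > 0:
            raise SumstatsError(f"{self.rsid}: se must be > 0")
        if not (0 < self.pvalue <= 1):
            raise SumstatsError(f"{self.rsid}: pvalue must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise SumstatsError(f"{self.rsid}: eaf must be in [0, 1]")

    @property
    def f_statistic(self) -> float:
        return self.beta**2 / self.se**2


@dataclass
class LoadReport:
    """Row accounting from :func:`read_sumstats`."""

    n_rows: int = 0
    n_kept: int = 0
    n_invalid: int = 0
    reasons: Counter = field(default_factory=Counter)


@dataclass
class SummaryStats:
    """One trait's GWAS summary statistics.

    ``df`` holds one row per variant with the canonical columns; rsids are
    unique.  ``trait_unit`` is ``"sd"`` for continuous traits and ``"logOR"``
    for binary ones — it is metadata, no rescaling is applied.
    """

    trait_id: str
    df: pd.DataFrame
    trait_unit: str = "sd"
    build: str = "GRCh37"
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        if self.trait_unit not in ("sd", "logOR"):
            raise SumstatsError(f"unknown trait_unit {self.trait_unit!r}")
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"missing columns: {missing}")
        dup = self.df["rsid"][self.df["rsid"].duplicated()].tolist()
        if dup:
            raise SumstatsError(f"duplicate rsids: {sorted(set(dup))}")
        self.df = self.df[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[VariantAssociation]:
        for row in self.df.itertuples(index=False):
            yield VariantAssociation(
                rsid=row.rsid, chrom=str(row.chrom), pos=int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                beta=float(row.beta), se=float(row.se), pvalue=float(row.pvalue),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                n=None if pd.isna(row.n) else float(row.n),
            )

    @property
    def rsids(self) -> list[str]:
        return self.df["rsid"].tolist()

    def subset(self, rsids: Iterable[str]) -> "SummaryStats":
        """Rows for ``rsids``, preserving the current row order."""
        keep = set(rsids)
        return self.replace(df=self.df[self.df["rsid"].isin(keep)])

    def replace(self, df: pd.DataFrame) -> "SummaryStats":
        return SummaryStats(trait_id=self.trait_id, df=df.reset_index(drop=True),
                            trait_unit=self.trait_unit, build=self.build)


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r²) matrix over an ordered rsid panel."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.rsids)
        if self.r2.shape != (n, n):
            raise SumstatsError("r2 matrix shape does not match rsid count")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise SumstatsError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise SumstatsError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise SumstatsError("r2 entries must lie in [0, 1]")
        self._index = {r: i for i, r in enumerate(self.rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def pair_r2(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(
            path, sep="\t", index_label="rsid")

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(rsids=list(df.index), r2=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# scale conversions

def or_to_beta(or_value):
    """Natural log of an odds ratio: the additive (log-odds) effect size."""
    arr = np.asarray(or_value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("odds ratio must be > 0")
    out = np.log(arr)
    return float(out) if np.isscalar(or_value) or arr.ndim == 0 else out


def ci_to_se(ci_low, ci_high, level: float = 0.95):
    """Standard error on the log scale recovered from an OR confidence interval.

    ``(ln(hi) - ln(lo)) / (2 z)`` with z the two-sided normal quantile for
    ``level`` (1.959964 at 95%).
    """
    lo = np.asarray(ci_low, dtype=float)
    hi = np.asarray(ci_high, dtype=float)
    if np.any(lo <= 0) or np.any(hi <= 0):
        raise ValueError("confidence bounds must be > 0")
    if np.any(lo > hi):
        raise ValueError("ci_low must not exceed ci_high")
    z = Z_95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2))
    out = (np.log(hi) - np.log(lo)) / (2 * z)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# file I/O

#: Named column dialects.  ``generic`` expects beta/se columns; ``or_ci``
#: expects OR and 95%-CI columns, converted on load via or_to_beta/ci_to_se.
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {
        "rsid": "rsid", "chrom": "chrom", "pos": "pos",
        "effect_allele": "effect_allele", "other_allele": "other_allele",
        "eaf": "eaf", "beta": "beta", "se": "se", "pvalue": "pvalue", "n": "n",
    },
    "or_ci": {
        "rsid": "rsid", "chrom": "chrom", "pos": "pos",
        "effect_allele": "effect_allele", "other_allele": "other_allele",
        "eaf": "eaf", "or": "or", "ci_low": "ci_low", "ci_high": "ci_high",
        "pvalue": "pvalue", "n": "n",
    },
}

_MANDATORY = ["rsid", "effect_allele", "other_allele", "pvalue"]


def read_sumstats(path, dialect: str | Mapping[str, str] = "generic",
                  trait_id: str | None = None, trait_unit: str = "sd",
                  build: str = "GRCh37") -> SummaryStats:
    """Read a TSV/CSV of summary statistics into a validated :class:`SummaryStats`.

    ``dialect`` maps canonical names to the file's column names, or names a
    shipped mapping (``"generic"``, ``"or_ci"``).  Rows violating record
    invariants (se ≤ 0, p outside (0,1], bad alleles) are dropped and counted
    in the attached :class:`LoadReport`; structural problems (missing
    mandatory columns, duplicate rsids) raise :class:`SumstatsError`.
    """
    mapping = dict(DIALECTS[dialect]) if isinstance(dialect, str) else dict(dialect)
    sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep)
    rename = {v: k for k, v in mapping.items() if v in raw.columns}
    df = raw.rename(columns=rename)

    has_or = "or" in df.columns and "ci_low" in df.columns and "ci_high" in df.columns
    needed = _MANDATORY + ([] if has_or else ["beta", "se"])
    for col in needed:
        if col not in df.columns:
            raise SumstatsError(f"mandatory column {col!r} missing from {path}")

    if has_or:
        bad = (df["or"] <= 0) | (df["ci_low"] <= 0) | (df["ci_high"] <= 0)
        df = df[~bad].copy()
        df["beta"] = np.log(df["or"].to_numpy(float))
        df["se"] = ci_to_se(df["ci_low"].to_numpy(float), df["ci_high"].to_numpy(float))
        n_or_bad = int(bad.sum())
    else:
        n_or_bad = 0

    for col in ("chrom", "pos", "eaf", "n"):
        if col not in df.columns:
            df[col] = "0" if col == "chrom" else np.nan
    df["chrom"] = df["chrom"].astype(str)

    report = LoadReport(n_rows=len(raw))
    report.reasons["bad_or_ci"] = n_or_bad
    ok_allele = (df["effect_allele"].isin(_BASES) & df["other_allele"].isin(_BASES)
                 & (df["effect_allele"] != df["other_allele"]))
    ok_se = pd.to_numeric(df["se"], errors="coerce") > 0
    ok_p = (pd.to_numeric(df["pvalue"], errors="coerce") > 0) & (df["pvalue"] <= 1)
    ok_eaf = df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))
    report.reasons.update({
        "bad_allele": int((~ok_allele).sum()),
        "bad_se": int((~ok_se).sum()),
        "bad_pvalue": int((~ok_p).sum()),
        "bad_eaf": int((~ok_eaf).sum()),
    })
    keep = ok_allele & ok_se & ok_p & ok_eaf
    df = df[keep].copy()
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").fillna(0).astype(int)
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    report.n_kept = len(df)
    report.n_invalid = report.n_rows - report.n_kept

    dup = df["rsid"][df["rsid"].duplicated()].tolist()
    if dup:
        raise SumstatsError(f"duplicate rsids in {path}: {sorted(set(dup))}")

    ss = SummaryStats(trait_id=trait_id or str(path), df=df[COLUMNS],
                      trait_unit=trait_unit, build=build)
    ss.load_report = report
    return ss


def write_sumstats(ss: SummaryStats, path) -> None:
    """Write a SummaryStats back to canonical-column TSV."""
    out = ss.df.copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# forest-table report

_REPORT_COLS = [
    "exposure", "outcome", "method", "k_snps", "beta", "se", "or", "ci_low",
    "ci_high", "pvalue", "q", "q_df", "q_pvalue",
    "egger_intercept", "egger_intercept_se", "egger_intercept_p", "label",
]


def write_report(estimates, path) -> None:
    """Write MR estimates as a forest-table TSV.

    One row per estimate; numeric cells carry six significant digits so a
    write→read round trip is lossless at that precision.  Fields an estimate
    does not have (e.g. Egger intercept columns for IVW rows) are left empty,
    not written as zeros.
    """
    if not estimates:
        raise ValueError("estimates must be non-empty")
    rows = []
    for est in estimates:
        d = est.as_dict() if hasattr(est, "as_dict") else dict(est)
        rows.append({c: d.get(c) for c in _REPORT_COLS})
    df = pd.DataFrame(rows, columns=_REPORT_COLS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
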