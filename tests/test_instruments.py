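"""Instrument-selection tests: thresholds, clumping, F filter, gene windows."""

import numpy as np
import pandas as pd
import pytest

from lipidmr.instruments import (DRUG_TARGET_REGIONS, GeneRegion, clump,
                                 f_statistic, filter_by_f, restrict_to_region,
                                 screen_confounders, select_by_pvalue)
from lipidmr.simulate import CausalModel, simulate_sumstats
from lipidmr.sumstats import LDMatrix

from conftest import make_sumstats


def ss_with_pvalues(pvals, **extra):
    return make_sumstats([dict(rsid=f"rs{i + 1}", beta=0.1, se=0.01,
                               pvalue=p, pos=1000 * (i + 1), **extra)
                          for i, p in enumerate(pvals)])


class TestPvalueAndF:
    def test_threshold_is_strict(self):
        ss = ss_with_pvalues([1e-9, 1e-7])
        assert len(select_by_pvalue(ss, 5e-8)) == 1
        assert len(select_by_pvalue(ss, 5e-6)) == 2
        assert len(select_by_pvalue(ss, 1e-12)) == 0

    def test_f_statistic_arithmetic(self):
        assert f_statistic(0.1, 0.01) == pytest.approx(100.0)
        assert f_statistic(0.0, 0.5) == 0.0
        assert f_statistic(0.031623, 0.01) == pytest.approx(10.0, rel=1e-4)
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)

    def test_filter_by_f_strictly_greater(self):
        # F values 4 (exactly the threshold), 1 and 9: only F > min_f survives
        ss = make_sumstats([
            dict(rsid="rs1", beta=2.0, se=1.0, pvalue=0.5),
            dict(rsid="rs2", beta=1.0, se=1.0, pvalue=0.5),
            dict(rsid="rs3", beta=3.0, se=1.0, pvalue=0.5),
        ])
        kept = filter_by_f(ss, 4.0)
        assert kept.rsids == ["rs3"]  # F exactly at the threshold is dropped

    def test_filter_by_f_empty_input(self):
        ss = ss_with_pvalues([])
        assert len(filter_by_f(ss)) == 0


class TestRegion:
    def test_cetp_flank_edges(self):
        region = DRUG_TARGET_REGIONS["CETP"]  # 56995762-57017757, flank 100kb
        ss = make_sumstats([
            dict(rsid="rs_in", chrom="16", pos=56895762, beta=0.1, se=0.01,
                 pvalue=1e-9),
            dict(rsid="rs_out", chrom="16", pos=56895761, beta=0.1, se=0.01,
                 pvalue=1e-9),
            dict(rsid="rs_chr", chrom="5", pos=57000000, beta=0.1, se=0.01,
                 pvalue=1e-9),
        ])
        kept = restrict_to_region(ss, region)
        assert kept.rsids == ["rs_in"]

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError):
            GeneRegion("X", "1", 100, 50)
        with pytest.raises(ValueError):
            GeneRegion("X", "1", 50, 100, flank_kb=-1)


class TestConfounderScreen:
    def test_strong_confounder_hit_removed(self):
        ss = ss_with_pvalues([1e-9, 1e-9, 1e-9])
        annot = pd.DataFrame({"rsid": ["rs1", "rs2"],
                              "trait": ["BMI", "diabetes"],
                              "pvalue": [1e-12, 1e-6]})
        kept, log = screen_confounders(ss, annot, 5e-8)
        assert kept.rsids == ["rs2", "rs3"]  # rs2's hit is above threshold
        assert list(log["rsid"]) == ["rs1"]
        assert list(log["trait"]) == ["BMI"]

    def test_empty_annotation_is_identity(self):
        ss = ss_with_pvalues([1e-9])
        kept, log = screen_confounders(ss, pd.DataFrame(
            columns=["rsid", "trait", "pvalue"]))
        assert kept.rsids == ss.rsids
        assert log.empty

    def test_commutes_with_f_filter(self):
        ss = make_sumstats([
            dict(rsid=f"rs{i}", beta=0.01 * i, se=0.01, pvalue=1e-9,
                 pos=1000 * i) for i in range(1, 8)])
        annot = pd.DataFrame({"rsid": ["rs3", "rs6"], "trait": ["BMI"] * 2,
                              "pvalue": [1e-10, 1e-10]})
        a = filter_by_f(screen_confounders(ss, annot)[0], 10)
        b = screen_confounders(filter_by_f(ss, 10), annot)[0]
        assert a.rsids == b.rsids


def clump_oracle(df, r2_lookup, r2_max, window_bp):
    """Independent clumping oracle: iterative survivor elimination.

    Repeatedly promote the remaining candidate with the smallest p (ties by
    rsid) and delete every remaining candidate correlated with it (r² ≥
    threshold) within the window on the same chromosome.
    """
    remaining = sorted(df.itertuples(index=False),
                       key=lambda r: (r.pvalue, r.rsid))
    kept = []
    while remaining:
        top = remaining.pop(0)
        kept.append(top.rsid)
        remaining = [r for r in remaining
                     if not (r.chrom == top.chrom
                             and abs(r.pos - top.pos) <= window_bp
                             and r2_lookup(top.rsid, r.rsid) >= r2_max)]
    return sorted(kept)


class TestClump:
    def make_ld(self, rsids, pairs):
        n = len(rsids)
        r2 = np.eye(n)
        idx = {r: i for i, r in enumerate(rsids)}
        for a, b, v in pairs:
            r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = v
        return LDMatrix(rsids=rsids, r2=r2)

    def test_correlated_pair_keeps_smaller_p(self):
        ss = ss_with_pvalues([1e-10, 1e-9])
        ld = self.make_ld(["rs1", "rs2"], [("rs1", "rs2", 0.5)])
        kept = clump(ss, ld, r2_max=0.001, window_kb=10_000)
        assert kept.rsids == ["rs1"]

    def test_partial_ld_structure(self):
        # r²(1,2) = 0.3, all other pairs 0; variant 1 has the smallest p
        ss = ss_with_pvalues([1e-12, 1e-10, 1e-9, 1e-8])
        ld = self.make_ld([f"rs{i}" for i in range(1, 5)],
                          [("rs1", "rs2", 0.3)])
        kept = clump(ss, ld, r2_max=0.001, window_kb=10_000)
        assert kept.rsids == ["rs1", "rs3", "rs4"]

    def test_window_never_spans_chromosomes(self):
        ss = make_sumstats([
            dict(rsid="rs1", chrom="1", pos=100, beta=0.1, se=0.01, pvalue=1e-10),
            dict(rsid="rs2", chrom="2", pos=100, beta=0.1, se=0.01, pvalue=1e-9),
        ])
        ld = self.make_ld(["rs1", "rs2"], [("rs1", "rs2", 0.99)])
        kept = clump(ss, ld, r2_max=0.001, window_kb=10_000)
        assert kept.rsids == ["rs1", "rs2"]

    def test_missing_candidate_names_rsid(self):
        ss = ss_with_pvalues([1e-9])
        ld = self.make_ld(["rsX"], [])
        with pytest.raises(KeyError, match="rs1"):
            clump(ss, ld)

    def test_order_invariance_and_fixed_point(self):
        rng = np.random.default_rng(7)
        n = 10
        rsids = [f"rs{i + 1}" for i in range(n)]
        r = rng.uniform(0, 1, (n, n))
        r2 = (r + r.T) / 2 * (rng.uniform(0, 1, (n, n)) < 0.5)
        r2 = np.triu(r2, 1) + np.triu(r2, 1).T + np.eye(n)
        ld = LDMatrix(rsids=rsids, r2=np.clip(r2, 0, 1))
        ss = ss_with_pvalues(list(rng.uniform(1e-12, 1e-6, n)))
        kept = clump(ss, ld, r2_max=0.1, window_kb=10_000)
        shuffled = ss.replace(ss.df.sample(frac=1, random_state=3))
        kept_shuf = clump(shuffled, ld, r2_max=0.1, window_kb=10_000)
        assert sorted(kept.rsids) == sorted(kept_shuf.rsids)
        again = clump(kept, ld, r2_max=0.1, window_kb=10_000)
        assert again.rsids == kept.rsids

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        rsids = [f"rs{i + 1}" for i in range(n)]
        a = rng.uniform(0, 1, (n, n))
        r2 = np.triu(a, 1) + np.triu(a, 1).T + np.eye(n)
        ld = LDMatrix(rsids=rsids, r2=r2)
        chroms = rng.choice(["1", "2"], n)
        rows = [dict(rsid=rsids[i], chrom=chroms[i],
                     pos=int(rng.integers(1, 5_000_000)),
                     beta=0.1, se=0.01, pvalue=float(rng.uniform(1e-12, 1e-6)))
                for i in range(n)]
        ss = make_sumstats(rows)
        r2_max = float(rng.choice([0.05, 0.3, 0.6]))
        window_kb = float(rng.choice([1, 1000, 10_000]))
        kept = clump(ss, ld, r2_max=r2_max, window_kb=window_kb)
        expected = clump_oracle(ss.df, ld.pair_r2, r2_max, window_kb * 1000)
        assert sorted(kept.rsids) == expected

    def test_planted_blocks_keep_one_variant_each(self):
        model = CausalModel(m_variants=30, ld_blocks=((5, 0.8), (5, 0.8),
                                                      (5, 0.8)),
                            exposure_effect_sd=0.05, seed=11)
        study = simulate_sumstats(model)
        sel = select_by_pvalue(study.exposure, 5e-6)
        kept = clump(sel, study.ld, r2_max=0.1, window_kb=10_000)
        blocks = study.truth.set_index("rsid")["block"]
        kept_blocks = [blocks[r] for r in kept.rsids]
        declared = set(study.truth.loc[study.truth["block"] >= 30, "block"])
        for b in declared:
            assert kept_blocks.count(b) <= 1
        # exhaustively check the kept set is pairwise below threshold
        for i, a in enumerate(kept.rsids):
            for b in kept.rsids[i + 1:]:
                assert study.ld.pair_r2(a, b) < 0.1
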