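"""Shared fixtures: small hand-built datasets and harmonized-set helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lipidmr.harmonize import HarmonizedSet
from lipidmr.sumstats import SummaryStats


def make_sumstats(rows, trait_id="trait", trait_unit="sd"):
    """Build a SummaryStats from dicts, filling boilerplate columns."""
    from lipidmr.sumstats import COLUMNS
    if not rows:
        return SummaryStats(trait_id=trait_id,
                            df=pd.DataFrame(columns=COLUMNS),
                            trait_unit=trait_unit)
    defaults = dict(chrom="1", pos=0, effect_allele="A", other_allele="G",
                    eaf=np.nan, n=np.nan)
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r.setdefault("pos", 0)
        r.update(row)
        r.setdefault("rsid", f"rs{i + 1}")
        full.append(r)
    df = pd.DataFrame(full)
    return SummaryStats(trait_id=trait_id, df=df, trait_unit=trait_unit)


def make_hset(beta_X, beta_Y, se_Y, se_X=None, rsids=None,
              exposure="exposure", outcome="outcome"):
    """Build a HarmonizedSet directly from effect arrays."""
    beta_X = np.asarray(beta_X, float)
    beta_Y = np.asarray(beta_Y, float)
    se_Y = np.broadcast_to(np.asarray(se_Y, float), beta_X.shape).copy()
    se_X = (np.broadcast_to(np.asarray(se_X, float), beta_X.shape).copy()
            if se_X is not None else np.full_like(beta_X, 0.01))
    rsids = rsids or [f"rs{i + 1}" for i in range(len(beta_X))]
    df = pd.DataFrame({"rsid": rsids, "beta_X": beta_X, "se_X": se_X,
                       "beta_Y": beta_Y, "se_Y": se_Y,
                       "aligned_allele": "A"})
    prov = dict(n_matched=len(df), n_flipped=0, n_strand_flipped=0,
                n_palindromic_dropped=0, n_unmatched=0, n_incompatible=0)
    return HarmonizedSet(exposure_id=exposure, outcome_id=outcome, df=df,
                         provenance=prov)


@pytest.fixture
def proportional_hset():
    """Exactly proportional effects: IVW beta = 0.2 with Q = 0."""
    return make_hset([0.1, 0.2, 0.3], [0.02, 0.04, 0.06], 0.1)


@pytest.fixture
def linear_hset():
    """Exact affine relation beta_Y = 0.05 + 0.2 beta_X, equal weights."""
    x = np.array([0.1, 0.2, 0.3, 0.4])
    return make_hset(x, 0.05 + 0.2 * x, 0.1)
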