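import numpy as np
import pytest

from mrsuite.instruments import HarmonizedData, HarmonizedPair
from mrsuite.summary_io import GwasRecord, GwasTable


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                beta=0.1, se=0.02, pval=1e-9, n=100_000):
    return GwasRecord(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                      other_allele=oa, eaf=eaf, beta=beta, se=se, pval=pval, n=n)


def make_harmonized(bx, sx, by, sy, ids=None):
    """HarmonizedData straight from effect arrays (test fixture factory)."""
    bx, sx, by, sy = map(np.atleast_1d, (bx, sx, by, sy))
    n = len(bx)
    ids = ids or [f"rs{i + 1}" for i in range(n)]
    pairs = [
        HarmonizedPair(snp_id=ids[i], beta_exp=float(bx[i]), se_exp=float(sx[i]),
                       beta_out=float(by[i]), se_out=float(sy[i]), eaf_exp=0.3)
        for i in range(n)
    ]
    return HarmonizedData(pairs=pairs, exposure_name="exp", outcome_name="out",
                          n_requested=n)


def random_harmonized(rng, n_snp, b=0.3):
    """Random well-behaved instance for oracle comparisons."""
    bx = rng.uniform(0.02, 0.08, n_snp) * rng.choice([-1, 1], n_snp)
    sx = rng.uniform(0.002, 0.006, n_snp)
    sy = rng.uniform(0.005, 0.02, n_snp)
    by = b * bx + rng.normal(0, sy)
    return make_harmonized(bx, sx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table():
    recs = [
        make_record("rs1", "1", 1_000_000, "A", "G", 0.3, 0.10, 0.02, 1e-10),
        make_record("rs2", "1", 3_000_000, "C", "T", 0.2, 0.08, 0.02, 1e-9),
        make_record("rs3", "2", 5_000_000, "G", "A", 0.4, -0.06, 0.015, 1e-12),
    ]
    return GwasTable(records=recs, trait_name="exposure", trait_type="continuous")
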