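import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from triplimeth.synthetic_data import duplication_plan_config, simulate_annotation

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_cx(rows):
    """Build a CX-report frame from (chrom, pos1, strand, meth, unmeth,
    context) tuples."""
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "count_methylated",
                 "count_unmethylated", "context"],
    )


def constant_cx(chrom, positions, level, coverage, context="CG", strand="+"):
    """CX frame with identical counts at every position (level exactly
    meth/coverage)."""
    meth = int(round(level * coverage))
    return make_cx([(chrom, int(p), strand, meth, coverage - meth, context)
                    for p in positions])


@pytest.fixture(scope="session")
def dup_genome():
    """The reference duplication plan: 100 singleton, 50 tandem-pair,
    50 proximal-pair, 50 dispersed-pair and 150 WGT genes (30 in 3-copy
    groups) on 9 chromosomes."""
    return simulate_annotation(duplication_plan_config(seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240711)
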