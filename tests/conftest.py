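import numpy as np
import pandas as pd
import pytest

from brainmr.instruments import SUMMARY_COLUMNS, SummaryStats
from brainmr.pipeline import demo_config, run_pipeline
from brainmr.simulate import simulate_reference_panel


def make_stats(trait, rows):
    """Build SummaryStats from (id, chrom, pos, ea, oa, beta, se, p) tuples."""
    return SummaryStats(trait, pd.DataFrame(rows, columns=SUMMARY_COLUMNS))


@pytest.fixture(scope="session")
def ld_block_panel():
    """One tightly correlated 10-variant block, 500 individuals."""
    return simulate_reference_panel(500, 10, [(10, 0.8)], seed=1)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demo pipeline run shared across test modules."""
    out = tmp_path_factory.mktemp("demo")
    summary = run_pipeline(demo_config(1), out)
    return out, summary
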