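import numpy as np
import pandas as pd
import pytest

import ccrcckit as ck


@pytest.fixture
def small_config():
    """A quick-to-generate cohort: 24 tumors, 6 normals, 800 genes."""
    return ck.SimulationConfig(
        n_tumor=24, n_normal=6, n_genes=800, n_class_genes=50, seed=42
    )


def _rec(**kw):
    base = dict(
        sample_id="S1",
        chrom="chr1",
        pos=100,
        ref="A",
        alt="T",
        filter_status="PASS",
        alt_depth=20,
        alt_rate=0.5,
        gene_symbol="VHL",
    )
    base.update(kw)
    return ck.VariantRecord(**base)


@pytest.fixture
def make_record():
    return _rec


@pytest.fixture
def hand_cascade_fixture():
    """Ten hand-built records tracing the cascade to counts [10, 7, 5, 4, 3].

    Two non-PASS and one poly-N indel fall at quality; two 1%-frequency
    records at population; one silent record at functional; one off-panel
    record at panel; three fully qualifying records survive.  One survivor
    also appears in its sample's matched normal.
    """
    records = [
        _rec(pos=1, filter_status="LowQual"),
        _rec(pos=2, filter_status="q10"),
        _rec(pos=3, is_indel=True, in_polyN_region=True, ref="A", alt="AT"),
        _rec(pos=4, pop_freq_1kg=0.01),
        _rec(pos=5, pop_freq_esp=0.01),
        _rec(pos=6, consequence="silent"),
        _rec(pos=7, gene_symbol="NOT_IN_PANEL"),
        _rec(pos=8),
        _rec(pos=9, gene_symbol="BAP1"),
        _rec(pos=10, gene_symbol="SETD2", sample_id="S2"),
    ]
    panel = ["VHL", "BAP1", "SETD2", "PBRM1"]
    normals = {"S1": [_rec(pos=9, gene_symbol="BAP1", sample_id="S1_N")]}
    return records, panel, normals


@pytest.fixture
def handworked_survival():
    """Six subjects; events at t=1,2,4,6 and censorings at t=3,5.

    Product-limit by hand: S(1)=5/6, S(2)=4/6, S(4)=4/6*2/3=4/9, S(6)=0.
    """
    data = pd.DataFrame(
        {"time_days": [1, 2, 3, 4, 5, 6], "event": [1, 1, 0, 1, 0, 1]},
        index=[f"P{i}" for i in range(6)],
    )
    expected_surv = {1: 5 / 6, 2: 4 / 6, 4: 4 / 9, 6: 0.0}
    return data, expected_surv
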