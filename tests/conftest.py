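import numpy as np
import pandas as pd
import pytest

from bscomp.io_formats import GenomeSequence, IntronRecord
from bscomp.splicing import CountMatrix


@pytest.fixture
def contrast_pair():
    """Two small contrast tables with one event per quadrant, boundary cases,
    and a pool of unchanged expressed controls."""
    rows_a, rows_b = [], []

    def add(eid, da, ma, db, mb, bm=500.0):
        rows_a.append((eid, "G" + eid, "AltEX", da, ma, bm))
        rows_b.append((eid, "G" + eid, "AltEX", db, mb, bm))

    add("q_uu", 20.0, 5.0, 15.0, 2.0)
    add("q_ud", 20.0, 5.0, -15.0, 2.0)
    add("q_du", -20.0, 5.0, 15.0, 2.0)
    add("q_dd", -20.0, 5.0, -15.0, 2.0)
    add("one_side", 20.0, 5.0, 3.0, 2.0)   # co-regulated via contrast A only
    add("boundary", 10.0, 5.0, 10.0, 5.0)  # |dpsi| not strictly > 10 in either
    add("mv_zero", 40.0, 0.0, 40.0, 5.0)   # mv_a == 0 blocks co-regulation
    add("weak", 5.0, 1.0, 6.0, 1.0)
    for i in range(20):
        add(f"ctrl{i}", 0.3, 0.0, -0.2, 0.0, bm=500.0)
    add("lowexpr", 0.1, 0.0, 0.1, 0.0, bm=50.0)
    cols = ["event_id", "gene_id", "event_type", "dpsi", "mv_dpsi95", "base_mean"]
    return pd.DataFrame(rows_a, columns=cols), pd.DataFrame(rows_b, columns=cols)


@pytest.fixture
def marker_genome():
    """A genome with a planted marker for window-extraction oracles."""
    seq = "A" * 30 + "ACTAAC" + "A" * 20
    return GenomeSequence({"chr1": seq}), IntronRecord("chr1", 0, 56, "+", "i1")


def make_count_matrix(u_ctrl, u_trt, s_ctrl, s_trt, intronless=None):
    """Build a one-gene CountMatrix from explicit per-sample counts."""
    n = len(u_ctrl)
    samples = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(len(u_trt))]
    groups = {s: ("control" if s.startswith("c") else "treatment") for s in samples}
    counts = pd.DataFrame(
        [list(u_ctrl) + list(u_trt), list(s_ctrl) + list(s_trt)],
        index=["g1_pre", "g1_m"],
        columns=samples,
        dtype=float,
    )
    meta = pd.DataFrame(
        {"tx_class": ["unspliced", "spliced"], "gene_id": ["g1", "g1"]},
        index=["g1_pre", "g1_m"],
    )
    if intronless is not None:
        for tid, row in intronless.items():
            counts.loc[tid] = row
            meta.loc[tid] = ["intronless", tid]
    return CountMatrix(counts=counts, meta=meta, sample_groups=groups)


@pytest.fixture
def nsc_table():
    return pd.DataFrame(
        {
            "protein_id": ["p1", "p2", "p3", "p4"],
            "NE": [4.0, 3.0, 0.0, 5.0],
            "WT": [10.0, 2.0, 6.0, np.nan],
            "upDEL": [2.0, 5.0, 6.0, 7.0],
            "dnDEL": [6.0, 1.0, 6.0, 7.0],
            "2xDEL": [2.0, 2.0, 6.0, 7.0],
            "APT": [2.0, 5.0, 1.0, 2.0],
            "eu2_member": [True, True, True, False],
        }
    )
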