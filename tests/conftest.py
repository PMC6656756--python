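import numpy as np
import pandas as pd
import pytest

from startrac import (
    ExpressionSpec,
    RepertoireSpec,
    TCRChain,
    simulate_expression,
    simulate_repertoire,
)


def mk_chain(
    cell="c1",
    chain_type="alpha",
    v="TRAV2",
    j="TRAJ4",
    nt="TGTGCCTTT",
    aa="CAF",
    productive=True,
    tpm=100.0,
):
    return TCRChain(
        cell_id=cell,
        chain_type=chain_type,
        v_segment=v,
        j_segment=j,
        cdr3_nt=nt,
        cdr3_aa=aa,
        productive=productive,
        abundance_tpm=tpm,
    )


@pytest.fixture(scope="session")
def small_repertoire():
    """~300-cell repertoire with expanded clones; no decoy chains."""
    spec = RepertoireSpec(
        seed=11,
        cluster_budgets={f"C{i}": 100 for i in range(1, 4)},
        clone_size_mean=3.0,
        decoy_chain_rate=0.0,
        secondary_chain_rate=0.0,
    )
    return simulate_repertoire(spec)


@pytest.fixture(scope="session")
def full_repertoire():
    """1000-cell repertoire with decoy/secondary chains and invariant cells."""
    spec = RepertoireSpec(
        seed=7,
        cluster_budgets={f"C{i:02d}": 200 for i in range(1, 6)},
        clone_size_mean=3.0,
    )
    return simulate_repertoire(spec)


@pytest.fixture(scope="session")
def expression_dataset(full_repertoire):
    cells, _, _ = full_repertoire
    spec = ExpressionSpec(seed=13)
    counts, model, truth = simulate_expression(spec, cells)
    return counts, model, truth
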