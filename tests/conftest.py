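import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pairrisk.containers import ExpressionMatrix
from pairrisk.signature import GenePair, PairSignature
from pairrisk.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def tied_survival():
    """20-subject censored fixture with tied event times."""
    rng = np.random.default_rng(7)
    times = np.round(rng.exponential(4, 20), 0) + 1.0
    events = rng.integers(0, 2, 20)
    events[:4] = 1
    z = rng.integers(0, 2, 20)
    z[:2] = 0
    z[2:4] = 1
    return times, events.astype(int), z.astype(int)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort simulated under the reference study conditions."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def four_pair_signature():
    """A k=4 signature over eight distinct genes."""
    return PairSignature(
        pairs=tuple(GenePair(f"U{i}", f"F{i}") for i in range(4)),
        name="synthetic-4-pair",
    )


def expr_from_array(arr, genes=None, samples=None) -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(values=pd.DataFrame(arr, index=genes, columns=samples))
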