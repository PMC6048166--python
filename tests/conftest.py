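import numpy as np
import pandas as pd
import pytest

from metscreen.barcodes import BarcodeLibrary
from metscreen.simulate import TINY, SimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def tiny_screen():
    """Small simulated screen shared across read-level tests."""
    return simulate_screen(TINY)


@pytest.fixture(scope="session")
def small_library():
    return BarcodeLibrary(
        orf_ids=["A", "B", "C"],
        barcodes=[
            "ACGTACGTACGTACGTACGTACGT",
            "TTTTCCCCGGGGAAAATTTTCCCC",
            "GACTGACTGACTGACTGACTGACT",
        ],
        length=24,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def expr_3pairs():
    """Three-pair expression matrix with hand-set log2 differences {1.0, 1.1, 0.9}
    for the first gene (reference columns all at log2 = 10)."""
    base = 10.0
    diffs = [1.0, 1.1, 0.9]
    ref = [2.0**base - 1.0] * 3
    test = [2.0 ** (base + d) - 1.0 for d in diffs]
    flat_ref = [2.0**8 - 1] * 3
    flat_test = [2.0**8 - 1] * 3
    mat = pd.DataFrame(
        [ref + test, flat_ref + flat_test],
        index=pd.Index(["g_shift", "g_flat"], name="gene_id"),
        columns=["r1", "r2", "r3", "t1", "t2", "t3"],
    )
    pairs = [("r1", "t1"), ("r2", "t2"), ("r3", "t3")]
    return mat, pairs
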