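import numpy as np
import pytest

import priorbn as pb


@pytest.fixture
def hmec_seq():
    """Observed six-gene trajectory 0,0,16,16,56,57."""
    return pb.datasets.hmec_sequence()


@pytest.fixture
def hmec_map():
    """Successor map of the published inferred network on its visited states."""
    return {0: 16, 16: 48, 48: 56, 56: 57, 57: 57}


def make_random_bn(n: int, k: int, seed: int) -> pb.BooleanNetwork:
    rng = np.random.default_rng(seed)
    wiring = pb.random_wiring(n, k, rng=rng)
    table = pb.TruthTable(rng.integers(0, 2, size=(n, 1 << k), dtype=np.uint8))
    return pb.BooleanNetwork(wiring, table)


@pytest.fixture
def random_bn3():
    return make_random_bn(3, 2, seed=42)


def identity_bn(n: int) -> pb.BooleanNetwork:
    """Each gene copies itself: successor(s) = s for every state."""
    wiring = pb.Wiring(n, 1, tuple((g,) for g in range(n)))
    table = pb.TruthTable(np.tile([0, 1], (n, 1)))
    return pb.BooleanNetwork(wiring, table)


def constant_bn(n: int, value: int = 0) -> pb.BooleanNetwork:
    """Every state maps to the all-`value` state."""
    wiring = pb.Wiring(n, 1, tuple((g,) for g in range(n)))
    table = pb.TruthTable(np.full((n, 2), value, dtype=np.uint8))
    return pb.BooleanNetwork(wiring, table)
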