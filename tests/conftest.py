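import numpy as np
import pytest

from tmcomplexity.machines import MachineSpec


@pytest.fixture(scope="session")
def spec22():
    return MachineSpec(2, 2)


@pytest.fixture(scope="session")
def spec10():
    return MachineSpec(10, 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent reference implementations used as oracles
# ---------------------------------------------------------------------------

def reference_simulate(matrix, iterations):
    """Dict-tape Turing machine stepper, independent of the compiled path.

    Returns (tape list over the read/write span, amplitude, usage list).
    """
    tape = {}
    pos, state = 0, 0
    lo = hi = 0
    usage = []
    a = matrix.spec.alphabet_size
    for _ in range(iterations):
        lo, hi = min(lo, pos), max(hi, pos)
        sym = tape.get(pos, 0)
        usage.append(state * a + sym)
        w, mv, ns = matrix.triple(state, sym)
        tape[pos] = w
        state = ns
        pos += {0: -1, 1: 0, 2: +1}[mv]
    span = [tape.get(i, 0) for i in range(lo, hi + 1)]
    return span, hi - lo + 1, usage


def reference_code_lengths(x, k, alphabet_size, alpha=1.0):
    """Dict-count adaptive order-k coder (pure Python)."""
    import math
    counts, totals = {}, {}
    out = []
    x = list(int(s) for s in x)
    for i, s in enumerate(x):
        if i < k:
            out.append(math.log2(alphabet_size))
            continue
        ctx = tuple(x[i - k:i])
        c = counts.get((ctx, s), 0)
        t = totals.get(ctx, 0)
        out.append(-math.log2((c + alpha) / (t + alpha * alphabet_size)))
        counts[(ctx, s)] = c + 1
        totals[ctx] = t + 1
    return out
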