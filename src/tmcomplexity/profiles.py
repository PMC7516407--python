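"""Normal (per-position) and dynamic (per-time) complexity profiles.

A normal profile maps a finished sequence position-by-position: value i is
the adaptive code length of symbol i given its predecessors, normalized by
log2 |A|, so the unnormalized profile sums exactly to the compressed size
C(x).  Spikes mark positions the model found surprising — pattern changes,
rewritten tape regions, rule-cycle switches.

A dynamic profile samples the best-order NC of the evolving tape at fixed
step intervals while a machine runs, tracing how statistical complexity
builds up or decays over execution time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .machines import RuleMatrix
from .markov import (DEFAULT_ALPHA, DEFAULT_ORDERS, NCResult, best_order_nc,
                     code_lengths, encode_sequence)


@dataclass(frozen=True)
class NormalProfile:
    """Per-position normalized complexity of a finished sequence."""

    values: np.ndarray
    order: int
    alphabet_size: int

    def total_bits(self) -> float:
        """C(x): the profile's sum un-normalized back to bits."""
        return float(self.values.sum() * np.log2(self.alphabet_size))

    def to_tsv(self) -> str:
        lines = ["position\tvalue"]
        lines += [f"{i}\t{v:.6f}" for i, v in enumerate(self.values)]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class DynamicProfile:
    """Best-order NC of a machine's tape sampled across execution time."""

    times: np.ndarray
    values: np.ndarray

    def to_tsv(self) -> str:
        lines = ["iteration\tnc"]
        lines += [f"{t}\t{v:.6f}" for t, v in zip(self.times, self.values)]
        return "\n".join(lines) + "\n"


def normal_profile(x, k: int | None = None, alphabet_size: int | None = None,
                   alpha: float = DEFAULT_ALPHA,
                   orders=DEFAULT_ORDERS) -> NormalProfile:
    """Causal per-position profile of x under an order-k model.

    With k omitted, the order is the best order selected on the full
    sequence (minimum NC over `orders`), so the profile decomposes the same
    quantity the global measure reports.
    """
    arr, a = encode_sequence(x, alphabet_size)
    if k is None:
        k = best_order_nc(arr, orders, a, alpha).best_order
    vals = code_lengths(arr, k, a, alpha) / np.log2(a)
    return NormalProfile(values=vals, order=int(k), alphabet_size=a)


def rule_usage_profile(rule_usage, num_cells: int,
                       orders=DEFAULT_ORDERS,
                       alpha: float = DEFAULT_ALPHA
                       ) -> tuple[NormalProfile, NCResult]:
    """Profile and best-order NC of a rule-usage index sequence.

    The alphabet is the machine's cell count #Q * #Sigma; compressible
    usage sequences reveal short rule cycles.
    """
    arr = np.asarray(rule_usage)
    if arr.size == 0:
        raise ValueError("empty rule-usage sequence")
    if int(arr.min()) < 0 or int(arr.max()) >= num_cells:
        raise ValueError("rule index outside [0, num_cells)")
    if num_cells < 2:
        raise ValueError("num_cells must be >= 2")
    res = best_order_nc(arr, orders, num_cells, alpha)
    prof = normal_profile(arr, res.best_order, num_cells, alpha)
    return prof, res


def dynamic_profile(m: RuleMatrix, max_iterations: int | None = None,
                    target_amplitude: int | None = None,
                    sample_interval: int = 100,
                    orders=DEFAULT_ORDERS,
                    alpha: float = DEFAULT_ALPHA) -> DynamicProfile:
    """Sample the best-order NC of the evolving tape while the machine runs.

    Simulation proceeds in bursts of `sample_interval` steps; after each
    burst the current written-span tape is scored from scratch with fresh
    models (the interior of the tape changes between samples, so counts
    cannot be carried over).  The run stops at `max_iterations` or as soon
    as the amplitude reaches `target_amplitude`, whichever comes first.
    """
    if sample_interval < 1:
        raise ValueError("sample_interval must be >= 1")
    if max_iterations is None and target_amplitude is None:
        raise ValueError("need max_iterations and/or target_amplitude")
    if max_iterations is None:
        # generous bound: amplitude grows at most one cell per step
        max_iterations = 1000 * int(target_amplitude)
    write, move, nstate = m._flat()
    a = m.spec.alphabet_size
    buf = np.zeros(2 * max_iterations + 1, dtype=np.int8)
    pos = max_iterations
    lo = hi = pos
    q = 0
    times, values = [], []
    t = 0
    while t < max_iterations:
        burst = min(sample_interval, max_iterations - t)
        pos, q, lo, hi = _kernels.simulate_steps(
            buf, pos, q, lo, hi, write, move, nstate, a, burst)
        t += burst
        tape = buf[lo:hi + 1].copy()
        times.append(t)
        values.append(best_order_nc(tape, orders, a, alpha).nc)
        if target_amplitude is not None and tape.size >= target_amplitude:
            break
    return DynamicProfile(times=np.asarray(times, dtype=np.int64),
                          values=np.asarray(values, dtype=np.float64))


def low_pass(values, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (length preserved).

    Near the edges the window shrinks to the available samples, so constant
    inputs pass through unchanged.  Window must be odd.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    v = np.asarray(values, dtype=np.float64)
    if window == 1 or v.size == 0:
        return v.copy()
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(v.size)
    starts = np.clip(idx - half, 0, v.size)
    ends = np.clip(idx + half + 1, 0, v.size)
    return (csum[ends] - csum[starts]) / (ends - starts)


def plot_profile(profile, path: str, title: str = "") -> None:
    """Render a profile to SVG/PNG (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    if isinstance(profile, DynamicProfile):
        ax.plot(profile.times, profile.values, lw=0.8)
        ax.set_xlabel("iteration")
        ax.set_ylabel("NC")
    else:
        ax.plot(profile.values, lw=0.8)
        ax.set_xlabel("position")
        ax.set_ylabel("normalized code length")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
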