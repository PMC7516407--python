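"""Machine-space sweeps: sequential enumeration and Monte-Carlo sampling.

A sweep runs every machine in an id range (or a uniform random sample of
the space) for a fixed number of iterations, scores each final tape with
the best-order adaptive Markov model, and collects one record per machine:
id, amplitude, compressed bits, NC, and the selected order.  Summaries use
population standard deviations (divide by n) — at sweep sizes of 10^4 and
up the sample/population distinction is far below the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .machines import MachineSpec, id_to_matrix, run_machine
from .markov import DEFAULT_ALPHA, DEFAULT_ORDERS, best_order_nc
from .profiles import rule_usage_profile

RECORD_COLUMNS = ("id", "amplitude", "bits", "nc", "best_k")

# chunk of machines processed per kernel call; also the TSV flush interval
_CHUNK = 1024


@dataclass(frozen=True)
class SweepSummary:
    """Mean/std aggregates of one sweep (population convention)."""

    count: int
    amplitude_mean: float
    amplitude_std: float
    nc_mean: float
    nc_std: float

    def to_tsv(self) -> str:
        return ("count\tmean_amplitude\tstd_amplitude\tmean_nc\tstd_nc\n"
                f"{self.count}\t{self.amplitude_mean:.6f}\t"
                f"{self.amplitude_std:.6f}\t{self.nc_mean:.6f}\t"
                f"{self.nc_std:.6f}\n")


def _orders_array(orders: Iterable[int]) -> np.ndarray:
    arr = np.asarray(sorted(set(int(k) for k in orders)), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("orders must be non-empty")
    return arr


def _frame(ids, amp, bits, nc_vals, best_k) -> pd.DataFrame:
    return pd.DataFrame({"id": ids, "amplitude": amp, "bits": bits,
                         "nc": nc_vals, "best_k": best_k})


def _append_tsv(df: pd.DataFrame, path: str, first: bool) -> None:
    df.to_csv(path, sep="\t", index=False, mode="w" if first else "a",
              header=first)


def sweep_sequential(spec: MachineSpec,
                     id_range: tuple[int, int] | None = None,
                     iterations: int = 50_000,
                     orders: Iterable[int] = DEFAULT_ORDERS,
                     alpha: float = DEFAULT_ALPHA,
                     out_path: str | None = None) -> pd.DataFrame:
    """Enumerate and score machines id_start..id_stop-1 in id order.

    Records stream to `out_path` (TSV) incrementally when given.  Ranges
    whose ids fit in int64 run through a fused compiled loop; larger spaces
    fall back to per-machine execution with exact ids.
    """
    total = spec.total_machines
    start, stop = id_range if id_range is not None else (0, total)
    if not (0 <= start <= stop <= total):
        raise ValueError(f"id range [{start}, {stop}) outside [0, {total})")
    ordarr = _orders_array(orders)
    chunks: list[pd.DataFrame] = []
    first = True
    if stop <= np.iinfo(np.int64).max:
        for lo in range(start, stop, _CHUNK):
            hi = min(lo + _CHUNK, stop)
            n = hi - lo
            amp = np.zeros(n, dtype=np.int64)
            bits = np.zeros(n, dtype=np.float64)
            bk = np.zeros(n, dtype=np.int64)
            _kernels.sweep_sequential_kernel(
                lo, hi, spec.num_states, spec.alphabet_size, iterations,
                ordarr, float(alpha), amp, bits, bk)
            nc_vals = bits / (amp * np.log2(spec.alphabet_size))
            df = _frame(np.arange(lo, hi, dtype=np.int64), amp, bits,
                        nc_vals, bk)
            if out_path:
                _append_tsv(df, out_path, first)
                first = False
            chunks.append(df)
    else:  # ids beyond int64: exact big-integer path
        rows = []
        for mid in range(start, stop):
            m = id_to_matrix(mid, spec)
            rec = run_machine(m, iterations)
            res = best_order_nc(rec.tape, ordarr, spec.alphabet_size, alpha)
            rows.append((mid, rec.amplitude, res.total_bits, res.nc,
                         res.best_order))
        df = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
        if out_path:
            _append_tsv(df, out_path, True)
        chunks.append(df)
    return pd.concat(chunks, ignore_index=True)


def sweep_monte_carlo(spec: MachineSpec, n_samples: int,
                      iterations: int = 50_000,
                      orders: Iterable[int] = DEFAULT_ORDERS,
                      alpha: float = DEFAULT_ALPHA,
                      seed: int | None = None,
                      out_path: str | None = None) -> pd.DataFrame:
    """Score `n_samples` machines drawn uniformly from the (#Q, #Sigma)
    space: every (write, move, next_state) component of every cell sampled
    independently.  The `id` column holds the sample index.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ordarr = _orders_array(orders)
    rng = np.random.default_rng(seed)
    q, a = spec.num_states, spec.alphabet_size
    ncells = spec.num_cells
    chunks: list[pd.DataFrame] = []
    first = True
    for lo in range(0, n_samples, _CHUNK):
        n = min(_CHUNK, n_samples - lo)
        triples = np.empty((n, ncells, 3), dtype=np.int8)
        triples[:, :, 0] = rng.integers(0, a, size=(n, ncells))
        triples[:, :, 1] = rng.integers(0, 3, size=(n, ncells))
        triples[:, :, 2] = rng.integers(0, q, size=(n, ncells))
        amp = np.zeros(n, dtype=np.int64)
        bits = np.zeros(n, dtype=np.float64)
        bk = np.zeros(n, dtype=np.int64)
        _kernels.sweep_sampled_kernel(triples, q, a, iterations, ordarr,
                                      float(alpha), amp, bits, bk)
        nc_vals = bits / (amp * np.log2(a))
        df = _frame(np.arange(lo, lo + n, dtype=np.int64), amp, bits,
                    nc_vals, bk)
        if out_path:
            _append_tsv(df, out_path, first)
            first = False
        chunks.append(df)
    return pd.concat(chunks, ignore_index=True)


def summarize(records: pd.DataFrame) -> SweepSummary:
    """Arithmetic means and population standard deviations of a sweep."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record set")
    amp = records["amplitude"].to_numpy(dtype=np.float64)
    ncv = records["nc"].to_numpy(dtype=np.float64)
    return SweepSummary(count=len(records),
                        amplitude_mean=float(amp.mean()),
                        amplitude_std=float(amp.std()),
                        nc_mean=float(ncv.mean()),
                        nc_std=float(ncv.std()))


def top_machines(records: pd.DataFrame, min_amplitude: int = 100,
                 top_n: int = 15) -> pd.DataFrame:
    """The `top_n` records with amplitude above `min_amplitude` and the
    highest NC; ties broken toward the smaller machine id."""
    kept = records[records["amplitude"] > min_amplitude]
    kept = kept.sort_values(["nc", "id"], ascending=[False, True],
                            kind="mergesort")
    return kept.head(top_n).reset_index(drop=True)


@dataclass(frozen=True)
class RegionComparison:
    """Inside-versus-outside aggregates for a union of id intervals."""

    inside: SweepSummary
    outside: SweepSummary
    inside_bits_mean: float
    outside_bits_mean: float
    # rule-usage aggregates (NaN when no re-simulation was requested)
    inside_rule_nc_mean: float = float("nan")
    outside_rule_nc_mean: float = float("nan")
    inside_rule_bits_mean: float = float("nan")
    outside_rule_bits_mean: float = float("nan")


def _interval_mask(ids: np.ndarray, intervals: Sequence[tuple[int, int]],
                   domain_stop: int) -> np.ndarray:
    prev_stop = None
    for start, stop in sorted(intervals):
        if not (0 <= start < stop <= domain_stop):
            raise ValueError(f"interval [{start}, {stop}) outside id domain")
        if prev_stop is not None and start < prev_stop:
            raise ValueError("overlapping id intervals")
        prev_stop = stop
    mask = np.zeros(ids.size, dtype=bool)
    for start, stop in intervals:
        mask |= (ids >= start) & (ids < stop)
    return mask


def _rule_usage_means(spec: MachineSpec, ids: np.ndarray, sample_size: int,
                      iterations: int, rng, orders, alpha):
    if ids.size == 0:
        raise ValueError("cannot sample rule usage from an empty side")
    take = min(sample_size, ids.size)
    chosen = rng.choice(ids, size=take, replace=False)
    ncs, bits = [], []
    for mid in chosen:
        m = id_to_matrix(int(mid), spec)
        rec = run_machine(m, iterations, record_usage=True)
        _, res = rule_usage_profile(rec.rule_usage, spec.num_cells, orders,
                                    alpha)
        ncs.append(res.nc)
        bits.append(res.total_bits)
    return float(np.mean(ncs)), float(np.mean(bits))


def region_stats(records: pd.DataFrame,
                 id_intervals: Sequence[tuple[int, int]],
                 spec: MachineSpec | None = None,
                 rule_sample_size: int | None = None,
                 rule_iterations: int = 1000,
                 seed: int | None = None,
                 orders: Iterable[int] = DEFAULT_ORDERS,
                 alpha: float = DEFAULT_ALPHA) -> RegionComparison:
    """Compare records inside a union of id intervals against the rest.

    Optionally re-simulates a seeded subsample from each side for
    `rule_iterations` steps to score the compressibility of the rule-usage
    sequences (requires `spec` and `rule_sample_size`).
    """
    ids = records["id"].to_numpy(dtype=np.int64)
    domain_stop = int(ids.max()) + 1 if spec is None else spec.total_machines
    mask = _interval_mask(ids, id_intervals, domain_stop)
    inside_df = records[mask]
    outside_df = records[~mask]
    if len(inside_df) == 0 or len(outside_df) == 0:
        raise ValueError("id intervals leave one side empty")
    result = {
        "inside": summarize(inside_df),
        "outside": summarize(outside_df),
        "inside_bits_mean": float(inside_df["bits"].mean()),
        "outside_bits_mean": float(outside_df["bits"].mean()),
    }
    if rule_sample_size:
        if spec is None:
            raise ValueError("rule-usage sampling needs the machine spec")
        rng = np.random.default_rng(seed)
        in_nc, in_bits = _rule_usage_means(
            spec, inside_df["id"].to_numpy(np.int64), rule_sample_size,
            rule_iterations, rng, orders, alpha)
        out_nc, out_bits = _rule_usage_means(
            spec, outside_df["id"].to_numpy(np.int64), rule_sample_size,
            rule_iterations, rng, orders, alpha)
        result.update(inside_rule_nc_mean=in_nc, outside_rule_nc_mean=out_nc,
                      inside_rule_bits_mean=in_bits,
                      outside_rule_bits_mean=out_bits)
    return RegionComparison(**result)


def partition_jobs(total: int, n_jobs: int) -> list[tuple[int, int]]:
    """Split [0, total) into n_jobs disjoint, exhaustive, near-equal
    contiguous ranges (earlier jobs take the remainder)."""
    if n_jobs < 1:
        raise ValueError("n_jobs must be >= 1")
    if total < 0:
        raise ValueError("total must be >= 0")
    base, rem = divmod(total, n_jobs)
    bounds = []
    start = 0
    for j in range(n_jobs):
        size = base + (1 if j < rem else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def read_records(path: str) -> pd.DataFrame:
    """Read a sweep record TSV (header required)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"record file lacks columns: {sorted(missing)}")
    return df


def write_records(records: pd.DataFrame, path: str) -> None:
    records.to_csv(path, sep="\t", index=False)
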