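"""Numba-compiled inner loops: tape simulation and adaptive context-model coding.

Everything here operates on flat integer arrays so the hot paths (full
machine-space sweeps) never touch Python objects.  Rule tables are passed as
three parallel arrays indexed by cell = state * alphabet_size + read_symbol.
"""

from __future__ import annotations

import numpy as np
from numba import njit, types
from numba.typed import Dict

# Dense count tables are used while |A|**k stays at or below this bound
# (4**9, the largest configuration the DNA alphabet needs); bigger
# context spaces fall back to hash-map counts.
DENSE_CONTEXT_LIMIT = 4 ** 9


@njit(cache=True)
def simulate(write, move, nstate, alphabet_size, iterations, record_usage):
    """Run one machine for `iterations` steps from a blank tape, state 0.

    The tape buffer is preallocated with 2*iterations + 1 cells centered at
    the origin, which is indistinguishable from an unbounded tape because the
    head moves at most one cell per step.  Returns (tape, amplitude, usage):
    the written-span tape left-to-right, the span size, and the per-step
    rule-cell index sequence (empty when record_usage is False).  The span
    covers the cells the head occupied when reading/writing; the cell it
    merely rests on after the final move is not part of the tape.
    """
    buf = np.zeros(2 * iterations + 1, dtype=np.int8)
    pos = iterations
    lo = pos
    hi = pos
    q = 0
    n_usage = iterations if record_usage else 0
    usage = np.empty(n_usage, dtype=np.int32)
    for t in range(iterations):
        if pos < lo:
            lo = pos
        elif pos > hi:
            hi = pos
        sym = buf[pos]
        cell = q * alphabet_size + sym
        if record_usage:
            usage[t] = cell
        buf[pos] = write[cell]
        mv = move[cell]
        q = nstate[cell]
        if mv == 0:
            pos -= 1
        elif mv == 2:
            pos += 1
    return buf[lo:hi + 1].copy(), hi - lo + 1, usage


@njit(cache=True)
def simulate_steps(buf, pos, q, lo, hi, write, move, nstate, alphabet_size,
                   nsteps):
    """Advance an in-flight simulation by `nsteps`, mutating `buf` in place.

    Returns the updated (pos, q, lo, hi) head/state/span registers so a
    caller can sample the evolving tape between bursts.
    """
    for t in range(nsteps):
        if pos < lo:
            lo = pos
        elif pos > hi:
            hi = pos
        sym = buf[pos]
        cell = q * alphabet_size + sym
        buf[pos] = write[cell]
        mv = move[cell]
        q = nstate[cell]
        if mv == 0:
            pos -= 1
        elif mv == 2:
            pos += 1
    return pos, q, lo, hi


@njit(cache=True)
def code_lengths_dense(x, k, alphabet_size, alpha):
    """Per-symbol adaptive code lengths (bits), dense count table.

    Positions with fewer than k predecessors cost log2|A| each; afterwards
    each symbol costs -log2 of its Laplace-smoothed conditional probability,
    and the (context, symbol) count is incremented.
    """
    n = x.size
    out = np.empty(n, dtype=np.float64)
    log_a = np.log2(np.float64(alphabet_size))
    kk = min(k, n)
    for i in range(kk):
        out[i] = log_a
    if n <= k:
        return out
    ncontexts = np.int64(alphabet_size) ** k
    counts = np.zeros((ncontexts, alphabet_size), dtype=np.float64)
    totals = np.zeros(ncontexts, dtype=np.float64)
    ctx = np.int64(0)
    for i in range(k):
        ctx = ctx * alphabet_size + x[i]
    denom_add = alpha * alphabet_size
    for i in range(k, n):
        s = x[i]
        p = (counts[ctx, s] + alpha) / (totals[ctx] + denom_add)
        out[i] = -np.log2(p)
        counts[ctx, s] += 1.0
        totals[ctx] += 1.0
        ctx = (ctx * alphabet_size + s) % ncontexts
    return out


@njit(cache=True)
def total_bits_dense(x, k, alphabet_size, alpha):
    """Sum of adaptive code lengths, dense table, no per-symbol output."""
    n = x.size
    log_a = np.log2(np.float64(alphabet_size))
    if n <= k:
        return n * log_a
    ncontexts = np.int64(alphabet_size) ** k
    counts = np.zeros((ncontexts, alphabet_size), dtype=np.float64)
    totals = np.zeros(ncontexts, dtype=np.float64)
    bits = k * log_a
    ctx = np.int64(0)
    for i in range(k):
        ctx = ctx * alphabet_size + x[i]
    denom_add = alpha * alphabet_size
    for i in range(k, n):
        s = x[i]
        p = (counts[ctx, s] + alpha) / (totals[ctx] + denom_add)
        bits -= np.log2(p)
        counts[ctx, s] += 1.0
        totals[ctx] += 1.0
        ctx = (ctx * alphabet_size + s) % ncontexts
    return bits


@njit(cache=True)
def code_lengths_sparse(x, k, alphabet_size, alpha):
    """Per-symbol adaptive code lengths with hash-map counts.

    Used when |A|**k exceeds the dense bound (e.g. rule-usage alphabets of
    20 cells at order 9).  Context ids fit in int64 for every supported
    configuration.
    """
    n = x.size
    out = np.empty(n, dtype=np.float64)
    log_a = np.log2(np.float64(alphabet_size))
    kk = min(k, n)
    for i in range(kk):
        out[i] = log_a
    if n <= k:
        return out
    ncontexts = np.int64(alphabet_size) ** k
    counts = Dict.empty(key_type=types.int64, value_type=types.float64)
    totals = Dict.empty(key_type=types.int64, value_type=types.float64)
    ctx = np.int64(0)
    for i in range(k):
        ctx = ctx * alphabet_size + x[i]
    denom_add = alpha * alphabet_size
    for i in range(k, n):
        s = x[i]
        key = ctx * alphabet_size + s
        c = counts.get(key, 0.0)
        t = totals.get(ctx, 0.0)
        p = (c + alpha) / (t + denom_add)
        out[i] = -np.log2(p)
        counts[key] = c + 1.0
        totals[ctx] = t + 1.0
        ctx = (ctx * alphabet_size + s) % ncontexts
    return out


@njit(cache=True)
def best_order_bits(x, orders, alphabet_size, alpha):
    """Minimum total bits over candidate orders (dense tables only).

    Orders are scanned in the given sequence with strictly-smaller
    acceptance, so with an ascending order list ties resolve to the
    smallest k.  Returns (bits, order).
    """
    best_bits = np.inf
    best_k = orders[0]
    for j in range(orders.size):
        k = orders[j]
        b = total_bits_dense(x, k, alphabet_size, alpha)
        if b < best_bits:
            best_bits = b
            best_k = k
    return best_bits, best_k


@njit(cache=True)
def decode_rules(machine_id, num_states, alphabet_size, write, move, nstate):
    """Fill rule arrays from a mixed-radix machine id (int64 range only).

    Digit layout per cell: write * (3 * #Q) + move * #Q + next_state, cells
    row-major over (state, read symbol) with the last cell least significant.
    """
    ncells = num_states * alphabet_size
    radix = 3 * alphabet_size * num_states
    rem = machine_id
    for c in range(ncells - 1, -1, -1):
        d = rem % radix
        rem //= radix
        write[c] = d // (3 * num_states)
        r = d % (3 * num_states)
        move[c] = r // num_states
        nstate[c] = r % num_states
    return rem


@njit(cache=True)
def sweep_sequential_kernel(id_start, id_stop, num_states, alphabet_size,
                            iterations, orders, alpha,
                            out_amp, out_bits, out_k):
    """Fused enumerate/simulate/score loop over a contiguous id range."""
    ncells = num_states * alphabet_size
    write = np.empty(ncells, dtype=np.int8)
    move = np.empty(ncells, dtype=np.int8)
    nstate = np.empty(ncells, dtype=np.int8)
    log_a = np.log2(np.float64(alphabet_size))
    for idx in range(id_stop - id_start):
        decode_rules(id_start + idx, num_states, alphabet_size,
                     write, move, nstate)
        tape, amp, _ = simulate(write, move, nstate, alphabet_size,
                                iterations, False)
        bits, bk = best_order_bits(tape, orders, alphabet_size, alpha)
        out_amp[idx] = amp
        out_bits[idx] = bits
        out_k[idx] = bk
    return log_a


@njit(cache=True)
def sweep_sampled_kernel(triples, num_states, alphabet_size, iterations,
                         orders, alpha, out_amp, out_bits, out_k):
    """Simulate and score a batch of pre-drawn rule tables.

    `triples` has shape (n_machines, n_cells, 3) with columns
    (write, move, next_state).
    """
    n = triples.shape[0]
    for idx in range(n):
        write = np.ascontiguousarray(triples[idx, :, 0])
        move = np.ascontiguousarray(triples[idx, :, 1])
        nstate = np.ascontiguousarray(triples[idx, :, 2])
        tape, amp, _ = simulate(write, move, nstate, alphabet_size,
                                iterations, False)
        bits, bk = best_order_bits(tape, orders, alphabet_size, alpha)
        out_amp[idx] = amp
        out_bits[idx] = bits
        out_k[idx] = bk
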