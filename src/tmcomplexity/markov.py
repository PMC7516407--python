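"""Normalized Compression with adaptive finite-context (Markov) models.

An order-k model predicts each symbol from its k predecessors using
Laplace-smoothed counts, P(s | ctx) = (n(ctx, s) + alpha) / (n(ctx) +
alpha |A|), updated online in a single left-to-right pass.  The per-symbol
code length is -log2 P, their sum is the compressed size C(x), and the
Normalized Compression is

    NC(x) = C(x) / (|x| * log2 |A|),

close to 1 for incompressible sequences and near 0 for trivially regular
ones.  The first k symbols, which lack a full context, are charged the
uniform cost log2 |A| each.  The best-order variant scores a sequence with
each order in a candidate set (default {2..9}) independently and keeps the
minimum, breaking ties toward the smallest order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import _kernels

DEFAULT_ORDERS: tuple[int, ...] = tuple(range(2, 10))
DEFAULT_ALPHA = 1.0

_DNA_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class NCResult:
    """Compressed size and Normalized Compression of one sequence."""

    total_bits: float
    nc: float
    best_order: int
    length: int
    alphabet_size: int

    def tsv_row(self) -> str:
        return (f"{self.length}\t{self.best_order}\t"
                f"{self.total_bits:.6f}\t{self.nc:.6f}")


def encode_sequence(x, alphabet_size: int | None = None) -> tuple[np.ndarray, int]:
    """Coerce a raw symbol string, DNA string, or integer sequence to an
    int8 symbol array, returning (symbols, alphabet_size).

    Digit strings map '0'..'9' to 0..9; other strings are read as DNA with
    A,C,G,T -> 0..3 (case-insensitive).  If alphabet_size is omitted it is
    inferred as max(symbol) + 1 (at least 2).
    """
    if isinstance(x, str):
        if len(x) == 0:
            raise ValueError("empty sequence")
        if all(c.isdigit() for c in x):
            arr = np.frombuffer(x.encode(), dtype=np.uint8) - ord("0")
            arr = arr.astype(np.int8)
            inferred = max(2, int(arr.max()) + 1)
        else:
            up = x.upper()
            try:
                arr = np.array([_DNA_CODE[c] for c in up], dtype=np.int8)
            except KeyError as e:
                raise ValueError(f"unsupported symbol {e.args[0]!r}") from None
            inferred = 4
    else:
        arr = np.asarray(x)
        if arr.size == 0:
            raise ValueError("empty sequence")
        arr = arr.astype(np.int8)
        inferred = max(2, int(arr.max()) + 1)
    a = inferred if alphabet_size is None else int(alphabet_size)
    if a < 2:
        raise ValueError("alphabet_size must be >= 2")
    if int(arr.min()) < 0 or int(arr.max()) >= a:
        raise ValueError("symbol outside [0, alphabet_size)")
    return arr, a


def _use_dense(alphabet_size: int, k: int) -> bool:
    return alphabet_size ** k <= _kernels.DENSE_CONTEXT_LIMIT


def code_lengths(x, k: int, alphabet_size: int | None = None,
                 alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Per-symbol adaptive code lengths in bits (one pass, counts updated
    after each prediction)."""
    if k < 0:
        raise ValueError("order k must be >= 0")
    if alpha <= 0:
        raise ValueError("smoothing alpha must be > 0")
    arr, a = encode_sequence(x, alphabet_size)
    if _use_dense(a, k):
        return _kernels.code_lengths_dense(arr, k, a, float(alpha))
    return _kernels.code_lengths_sparse(arr, k, a, float(alpha))


def total_bits(x, k: int, alphabet_size: int | None = None,
               alpha: float = DEFAULT_ALPHA) -> float:
    """Compressed size C(x) in bits: the sum of the per-symbol code lengths."""
    if k < 0:
        raise ValueError("order k must be >= 0")
    if alpha <= 0:
        raise ValueError("smoothing alpha must be > 0")
    arr, a = encode_sequence(x, alphabet_size)
    if _use_dense(a, k):
        return float(_kernels.total_bits_dense(arr, k, a, float(alpha)))
    return float(np.sum(_kernels.code_lengths_sparse(arr, k, a, float(alpha))))


def nc(x, k: int, alphabet_size: int | None = None,
       alpha: float = DEFAULT_ALPHA) -> NCResult:
    """Normalized Compression of x under a single order-k model."""
    arr, a = encode_sequence(x, alphabet_size)
    bits = total_bits(arr, k, a, alpha)
    return NCResult(total_bits=bits,
                    nc=bits / (arr.size * np.log2(a)),
                    best_order=k, length=arr.size, alphabet_size=a)


def best_order_nc(x, orders: Iterable[int] = DEFAULT_ORDERS,
                  alphabet_size: int | None = None,
                  alpha: float = DEFAULT_ALPHA) -> NCResult:
    """NC under the best order in `orders` (minimum NC, ties to smallest k).

    Each order is scored with a fresh model; nothing is shared across
    orders.
    """
    order_list = sorted(set(int(k) for k in orders))
    if not order_list:
        raise ValueError("orders must be non-empty")
    if any(k < 0 for k in order_list):
        raise ValueError("orders must be >= 0")
    if alpha <= 0:
        raise ValueError("smoothing alpha must be > 0")
    arr, a = encode_sequence(x, alphabet_size)
    if all(_use_dense(a, k) for k in order_list):
        bits, best_k = _kernels.best_order_bits(
            arr, np.asarray(order_list, dtype=np.int64), a, float(alpha))
        bits, best_k = float(bits), int(best_k)
    else:
        best_k, bits = order_list[0], np.inf
        for k in order_list:
            b = total_bits(arr, k, a, alpha)
            if b < bits:
                bits, best_k = b, k
    return NCResult(total_bits=bits,
                    nc=bits / (arr.size * np.log2(a)),
                    best_order=best_k, length=arr.size, alphabet_size=a)


def results_to_tsv(results: Sequence[NCResult]) -> str:
    """Render NCResult rows as a TSV table (length, best_k, bits, nc)."""
    lines = ["length\tbest_k\tbits\tnc"]
    lines += [r.tsv_row() for r in results]
    return "\n".join(lines) + "\n"
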