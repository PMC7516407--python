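"""Robustness assessment of the NC measure, plus synthetic fixtures.

The protocol: take a sequence, sweep a grid of per-symbol substitution
probabilities crossed with block-permutation granularities, and record the
best-order NC at every grid point as a heat map.  On low-complexity input
(a step string of 500 zeros then 500 ones) uniform random substitutions
and finer permutations should push NC up; on high-complexity DNA,
substitutions fixed to a single nucleotide should pull NC down.  Both
directions together show the measure is sensitive to, yet not destabilized
by, edits and rearrangements.

Also houses the synthetic generators: the step string and a seeded order-k
Markov DNA simulator whose `sharpness` dial spans near-uniform (NC ~ 1) to
deterministic/periodic (NC ~ 0) sequences, standing in for downloaded
genomes when only the complexity regime matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .markov import DEFAULT_ALPHA, DEFAULT_ORDERS, best_order_nc

_DNA = "ACGT"
_DNA_CODE = {c: i for i, c in enumerate(_DNA)}


def synth_step_string(n0: int = 500, n1: int = 500) -> np.ndarray:
    """`n0` zeros followed by `n1` ones (binary alphabet)."""
    if n0 < 0 or n1 < 0 or n0 + n1 == 0:
        raise ValueError("need a non-empty string")
    return np.concatenate([np.zeros(n0, np.int8), np.ones(n1, np.int8)])


def substitute(x, p: float, mode: str = "uniform",
               target: int | str | None = None,
               alphabet_size: int | None = None, seed=None) -> np.ndarray:
    """Independently substitute each position with probability `p`.

    uniform mode draws the replacement uniformly from the whole alphabet
    (it may equal the original symbol); fixed mode always writes `target`.
    Length is preserved.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("substitution probability must be in [0, 1]")
    arr = np.asarray(x, dtype=np.int8).copy()
    a = (int(arr.max()) + 1 if alphabet_size is None
         else int(alphabet_size))
    a = max(a, 2)
    rng = np.random.default_rng(seed)
    hit = rng.random(arr.size) < p
    if mode == "uniform":
        arr[hit] = rng.integers(0, a, size=int(hit.sum()), dtype=np.int8)
    elif mode == "fixed":
        if target is None:
            raise ValueError("fixed-symbol substitution needs a target")
        t = _DNA_CODE[target.upper()] if isinstance(target, str) else int(target)
        if not 0 <= t < a:
            raise ValueError("target symbol outside alphabet")
        arr[hit] = t
    else:
        raise ValueError(f"unknown substitution mode {mode!r}")
    return arr


def permute_blocks(x, n_blocks: int, seed=None) -> np.ndarray:
    """Cut x into `n_blocks` contiguous near-equal blocks (sizes differ by
    at most one, longer blocks first) and shuffle their order uniformly.
    The symbol multiset is preserved."""
    arr = np.asarray(x, dtype=np.int8)
    if not 1 <= n_blocks <= arr.size:
        raise ValueError("n_blocks must be in [1, len(x)]")
    base, rem = divmod(arr.size, n_blocks)
    sizes = [base + 1] * rem + [base] * (n_blocks - rem)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_blocks)
    return np.concatenate([arr[bounds[b]:bounds[b + 1]] for b in order])


@dataclass(frozen=True)
class PerturbationGrid:
    """The (substitution probability) x (block count) assessment grid."""

    substitution_probabilities: tuple[float, ...] = tuple(
        round(0.05 * i, 2) for i in range(21))
    block_counts: tuple[int, ...] = tuple(2 ** i for i in range(10))
    substitution_mode: str = "uniform"
    target_symbol: int | str | None = "A"

    def __post_init__(self) -> None:
        probs = self.substitution_probabilities
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if list(probs) != sorted(probs):
            raise ValueError("probabilities must be sorted ascending")
        if any(b < 1 for b in self.block_counts):
            raise ValueError("block counts must be positive")
        if self.substitution_mode not in ("uniform", "fixed"):
            raise ValueError("mode must be 'uniform' or 'fixed'")


@dataclass(frozen=True)
class HeatMap:
    """Best-order NC at every grid point, plus the order that won."""

    substitution_probabilities: tuple[float, ...]
    block_counts: tuple[int, ...]
    values: np.ndarray       # shape (n_probs, n_blocks)
    best_orders: np.ndarray  # same shape, int

    def to_tsv(self) -> str:
        header = "p\\blocks\t" + "\t".join(str(b) for b in self.block_counts)
        lines = [header]
        for i, p in enumerate(self.substitution_probabilities):
            row = "\t".join(f"{v:.6f}" for v in self.values[i])
            lines.append(f"{p}\t{row}")
        return "\n".join(lines) + "\n"


def heatmap(x, grid: PerturbationGrid | None = None,
            orders: Iterable[int] = DEFAULT_ORDERS,
            alphabet_size: int | None = None,
            alpha: float = DEFAULT_ALPHA, seed: int = 0) -> HeatMap:
    """Best-order NC of substitute-then-permute perturbations of x.

    Substitution is applied first, then block permutation.  Each grid cell
    draws from its own generator seeded by (master seed, probability index,
    block index), so any cell can be recomputed in isolation.
    """
    grid = grid or PerturbationGrid()
    arr = np.asarray(x, dtype=np.int8)
    a = int(arr.max()) + 1 if alphabet_size is None else int(alphabet_size)
    a = max(a, 2)
    if max(grid.block_counts) > arr.size:
        raise ValueError("block count exceeds sequence length")
    nP, nB = len(grid.substitution_probabilities), len(grid.block_counts)
    values = np.zeros((nP, nB))
    korders = np.zeros((nP, nB), dtype=np.int64)
    for i, p in enumerate(grid.substitution_probabilities):
        for j, nb in enumerate(grid.block_counts):
            sub_seed = np.random.SeedSequence([int(seed), i, j, 0])
            perm_seed = np.random.SeedSequence([int(seed), i, j, 1])
            y = substitute(arr, p, grid.substitution_mode,
                           grid.target_symbol, a, seed=sub_seed)
            y = permute_blocks(y, nb, seed=perm_seed)
            res = best_order_nc(y, orders, a, alpha)
            values[i, j] = res.nc
            korders[i, j] = res.best_order
    return HeatMap(tuple(grid.substitution_probabilities),
                   tuple(grid.block_counts), values, korders)


# ---------------------------------------------------------------------------
# FASTA plumbing
# ---------------------------------------------------------------------------

def read_fasta(path, ambiguity: str = "reject",
               seed=None) -> list[tuple[str, np.ndarray]]:
    """Read FASTA records as (header, int8 array) with A,C,G,T -> 0..3.

    Case-insensitive.  Non-ACGT IUPAC letters either abort the parse
    (ambiguity='reject') or are resolved to uniform random bases
    (ambiguity='random', reproducible via seed).
    """
    if ambiguity not in ("reject", "random"):
        raise ValueError("ambiguity must be 'reject' or 'random'")
    rng = np.random.default_rng(seed)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence in record {rec.id!r}")
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        coded = np.full(arr.size, -1, dtype=np.int8)
        for base, code in _DNA_CODE.items():
            coded[arr == ord(base)] = code
        unknown = coded < 0
        if unknown.any():
            bad = set(chr(c) for c in arr[unknown])
            if not bad <= set("RYSWKMBDHVN"):
                raise ValueError(
                    f"non-IUPAC characters {sorted(bad)} in {rec.id!r}")
            if ambiguity == "reject":
                raise ValueError(
                    f"ambiguity codes {sorted(bad)} in {rec.id!r}")
            coded[unknown] = rng.integers(0, 4, size=int(unknown.sum()),
                                          dtype=np.int8)
        out.append((rec.description, coded))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(path, records: Sequence[tuple[str, np.ndarray]],
                width: int = 70) -> None:
    """Write (header, int8 array) records back to FASTA (0..3 -> A,C,G,T)."""
    with open(path, "w") as fh:
        for header, arr in records:
            fh.write(f">{header}\n")
            seq = "".join(_DNA[int(s)] for s in np.asarray(arr))
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def synth_dna(length: int, order: int = 2, seed=None,
              sharpness: float = 0.0) -> np.ndarray:
    """Simulate DNA from a seeded order-k Markov chain.

    `sharpness` interpolates the per-context transition rows between the
    uniform distribution (0.0: i.i.d.-like, NC near 1) and a deterministic
    map to one context-specific base (1.0: eventually periodic, NC near 0).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= sharpness <= 1.0:
        raise ValueError("sharpness must be in [0, 1]")
    if order < 1:
        raise ValueError("order must be >= 1")
    rng = np.random.default_rng(seed)
    ncontexts = 4 ** order
    peaks = rng.integers(0, 4, size=ncontexts)
    rows = np.full((ncontexts, 4), (1.0 - sharpness) / 4)
    rows[np.arange(ncontexts), peaks] += sharpness
    cdf = np.cumsum(rows, axis=1)
    out = np.empty(length, dtype=np.int8)
    u = rng.random(length)
    ctx = 0
    warm = min(order, length)
    draws = rng.integers(0, 4, size=warm)
    for i in range(warm):
        out[i] = draws[i]
        ctx = (ctx * 4 + int(draws[i])) % ncontexts
    for i in range(warm, length):
        s = int(np.searchsorted(cdf[ctx], u[i], side="right"))
        s = min(s, 3)
        out[i] = s
        ctx = (ctx * 4 + s) % ncontexts
    return out
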