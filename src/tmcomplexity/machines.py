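"""Constrained Turing machines: representation, enumeration, simulation.

The machines studied here are deliberately minimal: #Q internal states, a
tape alphabet of #Sigma symbols shared with the input alphabet, blank = 0,
initial state 0, no accepting states, and a transition table delta that maps
every (state, read symbol) pair to a (write symbol, head move, next state)
triple with moves in {0: left, 1: stay, 2: right}.  A run is halted only by
an external iteration bound, so every machine produces a tape.

The machine space for a (#Q, #Sigma) pair has (3 * #Sigma * #Q)**(#Sigma * #Q)
members ("TNTM"), which is placed in a total order: each cell contributes one
mixed-radix digit write * (3 * #Q) + move * #Q + next_state, cells taken
row-major over (state, read symbol) with the last cell least significant.
The all-(0,0,0) table is machine 0 and the all-(#Sigma-1, 2, #Q-1) table is
machine TNTM - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

MOVE_LEFT, MOVE_STAY, MOVE_RIGHT = 0, 1, 2


@dataclass(frozen=True)
class MachineSpec:
    """State and alphabet cardinality of a machine family."""

    num_states: int
    alphabet_size: int

    def __post_init__(self) -> None:
        if self.num_states < 1:
            raise ValueError("num_states must be >= 1")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")

    @property
    def num_cells(self) -> int:
        return self.num_states * self.alphabet_size

    @property
    def cell_radix(self) -> int:
        """Number of distinct triples a single cell can hold."""
        return 3 * self.alphabet_size * self.num_states

    @property
    def total_machines(self) -> int:
        """TNTM = (3 #Sigma #Q)**(#Sigma #Q), exact (Python int)."""
        return self.cell_radix ** self.num_cells


@dataclass(frozen=True)
class RuleMatrix:
    """A machine's entire description: one (write, move, next_state) triple
    per (state, read symbol) cell, stored as an int8 array of shape
    (#Q, #Sigma, 3)."""

    spec: MachineSpec
    cells: np.ndarray

    def __post_init__(self) -> None:
        q, a = self.spec.num_states, self.spec.alphabet_size
        c = np.asarray(self.cells, dtype=np.int8)
        if c.shape != (q, a, 3):
            raise ValueError(f"cells must have shape {(q, a, 3)}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("negative rule component")
        if (c[:, :, 0] >= a).any():
            raise ValueError("write symbol out of range")
        if (c[:, :, 1] > 2).any():
            raise ValueError("move must be 0 (left), 1 (stay) or 2 (right)")
        if (c[:, :, 2] >= q).any():
            raise ValueError("next state out of range")
        c.flags.writeable = False
        object.__setattr__(self, "cells", c)

    # -- flat views used by the simulation kernels ------------------------
    def _flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        flat = self.cells.reshape(self.spec.num_cells, 3)
        return (np.ascontiguousarray(flat[:, 0]),
                np.ascontiguousarray(flat[:, 1]),
                np.ascontiguousarray(flat[:, 2]))

    def triple(self, state: int, read_symbol: int) -> tuple[int, int, int]:
        w, m, s = self.cells[state, read_symbol]
        return int(w), int(m), int(s)

    def __eq__(self, other) -> bool:
        return (isinstance(other, RuleMatrix) and self.spec == other.spec
                and np.array_equal(self.cells, other.cells))

    def __hash__(self) -> int:
        return hash((self.spec, self.cells.tobytes()))


@dataclass
class SimulationRecord:
    """Outcome of one bounded run: the visited-span tape (left cell first),
    its amplitude (span size), and the per-step rule-cell index sequence
    (state * #Sigma + read symbol) when usage recording was requested."""

    tape: np.ndarray
    amplitude: int
    rule_usage: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))

    def tape_string(self) -> str:
        """The tape as a compact digit string, e.g. '00110'."""
        return "".join(str(int(s)) for s in self.tape)

    def tape_fasta(self, name: str = "tape") -> str:
        """Single-record FASTA with the digit string as sequence."""
        seq = self.tape_string()
        lines = [f">{name}"]
        lines += [seq[i:i + 70] for i in range(0, len(seq), 70)]
        return "\n".join(lines) + "\n"


def matrix_to_id(m: RuleMatrix) -> int:
    """Rank of a rule matrix in the total enumeration order (exact int)."""
    spec = m.spec
    q = spec.num_states
    mid = 0
    for state in range(q):
        for sym in range(spec.alphabet_size):
            w, mv, ns = m.triple(state, sym)
            digit = w * (3 * q) + mv * q + ns
            mid = mid * spec.cell_radix + digit
    return mid


def id_to_matrix(machine_id: int, spec: MachineSpec) -> RuleMatrix:
    """Inverse of :func:`matrix_to_id`."""
    if not 0 <= machine_id < spec.total_machines:
        raise ValueError(
            f"machine id {machine_id} outside [0, {spec.total_machines})")
    q, a = spec.num_states, spec.alphabet_size
    cells = np.zeros((q, a, 3), dtype=np.int8)
    rem = machine_id
    for state in range(q - 1, -1, -1):
        for sym in range(a - 1, -1, -1):
            digit = rem % spec.cell_radix
            rem //= spec.cell_radix
            cells[state, sym, 0] = digit // (3 * q)
            r = digit % (3 * q)
            cells[state, sym, 1] = r // q
            cells[state, sym, 2] = r % q
    return RuleMatrix(spec, cells)


def next_matrix(m: RuleMatrix) -> RuleMatrix:
    """Successor in the enumeration order; the last machine wraps to tm0."""
    nxt = (matrix_to_id(m) + 1) % m.spec.total_machines
    return id_to_matrix(nxt, m.spec)


def tm0(spec: MachineSpec) -> RuleMatrix:
    """The first machine: every cell (0, 0, 0)."""
    return RuleMatrix(spec, np.zeros((spec.num_states, spec.alphabet_size, 3),
                                     dtype=np.int8))


def random_matrix(spec: MachineSpec, rng) -> RuleMatrix:
    """Draw each cell's (write, move, next_state) independently uniformly."""
    rng = np.random.default_rng(rng)
    q, a = spec.num_states, spec.alphabet_size
    cells = np.empty((q, a, 3), dtype=np.int8)
    cells[:, :, 0] = rng.integers(0, a, size=(q, a))
    cells[:, :, 1] = rng.integers(0, 3, size=(q, a))
    cells[:, :, 2] = rng.integers(0, q, size=(q, a))
    return RuleMatrix(spec, cells)


def run_machine(m: RuleMatrix, iterations: int,
                record_usage: bool = False) -> SimulationRecord:
    """Execute exactly `iterations` steps from a blank tape in state 0.

    The tape is unbounded in both directions (blank = symbol 0); the
    returned tape covers exactly the span of cells the head read and
    rewrote.  The cell the head merely rests on after its final move is
    not counted in the amplitude.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    write, move, nstate = m._flat()
    tape, amp, usage = _kernels.simulate(
        write, move, nstate, m.spec.alphabet_size, iterations, record_usage)
    return SimulationRecord(tape=tape, amplitude=int(amp), rule_usage=usage)


# ---------------------------------------------------------------------------
# one-line text serialization
# ---------------------------------------------------------------------------

def machine_to_text(m: RuleMatrix, dialect: str = "id") -> str:
    """Serialize as '#Q #Sigma id' or as an explicit row-major triple list
    '#Q #Sigma w,m,s;w,m,s;...'."""
    spec = m.spec
    if dialect == "id":
        return f"{spec.num_states} {spec.alphabet_size} {matrix_to_id(m)}"
    if dialect == "triples":
        flat = m.cells.reshape(spec.num_cells, 3)
        body = ";".join(",".join(str(int(v)) for v in t) for t in flat)
        return f"{spec.num_states} {spec.alphabet_size} {body}"
    raise ValueError(f"unknown dialect {dialect!r}")


def machine_from_text(line: str) -> RuleMatrix:
    """Parse either serialization dialect produced by machine_to_text."""
    parts = line.split()
    if len(parts) != 3:
        raise ValueError(f"expected '#Q #Sigma payload', got {line!r}")
    q, a, payload = int(parts[0]), int(parts[1]), parts[2]
    spec = MachineSpec(q, a)
    if ";" in payload or "," in payload:
        triples = [tuple(int(v) for v in t.split(","))
                   for t in payload.split(";")]
        if len(triples) != spec.num_cells:
            raise ValueError(
                f"expected {spec.num_cells} triples, got {len(triples)}")
        cells = np.array(triples, dtype=np.int8).reshape(q, a, 3)
        return RuleMatrix(spec, cells)
    return id_to_matrix(int(payload), spec)
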