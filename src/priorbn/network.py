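"""Boolean network representation and state-space analysis.

A Boolean network on ``n`` genes assigns each gene a Boolean update
function of ``k`` regulators.  All genes update synchronously and
deterministically, so the network defines a functional graph (a
self-map) on the ``2**n`` network states.  This module holds the core
containers (:class:`Wiring`, :class:`TruthTable`,
:class:`BooleanNetwork`) and exhaustive state-space operations:
state-transition-graph construction, attractor/basin decomposition and
the coherency robustness measure.

State encoding convention
-------------------------
A network state is a length-``n`` bit vector or, equivalently, its
decimal encoding with the *first-listed gene as the most significant
bit*.  The same convention applies inside truth tables: the
first-listed regulator of a gene is the most significant bit of the
table row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "STATE_CAP",
    "Wiring",
    "TruthTable",
    "BooleanNetwork",
    "AttractorDecomposition",
    "encode_state",
    "decode_state",
    "trajectory",
    "build_stg",
    "find_attractors",
    "coherency",
]

#: Largest ``n`` for which exhaustive 2**n state-space operations run
#: by default.  Exhaustive operations accept an explicit override.
STATE_CAP = 20


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def _check_cap(n: int, cap: int | None = None) -> None:
    cap = STATE_CAP if cap is None else cap
    if n > cap:
        raise ValidationError(
            f"exhaustive operation over 2**{n} states exceeds the cap of "
            f"2**{cap}; pass an explicit cap to override if you mean it"
        )


def encode_state(bits: Sequence[int]) -> int:
    """Encode a bit vector as its decimal state, first gene = MSB.

    >>> encode_state([0, 1, 0, 0, 0, 0])
    16
    """
    value = 0
    for b in bits:
        if b not in (0, 1):
            raise ValidationError(f"non-binary entry {b!r} in state vector")
        value = (value << 1) | int(b)
    return value


def decode_state(state: int, n: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_state` for a width-``n`` state."""
    if not 0 <= state < (1 << n):
        raise ValidationError(f"state {state} out of range for n={n}")
    return tuple((state >> (n - 1 - i)) & 1 for i in range(n))


def state_bit(state: int, gene: int, n: int) -> int:
    """Bit of ``gene`` (index from the MSB end) in decimal ``state``."""
    return (state >> (n - 1 - gene)) & 1


@dataclass(frozen=True)
class Wiring:
    """Regulator assignment: each gene has an ordered list of k regulators.

    Parameters
    ----------
    n : int
        Number of genes.
    k : int
        In-degree (regulators per gene); uniform across genes.
    regulators : sequence of sequences of int
        ``regulators[g]`` lists gene ``g``'s k regulator indices in MSB
        order for the truth-table row encoding.
    fixed_mask : sequence of sequences of bool, optional
        ``fixed_mask[g][j]`` is True when slot ``j`` of gene ``g`` came
        from prior knowledge and must not be resampled.  Defaults to all
        fixed.
    """

    n: int
    k: int
    regulators: tuple[tuple[int, ...], ...]
    fixed_mask: tuple[tuple[bool, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        if not (1 <= self.k <= self.n):
            raise ValidationError(f"need 1 <= k <= n, got n={self.n}, k={self.k}")
        regs = tuple(tuple(int(r) for r in row) for row in self.regulators)
        object.__setattr__(self, "regulators", regs)
        if len(regs) != self.n:
            raise ValidationError(f"expected {self.n} regulator lists, got {len(regs)}")
        for g, row in enumerate(regs):
            if len(row) != self.k:
                raise ValidationError(f"gene {g}: expected {self.k} regulators, got {len(row)}")
            if len(set(row)) != len(row):
                raise ValidationError(f"gene {g}: duplicate regulators {row}")
            for r in row:
                if not 0 <= r < self.n:
                    raise ValidationError(f"gene {g}: regulator index {r} out of range")
        if not self.fixed_mask:
            mask = tuple(tuple(True for _ in range(self.k)) for _ in range(self.n))
        else:
            mask = tuple(tuple(bool(b) for b in row) for row in self.fixed_mask)
            if len(mask) != self.n or any(len(row) != self.k for row in mask):
                raise ValidationError("fixed_mask shape must match regulators")
        object.__setattr__(self, "fixed_mask", mask)

    @property
    def has_free_slots(self) -> bool:
        return any(not b for row in self.fixed_mask for b in row)

    def row_index(self, gene: int, state: int) -> int:
        """Truth-table row of ``gene`` given decimal network ``state``."""
        row = 0
        for r in self.regulators[gene]:
            row = (row << 1) | state_bit(state, r, self.n)
        return row


@dataclass(frozen=True)
class TruthTable:
    """Per-gene output columns: ``outputs[g][row]`` is gene g's next bit.

    ``outputs`` has shape (n, 2**k); the row index encodes the
    regulator bits with the first-listed regulator as MSB.
    """

    outputs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.outputs, dtype=np.uint8)
        if arr.ndim != 2:
            raise ValidationError("truth table must be a 2-D (n x 2**k) array")
        m = arr.shape[1]
        if m < 1 or (m & (m - 1)) != 0:
            raise ValidationError(f"row count {m} is not a power of two")
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("truth-table entries must be 0/1")
        object.__setattr__(self, "outputs", arr)

    @property
    def n(self) -> int:
        return self.outputs.shape[0]

    @property
    def k(self) -> int:
        return int(self.outputs.shape[1]).bit_length() - 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TruthTable):
            return NotImplemented
        return self.outputs.shape == other.outputs.shape and bool(
            (self.outputs == other.outputs).all()
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(self.outputs.tobytes())


@dataclass(frozen=True)
class BooleanNetwork:
    """A wiring plus truth table; a deterministic self-map on 2**n states."""

    wiring: Wiring
    table: TruthTable
    gene_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.table.n != self.wiring.n or self.table.k != self.wiring.k:
            raise ValidationError(
                f"table shape {self.table.outputs.shape} inconsistent with "
                f"wiring n={self.wiring.n}, k={self.wiring.k}"
            )
        if self.gene_names is not None:
            names = tuple(str(s) for s in self.gene_names)
            if len(names) != self.wiring.n:
                raise ValidationError("gene_names length must equal n")
            object.__setattr__(self, "gene_names", names)

    @property
    def n(self) -> int:
        return self.wiring.n

    def successor(self, state: int) -> int:
        """Next network state under the synchronous update."""
        n = self.n
        if not 0 <= state < (1 << n):
            raise ValidationError(f"state {state} out of range for n={n}")
        nxt = 0
        for g in range(n):
            row = self.wiring.row_index(g, state)
            nxt |= int(self.table.outputs[g, row]) << (n - 1 - g)
        return nxt

    def successor_map(self, cap: int | None = None) -> np.ndarray:
        """Vector of successors for every state 0..2**n-1 (vectorised)."""
        n, k = self.wiring.n, self.wiring.k
        _check_cap(n, cap)
        states = np.arange(1 << n, dtype=np.int64)
        nxt = np.zeros_like(states)
        for g in range(n):
            rows = np.zeros_like(states)
            for r in self.wiring.regulators[g]:
                rows = (rows << 1) | ((states >> (n - 1 - r)) & 1)
            bits = self.table.outputs[g][rows].astype(np.int64)
            nxt |= bits << (n - 1 - g)
        return nxt

    def __eq__(self, other: object) -> bool:
        """Equality of the induced successor maps (not of the encoding)."""
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        if self.n != other.n:
            return False
        return bool((self.successor_map() == other.successor_map()).all())

    def __hash__(self) -> int:
        return hash((self.n, self.successor_map().tobytes()))


SuccessorLike = BooleanNetwork | Mapping[int, int] | Callable[[int], int | None]


def successor_fn(bn: SuccessorLike) -> Callable[[int], int | None]:
    """Adapt a BooleanNetwork, dict or callable to a successor function.

    Partial mappings return ``None`` for states with no recorded
    successor; trajectory walks stop there.
    """
    if isinstance(bn, BooleanNetwork):
        return bn.successor
    if isinstance(bn, Mapping):
        return lambda s: bn.get(s)
    return bn


def trajectory(bn: SuccessorLike, s0: int) -> list[int]:
    """Distinct-state trajectory from ``s0``.

    Iterates the successor map, stopping immediately before the first
    state that already occurred, so every listed state is distinct.  The
    successor of the last listed state is the entry point of the cycle
    reached (or ``None`` for a partial map that dead-ends).
    """
    succ = successor_fn(bn)
    seen: set[int] = set()
    seq: list[int] = []
    s: int | None = s0
    while s is not None and s not in seen:
        seen.add(s)
        seq.append(s)
        s = succ(s)
    return seq


def build_stg(bn: BooleanNetwork, cap: int | None = None) -> list[tuple[int, int]]:
    """State transition graph as an edge list over all 2**n states."""
    succ = bn.successor_map(cap=cap)
    return [(int(s), int(t)) for s, t in enumerate(succ)]


@dataclass(frozen=True)
class AttractorDecomposition:
    """Attractor cycles and the basin partition of the state space.

    ``attractors`` lists each cycle once, rotated to start at its
    smallest decimal state, sorted by that smallest state.  ``basin_of``
    maps every state to the index of its attractor.
    """

    attractors: tuple[tuple[int, ...], ...]
    basin_of: np.ndarray
    basin_sizes: tuple[int, ...]

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)

    def attractor_of(self, state: int) -> tuple[int, ...]:
        return self.attractors[int(self.basin_of[state])]


def _decompose_successor_array(succ: np.ndarray) -> AttractorDecomposition:
    N = len(succ)
    basin_of = np.full(N, -1, dtype=np.int64)
    color = np.zeros(N, dtype=np.int8)  # 0 white, 1 on current walk, 2 done
    raw_cycles: list[list[int]] = []
    for s0 in range(N):
        if color[s0] != 0:
            continue
        path: list[int] = []
        u = s0
        while color[u] == 0:
            color[u] = 1
            path.append(u)
            u = int(succ[u])
        if color[u] == 1:  # new cycle closed inside this walk
            cycle = path[path.index(u):]
            aidx = len(raw_cycles)
            raw_cycles.append(cycle)
            for v in cycle:
                basin_of[v] = aidx
        aidx = int(basin_of[u])
        for v in path:
            if basin_of[v] == -1:
                basin_of[v] = aidx
            color[v] = 2
    # canonical order: rotate each cycle to smallest state, sort cycles
    canon = []
    for cycle in raw_cycles:
        j = cycle.index(min(cycle))
        canon.append(tuple(cycle[j:] + cycle[:j]))
    order = sorted(range(len(canon)), key=lambda i: canon[i][0])
    remap = {old: new for new, old in enumerate(order)}
    basin_of = np.array([remap[int(a)] for a in basin_of], dtype=np.int64)
    attractors = tuple(canon[i] for i in order)
    sizes = tuple(int(c) for c in np.bincount(basin_of, minlength=len(attractors)))
    return AttractorDecomposition(attractors, basin_of, sizes)


def find_attractors(bn: BooleanNetwork, cap: int | None = None) -> AttractorDecomposition:
    """Exhaustive attractor cycles and basins of attraction."""
    return _decompose_successor_array(bn.successor_map(cap=cap))


def coherency(
    bn: BooleanNetwork,
    decomposition: AttractorDecomposition | None = None,
    cap: int | None = None,
) -> tuple[float, np.ndarray]:
    """Network coherency and per-state values.

    The coherency of a state s is the fraction of its n Hamming-distance-1
    neighbours that lie in the same basin of attraction as s; the network
    coherency is the mean over all 2**n states.  It measures robustness
    of the basin structure to single-gene perturbations: 1 means no
    single-bit flip ever changes the eventual attractor.
    """
    n = bn.n
    dec = decomposition if decomposition is not None else find_attractors(bn, cap=cap)
    basin = dec.basin_of
    states = np.arange(1 << n)
    phi = np.zeros(1 << n, dtype=float)
    for j in range(n):
        phi += basin[states ^ (1 << j)] == basin[states]
    phi /= n
    return float(phi.mean()), phi
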