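"""Boolean-network inference from short transition sequences.

The inference problem: given one or more observed state-transition
sequences and a wiring constraint (k regulators per gene, some slots
pinned by prior pathway knowledge, others free), fill in each gene's
truth table so the resulting deterministic Boolean network reproduces as
many of the observed transitions as possible.

The procedure:

1. fix a candidate wiring (prior slots kept, free slots sampled);
2. tally, for every gene and regulator-row, how often the gene's next
   value was observed as 0 and as 1 over the distinct transitions;
3. resolve each row by majority vote, breaking ties — and filling rows
   never observed — with the gene's value at the steady state (the final
   observed time point of the primary sequence);
4. score the candidate network against the data and, if free wiring
   slots exist, resample them and keep the best-scoring network.

The score counts, for each observed state S_i, how many of the states
the candidate network visits downstream of S_i appear among the later
observed states S_{i+1}..S_{L+1}; off-path excursions are skipped rather
than truncating the walk.  The inconsistency of the data under a wiring
is, per gene, (1/L) * sum over truth-table rows of min(y(0), y(1)) — the
number of observations that any deterministic function must contradict.

The module exposes both a functional surface (:func:`tally_counts`,
:func:`score_network`, :func:`infer_single_path`, ...) and a
statsmodels-style model object, :class:`BNInference`, whose ``fit``
returns an :class:`InferenceResult` with a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .network import (
    BooleanNetwork,
    SuccessorLike,
    TruthTable,
    ValidationError,
    Wiring,
    coherency,
    find_attractors,
    state_bit,
    successor_fn,
)

__all__ = [
    "TransitionSequence",
    "ObservationCounts",
    "InferenceResult",
    "BNInference",
    "tally_counts",
    "inconsistency",
    "resolve_table",
    "score_network",
    "max_distinct_score",
    "infer_single_path",
    "refine_wiring",
    "infer_multi_path",
]


@dataclass(frozen=True)
class TransitionSequence:
    """An observed path of network states S_1 .. S_{L+1}.

    ``L`` is the number of transitions.  Single-state sequences (L = 0)
    are permitted so that isolated fixed points can be represented as
    paths; inference entry points require at least one transition
    overall.

    ``attractor``, when known (paths extracted from a reference
    network), records the terminal attractor cycle in canonical form;
    otherwise the final state stands in for it.
    """

    states: tuple[int, ...]
    n: int
    attractor: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        states = tuple(int(s) for s in self.states)
        object.__setattr__(self, "states", states)
        if len(states) < 1:
            raise ValidationError("a transition sequence needs at least one state")
        hi = 1 << self.n
        for s in states:
            if not 0 <= s < hi:
                raise ValidationError(f"state {s} out of range for n={self.n}")

    @property
    def L(self) -> int:
        return len(self.states) - 1

    @property
    def steady_state(self) -> int:
        """The final observed state (time point L+1)."""
        return self.states[-1]

    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.states, self.states[1:]))

    def attractor_key(self) -> tuple[int, ...]:
        """Canonical identity of the terminal attractor (for distinctness)."""
        if self.attractor is not None:
            cyc = list(self.attractor)
            j = cyc.index(min(cyc))
            return tuple(cyc[j:] + cyc[:j])
        return (self.states[-1],)

    @classmethod
    def from_bits(cls, rows: Iterable[Sequence[int]], n: int | None = None) -> "TransitionSequence":
        from .network import encode_state

        rows = list(rows)
        width = len(rows[0])
        if n is None:
            n = width
        return cls(tuple(encode_state(r) for r in rows), n)


@dataclass(frozen=True)
class ObservationCounts:
    """Per-gene, per-truth-table-row counts of observed next values.

    ``y[g, i, b]`` counts how often gene g's next value was b when its
    regulators encoded row i in the preceding state.  ``L`` is the
    number of distinct transitions tallied; per gene the counts sum to L.
    """

    y: np.ndarray
    L: int

    @property
    def filled_mask(self) -> np.ndarray:
        """Rows with at least one observation, shape (n, 2**k)."""
        return self.y.sum(axis=2) > 0


def _distinct_pairs(seqs: Sequence[TransitionSequence]) -> list[tuple[int, int]]:
    seen: set[tuple[int, int]] = set()
    out: list[tuple[int, int]] = []
    for seq in seqs:
        for pair in seq.pairs():
            if pair not in seen:
                seen.add(pair)
                out.append(pair)
    return out


def tally_counts(
    seqs: TransitionSequence | Sequence[TransitionSequence],
    wiring: Wiring,
) -> ObservationCounts:
    """Tally observed next-step values over the distinct transitions.

    Identical consecutive pairs — within one sequence or across
    sequences — are counted once: the data are treated as a set of
    distinct transitions.
    """
    if isinstance(seqs, TransitionSequence):
        seqs = [seqs]
    for seq in seqs:
        if seq.n != wiring.n:
            raise ValidationError(
                f"sequence width {seq.n} does not match wiring n={wiring.n}"
            )
    n, k = wiring.n, wiring.k
    pairs = _distinct_pairs(seqs)
    y = np.zeros((n, 1 << k, 2), dtype=np.int64)
    for a, b in pairs:
        for g in range(n):
            row = wiring.row_index(g, a)
            y[g, row, state_bit(b, g, n)] += 1
    return ObservationCounts(y=y, L=len(pairs))


def inconsistency(counts: ObservationCounts, L: int | None = None) -> tuple[int, np.ndarray]:
    """Raw and per-gene inconsistency of tallied observations.

    Per gene g the inconsistency is (1/L) * sum over rows i of
    min(y_ig(0), y_ig(1)); the raw value is the integer numerator summed
    over genes (reported as "raw out of n*L").
    """
    if L is None:
        L = counts.L
    if L < 1:
        raise ValidationError("need L >= 1")
    mins = counts.y.min(axis=2)  # (n, 2**k)
    per_gene = mins.sum(axis=1) / L
    return int(mins.sum()), per_gene


def resolve_table(
    counts: ObservationCounts,
    steady_state: int,
    wiring: Wiring,
) -> TruthTable:
    """Fill every truth-table row from the tallied observations.

    Majority value where the observations disagree in count; the gene's
    bit at the steady state both for exact ties and for rows never
    observed.
    """
    n, k = wiring.n, wiring.k
    out = np.zeros((n, 1 << k), dtype=np.uint8)
    for g in range(n):
        steady_bit = state_bit(steady_state, g, n)
        y0 = counts.y[g, :, 0]
        y1 = counts.y[g, :, 1]
        out[g] = np.where(y1 > y0, 1, np.where(y0 > y1, 0, steady_bit))
    return TruthTable(out)


def _downstream(bn: SuccessorLike, s0: int) -> list[int]:
    """States generated after s0, stopping when one repeats.

    The start itself is excluded from the repeat check, so a fixed point
    s -> s yields [s]: the self-transition is represented once.
    """
    succ = successor_fn(bn)
    out: list[int] = []
    seen: set[int] = set()
    s = succ(s0)
    while s is not None and s not in seen:
        out.append(s)
        seen.add(s)
        s = succ(s)
    return out


def score_network(bn: SuccessorLike, seq: TransitionSequence) -> int:
    """Count the observed transitions reflected in a candidate network.

    For each observed state S_i (i = 1..L), walk the candidate network
    forward from S_i and keep — skipping states that are not later
    observations — every visited state belonging to {S_{i+1},..,S_{L+1}}.
    The score is the total number kept.  For a path of distinct states
    it is bounded by L(L+1)/2.
    """
    states = seq.states
    total = 0
    for i in range(seq.L):
        allowed = set(states[i + 1:])
        total += sum(1 for s in _downstream(bn, states[i]) if s in allowed)
    return total


def max_distinct_score(seq: TransitionSequence) -> int:
    """Best achievable score counting only distinct transitions.

    Builds the ideal successor map over the order-preserving
    deduplicated state list (each distinct state maps to the next
    distinct one, the last to itself; earliest assignment wins) and
    scores it against the sequence.  Equals L(L+1)/2 when all states are
    distinct.
    """
    distinct: list[int] = []
    for s in seq.states:
        if s not in distinct:
            distinct.append(s)
    ideal: dict[int, int] = {}
    for a, b in zip(distinct, distinct[1:]):
        ideal.setdefault(a, b)
    ideal.setdefault(distinct[-1], distinct[-1])
    return score_network(ideal, seq)


@dataclass
class InferenceResult:
    """Fitted network plus fit diagnostics (the results object).

    Attributes
    ----------
    network : BooleanNetwork
        The inferred network.
    score, max_score : int
        Achieved and best-achievable transition-reproduction scores.
    inconsistency_raw : int
        Total min(y0, y1) over genes and rows; out of ``n * L`` tallies.
    inconsistency_per_gene : np.ndarray
        (1/L) * row-sums of min(y0, y1), per gene.
    coherency : float or None
        Mean single-bit-perturbation basin robustness, None when the
        state space exceeded the exhaustive cap.
    """

    network: BooleanNetwork
    score: int
    max_score: int
    inconsistency_raw: int
    inconsistency_per_gene: np.ndarray
    coherency: float | None
    L: int
    iterations: int = 1
    seed: int | None = None
    wiring_used: Wiring | None = None
    counts: ObservationCounts | None = None

    @property
    def n_attractors(self) -> int | None:
        if self.network.n > 20:
            return None
        return find_attractors(self.network).n_attractors

    def sort_key(self) -> tuple:
        """Lexicographic preference: high score, low inconsistency, high coherency."""
        coh = -1.0 if self.coherency is None else self.coherency
        return (-self.score, self.inconsistency_raw, -coh)

    def summary(self) -> str:
        n = self.network.n
        names = self.network.gene_names or tuple(f"g{i}" for i in range(n))
        lines = [
            "Boolean network inference results",
            "=" * 41,
            f"genes (n):             {n}",
            f"in-degree (k):         {self.network.wiring.k}",
            f"distinct transitions:  {self.L}",
            f"score:                 {self.score} / {self.max_score}",
            f"inconsistency:         {self.inconsistency_raw} out of {n * self.L}",
            f"coherency:             "
            + ("n/a" if self.coherency is None else f"{self.coherency:.4f}"),
            f"iterations:            {self.iterations}",
        ]
        na = self.n_attractors
        if na is not None:
            dec = find_attractors(self.network)
            lines.append(f"attractors:            {na} "
                         f"(cycle lengths {[len(a) for a in dec.attractors]})")
        lines.append("-" * 41)
        lines.append("gene  regulators            inconsistency")
        for g in range(n):
            regs = ",".join(names[r] for r in self.network.wiring.regulators[g])
            lines.append(f"{names[g]:<5} {regs:<21} {self.inconsistency_per_gene[g]:.4f}")
        return "\n".join(lines)


def infer_single_path(
    seq: TransitionSequence,
    wiring: Wiring,
    compute_coherency: bool = True,
) -> InferenceResult:
    """Infer a network from one sequence under a fully specified wiring."""
    if seq.L < 1:
        raise ValidationError("need at least one transition to infer from")
    counts = tally_counts(seq, wiring)
    table = resolve_table(counts, seq.steady_state, wiring)
    bn = BooleanNetwork(wiring, table)
    raw, per_gene = inconsistency(counts)
    coh = coherency(bn)[0] if (compute_coherency and wiring.n <= 20) else None
    return InferenceResult(
        network=bn,
        score=score_network(bn, seq),
        max_score=max_distinct_score(seq),
        inconsistency_raw=raw,
        inconsistency_per_gene=per_gene,
        coherency=coh,
        L=counts.L,
        wiring_used=wiring,
        counts=counts,
    )


def refine_wiring(
    seq: TransitionSequence,
    wiring_prior: Wiring,
    max_iters: int = 100,
    seed: int | None = None,
    compute_coherency: bool = True,
) -> InferenceResult:
    """Iteratively resample free wiring slots, keeping the best network.

    The first iteration evaluates the prior wiring as given; subsequent
    iterations redraw every free slot uniformly (no duplicate regulators
    within a gene).  Iteration stops early once the score reaches the
    maximum distinct score with zero inconsistency.  The best result is
    chosen by (score desc, raw inconsistency asc, coherency desc).
    """
    from .synthetic import random_wiring  # cycle-free: synthetic imports network only

    if max_iters < 1:
        raise ValidationError("max_iters must be >= 1")
    rng = np.random.default_rng(seed)
    best = infer_single_path(seq, wiring_prior, compute_coherency=compute_coherency)
    best.iterations = 1
    best.seed = seed
    if not wiring_prior.has_free_slots:
        return best
    for it in range(2, max_iters + 1):
        if best.score >= best.max_score and best.inconsistency_raw == 0:
            break
        cand_wiring = random_wiring(
            wiring_prior.n, wiring_prior.k, rng=rng, fixed=wiring_prior
        )
        cand = infer_single_path(seq, cand_wiring, compute_coherency=compute_coherency)
        if cand.sort_key() < best.sort_key():
            best = cand
        best.iterations = it
        best.seed = seed
    return best


def _order_paths(
    paths: Sequence[TransitionSequence], rng: np.random.Generator
) -> list[TransitionSequence]:
    """Primary-path selection for multi-path inference.

    The primary sequence SD_1 is the longest path; among equally long
    candidates one with a singleton attractor is preferred; remaining
    ties are broken by a seeded uniform choice.  The order of the other
    paths does not affect the tally.
    """
    max_L = max(p.L for p in paths)
    longest = [p for p in paths if p.L == max_L]
    singles = [p for p in longest if len(p.attractor_key()) == 1]
    pool = singles if singles else longest
    first = pool[int(rng.integers(len(pool)))] if len(pool) > 1 else pool[0]
    rest = [p for p in paths if p is not first]
    return [first] + rest


def infer_multi_path(
    paths: Sequence[TransitionSequence],
    wiring: Wiring,
    seed: int | None = None,
    compute_coherency: bool = True,
) -> InferenceResult:
    """Infer a network from several paths with distinct terminal attractors.

    Distinct transitions from all paths are tallied jointly; ties and
    unobserved rows are resolved with the steady state of the primary
    path SD_1.  The reported score and maximum are summed over paths.
    """
    paths = list(paths)
    if not paths:
        raise ValidationError("need at least one path")
    keys = [p.attractor_key() for p in paths]
    if len(set(keys)) != len(keys):
        raise ValidationError("paths must have pairwise distinct terminal attractors")
    if all(p.L < 1 for p in paths):
        raise ValidationError("need at least one transition among the paths")
    rng = np.random.default_rng(seed)
    ordered = _order_paths(paths, rng)
    counts = tally_counts(ordered, wiring)
    table = resolve_table(counts, ordered[0].steady_state, wiring)
    bn = BooleanNetwork(wiring, table)
    raw, per_gene = inconsistency(counts)
    coh = coherency(bn)[0] if (compute_coherency and wiring.n <= 20) else None
    return InferenceResult(
        network=bn,
        score=sum(score_network(bn, p) for p in ordered if p.L >= 1),
        max_score=sum(max_distinct_score(p) for p in ordered if p.L >= 1),
        inconsistency_raw=raw,
        inconsistency_per_gene=per_gene,
        coherency=coh,
        L=counts.L,
        seed=seed,
        wiring_used=wiring,
        counts=counts,
    )


class BNInference:
    """Model object: transition data plus a wiring constraint.

    Parameters
    ----------
    data : TransitionSequence or sequence thereof
        One or more observed paths.
    wiring : Wiring
        Regulator assignment; slots marked free in ``fixed_mask`` are
        resampled during fitting when ``method="refine"``.

    Examples
    --------
    >>> model = BNInference(seq, wiring)
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(
        self,
        data: TransitionSequence | Sequence[TransitionSequence],
        wiring: Wiring,
    ) -> None:
        if isinstance(data, TransitionSequence):
            data = [data]
        self.data: list[TransitionSequence] = list(data)
        if not self.data:
            raise ValidationError("no data")
        self.wiring = wiring
        for seq in self.data:
            if seq.n != wiring.n:
                raise ValidationError("sequence width does not match wiring")

    @classmethod
    def from_expression(cls, frame, wiring: Wiring, **binarize_kwargs) -> "BNInference":
        """Build the model from a genes x time-points expression DataFrame."""
        from .io import binarize

        seq, _ = binarize(frame, **binarize_kwargs)
        return cls(seq, wiring)

    def fit(
        self,
        method: str = "auto",
        max_iters: int = 100,
        seed: int | None = None,
        compute_coherency: bool = True,
    ) -> InferenceResult:
        """Fit the Boolean network.

        ``method`` is one of ``"auto"``, ``"single"``, ``"refine"``,
        ``"multi"``: auto picks multi-path for several sequences,
        the refining loop when free wiring slots exist, and the plain
        single-path fit otherwise.
        """
        if method == "auto":
            if len(self.data) > 1:
                method = "multi"
            elif self.wiring.has_free_slots:
                method = "refine"
            else:
                method = "single"
        if method == "single":
            return infer_single_path(self.data[0], self.wiring, compute_coherency)
        if method == "refine":
            return refine_wiring(
                self.data[0], self.wiring, max_iters=max_iters, seed=seed,
                compute_coherency=compute_coherency,
            )
        if method == "multi":
            return infer_multi_path(
                self.data, self.wiring, seed=seed, compute_coherency=compute_coherency
            )
        raise ValueError(f"unknown method {method!r}")
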