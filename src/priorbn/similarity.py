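"""Path-based similarity between Boolean networks.

A reference network is summarised by its set of paths: one trajectory
per Garden-of-Eden state (a state with no predecessor in the state
transition graph) running down to — and once around — its attractor,
plus one path per attractor cycle that no Garden-of-Eden trajectory
reaches.  A candidate network is scored path by path with the same
transition-reproduction score used during inference; perfectly
reproduced paths contribute their full score, imperfect ones a quarter
of it.  The similarity ratio R is the total contribution divided by the
total of the per-path maxima L(L+1)/2, so R = 1 exactly when every path
is reproduced in full.

``r_max`` and ``r_mean`` drive the validation experiments: enumerate
(or subsample) combinations of paths with pairwise distinct terminal
attractors, run multi-path inference on each combination, and report the
best / mean similarity ratio of the inferred networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .inference import (
    TransitionSequence,
    infer_multi_path,
    max_distinct_score,
    score_network,
)
from .network import BooleanNetwork, ValidationError, Wiring, find_attractors, trajectory

__all__ = [
    "PathScore",
    "SimilarityReport",
    "enumerate_paths",
    "similarity",
    "r_max",
    "r_mean",
]


@dataclass(frozen=True)
class PathScore:
    path: TransitionSequence
    score: int
    max_score: int

    @property
    def full_match(self) -> bool:
        return self.score == self.max_score


@dataclass(frozen=True)
class SimilarityReport:
    similarity_score: float
    max_similarity_score: int
    ratio: float
    per_path: tuple[PathScore, ...]

    @property
    def full_match(self) -> bool:
        return all(p.full_match for p in self.per_path)


def enumerate_paths(bn: BooleanNetwork, cap: int | None = None) -> list[TransitionSequence]:
    """All canonical paths of a network.

    One path per Garden-of-Eden state: the distinct-state trajectory
    from it, which traverses the transient part and then the attractor
    cycle exactly once (a singleton attractor contributes just its
    state).  Attractor cycles not reached from any Garden-of-Eden state
    are appended as one path each, starting at the cycle's smallest
    state.  In a network with no Garden-of-Eden states at all (a
    permutation of the state space) every attractor is covered by the
    second rule.
    """
    succ = bn.successor_map(cap=cap)
    n = bn.n
    indeg = np.bincount(succ, minlength=1 << n)
    dec = find_attractors(bn, cap=cap)
    paths: list[TransitionSequence] = []
    reachable: set[int] = set()
    for s in np.flatnonzero(indeg == 0):
        traj = trajectory(bn, int(s))
        reachable.update(traj)
        att = dec.attractor_of(int(s))
        paths.append(TransitionSequence(tuple(traj), n, attractor=att))
    for cycle in dec.attractors:
        if not any(c in reachable for c in cycle):
            paths.append(TransitionSequence(cycle, n, attractor=cycle))
    return paths


def similarity(
    bn1: BooleanNetwork,
    bn2: BooleanNetwork,
    paths: Sequence[TransitionSequence] | None = None,
) -> SimilarityReport:
    """Similarity of a candidate ``bn2`` against a reference ``bn1``.

    Per reference path with L transitions, the candidate's score is
    computed with the inference scoring rule; a path matched in full
    (score == L(L+1)/2) contributes its score, otherwise a quarter of
    it.  Zero-transition paths (isolated fixed points) carry no score
    mass and are excluded from numerator and denominator; in the
    degenerate case where *all* paths are zero-transition, R is 1 when
    the candidate preserves every such fixed point and 0 otherwise.
    """
    if bn1.n != bn2.n:
        raise ValidationError("networks must have the same number of genes")
    if paths is None:
        paths = enumerate_paths(bn1)
    per: list[PathScore] = []
    sim = 0.0
    max_sim = 0
    for p in paths:
        if p.L == 0:
            continue
        sc = score_network(bn2, p)
        mx = p.L * (p.L + 1) // 2
        per.append(PathScore(p, sc, mx))
        sim += sc if sc == mx else 0.25 * sc
        max_sim += mx
    if max_sim == 0:
        fixed = all(bn2.successor(p.states[0]) == p.states[0] for p in paths)
        ratio = 1.0 if fixed else 0.0
        return SimilarityReport(ratio, 0, ratio, tuple(per))
    return SimilarityReport(sim, max_sim, sim / max_sim, tuple(per))


def _admissible_combinations(
    paths: Sequence[TransitionSequence],
    eta: int,
    min_transitions: int,
) -> list[tuple[TransitionSequence, ...]]:
    eligible = [p for p in paths if p.L >= max(1, min_transitions)]
    combos = []
    for combo in itertools.combinations(eligible, eta):
        keys = [p.attractor_key() for p in combo]
        if len(set(keys)) == len(keys):
            combos.append(combo)
    return combos


def _evaluate_combo(
    bn1: BooleanNetwork,
    combo: Sequence[TransitionSequence],
    wiring: Wiring,
    ref_paths: Sequence[TransitionSequence],
    seed: int | None,
) -> float:
    res = infer_multi_path(list(combo), wiring, seed=seed, compute_coherency=False)
    return similarity(bn1, res.network, paths=ref_paths).ratio


def r_max(
    bn1: BooleanNetwork,
    eta: int,
    wiring: Wiring | None = None,
    min_transitions: int = 1,
    seed: int | None = None,
    max_combinations: int = 200,
) -> tuple[float, tuple[TransitionSequence, ...]]:
    """Best similarity ratio over eta-path combinations.

    Every admissible combination of eta reference paths (pairwise
    distinct terminal attractors, each with at least ``min_transitions``
    transitions) is used as synthetic data for multi-path inference with
    ``wiring`` (the reference network's own wiring by default); the
    maximum similarity ratio of the inferred networks is returned along
    with the combination achieving it.  When more than
    ``max_combinations`` combinations exist, a seeded subsample is used.
    """
    if eta < 1:
        raise ValidationError("eta must be >= 1")
    wiring = bn1.wiring if wiring is None else wiring
    ref_paths = enumerate_paths(bn1)
    combos = _admissible_combinations(ref_paths, eta, min_transitions)
    if not combos:
        raise ValidationError(
            f"no admissible combination of {eta} paths with distinct attractors "
            f"and >= {min_transitions} transitions"
        )
    rng = np.random.default_rng(seed)
    if len(combos) > max_combinations:
        idx = rng.choice(len(combos), size=max_combinations, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    best_r, best_combo = -1.0, combos[0]
    for combo in combos:
        r = _evaluate_combo(bn1, combo, wiring, ref_paths, seed)
        if r > best_r:
            best_r, best_combo = r, combo
    return best_r, best_combo


def r_mean(
    bn1: BooleanNetwork,
    eta: int,
    min_transitions: int = 1,
    wiring: Wiring | None = None,
    seed: int | None = None,
    max_combinations: int = 200,
) -> tuple[float, int]:
    """Mean similarity ratio over admissible eta-path combinations.

    Combinations must use paths of at least ``min_transitions``
    transitions; returns the mean ratio and the number of combinations
    evaluated (seeded subsample above ``max_combinations``).
    """
    if eta < 1:
        raise ValidationError("eta must be >= 1")
    wiring = bn1.wiring if wiring is None else wiring
    ref_paths = enumerate_paths(bn1)
    combos = _admissible_combinations(ref_paths, eta, min_transitions)
    if not combos:
        raise ValidationError(
            f"no admissible combination of {eta} paths with distinct attractors "
            f"and >= {min_transitions} transitions"
        )
    rng = np.random.default_rng(seed)
    if len(combos) > max_combinations:
        idx = rng.choice(len(combos), size=max_combinations, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    ratios = [_evaluate_combo(bn1, c, wiring, ref_paths, seed) for c in combos]
    return float(np.mean(ratios)), len(combos)
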