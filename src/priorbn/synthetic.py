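"""Random Boolean networks and synthetic transition data.

Generators for the validation experiments: random k-regulator wirings,
random networks with constraints on attractor structure, paths sampled
from a network's basins, and packaged benchmark instances (a source
network plus admissible paths with pairwise distinct attractors).

Truth-table bits are i.i.d. fair coin flips and regulator sets are
uniform over the C(n,k) subsets — the simplest null model of an
unstructured network.  All sampling is reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .inference import TransitionSequence
from .network import (
    BooleanNetwork,
    TruthTable,
    ValidationError,
    Wiring,
    find_attractors,
    trajectory,
)

__all__ = [
    "random_wiring",
    "random_network",
    "sample_path",
    "BenchmarkInstance",
    "benchmark_instance",
]

#: Rejection-sampling retry budget for constrained generation.
MAX_RETRIES = 10_000


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_wiring(
    n: int,
    k: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    fixed: Wiring | None = None,
) -> Wiring:
    """Draw a wiring, preserving the fixed slots of a prior.

    Free slots are filled uniformly at random without duplicating a
    regulator within one gene's list.  With no prior every slot is free.
    The returned wiring keeps the prior's fixed mask (all-free when no
    prior was given) so it can be resampled again.
    """
    rng = _as_rng(rng if rng is not None else seed)
    if k > n:
        raise ValidationError(f"k={k} exceeds n={n}")
    if fixed is not None and (fixed.n != n or fixed.k != k):
        raise ValidationError("prior wiring shape mismatch")
    regulators = []
    mask = []
    for g in range(n):
        if fixed is not None:
            slots = list(fixed.regulators[g])
            gene_mask = list(fixed.fixed_mask[g])
        else:
            slots = [-1] * k
            gene_mask = [False] * k
        kept = {slots[j] for j in range(k) if gene_mask[j]}
        if len(kept) != sum(gene_mask):
            raise ValidationError(f"gene {g}: duplicate fixed regulators")
        pool = [r for r in range(n) if r not in kept]
        n_free = k - len(kept)
        draw = list(rng.choice(len(pool), size=n_free, replace=False)) if n_free else []
        fresh = iter(pool[i] for i in draw)
        slots = [slots[j] if gene_mask[j] else next(fresh) for j in range(k)]
        regulators.append(tuple(slots))
        mask.append(tuple(gene_mask))
    return Wiring(n, k, tuple(regulators), tuple(mask))


def random_network(
    n: int,
    k: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    wiring: Wiring | None = None,
    min_attractors: int = 1,
    max_cycle_len: int | None = None,
    max_retries: int = MAX_RETRIES,
) -> BooleanNetwork:
    """Random Boolean network, rejection-sampled to meet constraints.

    Draws a wiring (unless one is supplied) and i.i.d. uniform
    truth-table bits until the network has at least ``min_attractors``
    attractors, none longer than ``max_cycle_len`` (if set).
    """
    rng = _as_rng(rng if rng is not None else seed)
    for _ in range(max_retries):
        w = wiring if wiring is not None else random_wiring(n, k, rng=rng)
        table = TruthTable(rng.integers(0, 2, size=(n, 1 << k), dtype=np.uint8))
        bn = BooleanNetwork(w, table)
        dec = find_attractors(bn)
        if dec.n_attractors < min_attractors:
            continue
        if max_cycle_len is not None and any(
            len(a) > max_cycle_len for a in dec.attractors
        ):
            continue
        return bn
    raise ValidationError(
        f"could not satisfy constraints (>= {min_attractors} attractors, "
        f"cycle length <= {max_cycle_len}) within {max_retries} draws"
    )


def sample_path(
    bn: BooleanNetwork,
    start: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TransitionSequence:
    """A path of the network: trajectory from a state into its attractor.

    With no ``start`` a Garden-of-Eden state is chosen uniformly (any
    state uniformly if the network has none).  The path lists distinct
    states and traverses the attractor cycle exactly once.
    """
    rng = _as_rng(rng if rng is not None else seed)
    n = bn.n
    if start is None:
        succ = bn.successor_map()
        indeg = np.bincount(succ, minlength=1 << n)
        goe = np.flatnonzero(indeg == 0)
        pool = goe if len(goe) else np.arange(1 << n)
        start = int(pool[int(rng.integers(len(pool)))])
    elif not 0 <= start < (1 << n):
        raise ValidationError(f"start state {start} out of range for n={n}")
    traj = trajectory(bn, int(start))
    dec = find_attractors(bn)
    return TransitionSequence(tuple(traj), n, attractor=dec.attractor_of(int(start)))


@dataclass(frozen=True)
class BenchmarkInstance:
    """A source network with admissible synthetic paths and its true wiring."""

    network: BooleanNetwork
    paths: tuple[TransitionSequence, ...]
    wiring: Wiring
    seed: int | None = None


def benchmark_instance(
    n: int = 6,
    k: int = 3,
    eta: int = 1,
    seed: int | None = None,
    min_attractors: int | None = None,
    max_retries: int = MAX_RETRIES,
) -> BenchmarkInstance:
    """Source network plus eta paths with pairwise distinct attractors.

    The network is rejection-sampled until its enumerable paths cover at
    least eta distinct attractors with at least one transition each; for
    each chosen attractor the longest available path is taken (seeded
    tie-break).  Defaults n=6, k=3 match the experimental benchmark
    scale.
    """
    from .similarity import enumerate_paths

    rng = _as_rng(seed)
    min_attractors = eta if min_attractors is None else max(min_attractors, eta)
    for _ in range(max_retries):
        bn = random_network(n, k, rng=rng, min_attractors=min_attractors)
        paths = [p for p in enumerate_paths(bn) if p.L >= 1]
        by_att: dict[tuple[int, ...], list[TransitionSequence]] = {}
        for p in paths:
            by_att.setdefault(p.attractor_key(), []).append(p)
        if len(by_att) < eta:
            continue
        keys = sorted(by_att, key=lambda a: a[0])
        chosen_keys = [keys[i] for i in rng.choice(len(keys), size=eta, replace=False)]
        chosen = []
        for key in chosen_keys:
            group = by_att[key]
            best_L = max(p.L for p in group)
            pool = [p for p in group if p.L == best_L]
            chosen.append(pool[int(rng.integers(len(pool)))])
        return BenchmarkInstance(bn, tuple(chosen), bn.wiring, seed=seed)
    raise ValidationError(
        f"could not build an instance with {eta} distinct-attractor paths "
        f"within {max_retries} draws"
    )
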