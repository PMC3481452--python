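"""REVEAL-style mutual-information network inference (baseline).

REVEAL searches, for each target gene, for the smallest set of
predictor genes whose current values fully determine the target's next
value, using the information-theoretic criterion that the mutual
information between predictor pattern and target output equals the
target's output entropy.  This implementation works from state
transition pairs, searches subsets in increasing size and lexicographic
order, and accepts the first fully determining subset.

Short time series rarely determine every target; choices for those
cases (tolerance on the MI criterion, best-MI fallback subset, majority
fill of unobserved rows) are documented parameters, not part of the
original method.  The returned network pads every predictor set to a
uniform in-degree ``k_max`` with inert regulators so the result is
directly comparable through the similarity module.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from typing import Hashable, Sequence

import numpy as np

from .inference import TransitionSequence
from .network import (
    BooleanNetwork,
    TruthTable,
    ValidationError,
    Wiring,
    state_bit,
)

__all__ = ["entropy", "mutual_information", "reveal_infer"]


def entropy(samples: Sequence[Hashable]) -> float:
    """Shannon entropy (bits) of the empirical distribution of a sequence."""
    samples = list(samples)
    if not samples:
        raise ValidationError("entropy of an empty sample is undefined")
    total = len(samples)
    return -sum(
        (c / total) * math.log2(c / total) for c in Counter(samples).values()
    )


def mutual_information(xs: Sequence[Hashable], ys: Sequence[Hashable]) -> float:
    """Empirical mutual information I(X;Y) in bits, H(X)+H(Y)-H(X,Y)."""
    if len(xs) != len(ys):
        raise ValidationError("sequences must be the same length")
    return entropy(xs) + entropy(ys) - entropy(list(zip(xs, ys)))


def _pad_regulators(subset: tuple[int, ...], n: int, k_max: int) -> tuple[int, ...]:
    pad = [g for g in range(n) if g not in subset]
    return tuple(subset) + tuple(pad[: k_max - len(subset)])


def reveal_infer(
    seqs: TransitionSequence | Sequence[TransitionSequence],
    n: int,
    k_max: int = 3,
    tol: float = 1e-9,
) -> BooleanNetwork:
    """Infer a Boolean network with the REVEAL determination criterion.

    For each target gene, predictor subsets of sizes 1..k_max are tried
    in increasing size and lexicographic order; the first subset whose
    mutual information with the target's next value reaches the target's
    entropy (within ``tol``) is accepted.  Observed truth-table rows are
    set to the majority observed output (unanimous when determined),
    unobserved rows to the target's overall majority value (ties to 0).
    A constant target is determined by the empty set.  If no subset
    determines a target, the subset with the highest mutual information
    (smallest, earliest on ties) is used with the same majority fill.

    Predictor sets are padded to a uniform in-degree ``k_max`` with
    inert regulators (their bits do not affect the output), so the
    result is an ordinary :class:`BooleanNetwork`.
    """
    if isinstance(seqs, TransitionSequence):
        seqs = [seqs]
    if k_max > n:
        raise ValidationError(f"k_max={k_max} exceeds n={n}")
    pairs = [pair for seq in seqs for pair in seq.pairs()]
    if not pairs:
        raise ValidationError("need at least one transition")
    for seq in seqs:
        if seq.n != n:
            raise ValidationError("sequence width mismatch")

    regulators: list[tuple[int, ...]] = []
    tables = np.zeros((n, 1 << k_max), dtype=np.uint8)
    for g in range(n):
        outputs = [state_bit(b, g, n) for _, b in pairs]
        majority = 1 if sum(outputs) * 2 > len(outputs) else 0
        h_target = entropy(outputs)
        chosen: tuple[int, ...] | None = None
        best: tuple[float, int, tuple[int, ...]] | None = None
        if h_target <= tol:  # constant target: determined vacuously
            chosen = ()
        else:
            for size in range(1, k_max + 1):
                for subset in itertools.combinations(range(n), size):
                    patterns = [
                        tuple(state_bit(a, r, n) for r in subset) for a, _ in pairs
                    ]
                    mi = mutual_information(patterns, outputs)
                    if best is None or mi > best[0] + tol:
                        best = (mi, size, subset)
                    if h_target - mi <= tol:
                        chosen = subset
                        break
                if chosen is not None:
                    break
            if chosen is None:
                chosen = best[2]  # undetermined target: best-MI fallback
        regs = _pad_regulators(chosen, n, k_max)
        t = len(chosen)
        # sub-table over the true predictors, then broadcast over padding
        sub = np.full(1 << t, majority, dtype=np.uint8)
        votes = np.zeros((1 << t, 2), dtype=np.int64)
        for a, b in pairs:
            row = 0
            for r in chosen:
                row = (row << 1) | state_bit(a, r, n)
            votes[row, state_bit(b, g, n)] += 1
        observed = votes.sum(axis=1) > 0
        maj_rows = np.where(votes[:, 1] > votes[:, 0], 1,
                            np.where(votes[:, 0] > votes[:, 1], 0, 0))
        sub[observed] = maj_rows[observed]
        rows = np.arange(1 << k_max)
        tables[g] = sub[rows >> (k_max - t)]
        regulators.append(regs)
    wiring = Wiring(n, k_max, tuple(regulators))
    return BooleanNetwork(wiring, TruthTable(tables))
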