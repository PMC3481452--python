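"""Search-space and attractor-structure combinatorics.

Closed-form answers to "how hard is the inverse problem": how many
Boolean networks exist with and without an in-degree constraint, how
fast observed transitions shrink that space, how many random distinct
transitions it takes to nearly fill a truth table, and how rare
singleton-attractor structure is among random networks.  Each formula is
paired (in the test suite and via the oracles here) with an exhaustive
or Monte Carlo check.

Counts use exact Python big integers; the residual search space, whose
exponent is fractional, is also reported in log10 form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "SearchSpaceParams",
    "count_unconstrained",
    "count_constrained",
    "unique_fill_probability",
    "unique_fill_probability_exhaustive",
    "expected_filled",
    "monte_carlo_filled",
    "expected_search_space",
    "expected_transitions",
    "singleton_attractor_ratio",
    "brute_force_attractor_census",
    "summary_table",
]


@dataclass(frozen=True)
class SearchSpaceParams:
    """Problem-size parameters: n genes, in-degree k, L distinct transitions."""

    n: int
    k: int
    L: int

    def __post_init__(self) -> None:
        if self.n < 1 or not (1 <= self.k <= self.n) or self.L < 0:
            raise ValueError(f"invalid parameters n={self.n}, k={self.k}, L={self.L}")

    @property
    def m(self) -> int:
        """Truth-table row count per gene, 2**k."""
        return 1 << self.k

    @property
    def N(self) -> int:
        """State count, 2**n."""
        return 1 << self.n


def count_unconstrained(n: int) -> int:
    """Number of Boolean networks on n genes with no wiring constraint.

    Every way of filling the n x 2**n full truth table: N**N with
    N = 2**n.
    """
    N = 1 << n
    return N**N


def count_constrained(n: int, k: int) -> int:
    """Number of Boolean networks with k regulators per gene.

    C(n,k)**n regulator-set choices, times 2**(n * 2**k) truth tables.
    """
    return math.comb(n, k) ** n * 2 ** (n * (1 << k))


def unique_fill_probability(m: int, L: int) -> float:
    """Probability that the L-th random transition fills a fresh table cell.

    Each transition drops one ball uniformly into the m = 2**k cells of
    a truth-table row; the chance that ball L lands in a cell untouched
    by the previous L-1 balls is (1 - 1/m)**(L-1), equivalently
    m * (m-1)**(L-1) / m**L.
    """
    if m < 1 or L < 1:
        raise ValueError("need m >= 1 and L >= 1")
    return (1 - 1 / m) ** (L - 1)


def unique_fill_probability_exhaustive(m: int, L: int) -> float:
    """Oracle for :func:`unique_fill_probability` by full enumeration.

    Enumerates all m**L ball placements and counts those in which the
    L-th ball occupies a cell missed by all earlier balls.  Intended for
    small m, L only.
    """
    if m**L > 10**7:
        raise ValueError("enumeration too large; use the closed form")
    hits = sum(1 for seq in product(range(m), repeat=L) if seq[-1] not in seq[:-1])
    return hits / m**L


def expected_filled(n: int, k: int, L: int) -> float:
    """Expected number of distinct truth-table cells filled by L transitions.

    n * 2**k * (1 - (1 - 2**-k)**L); each transition fills one uniform
    cell per row, so this is the coupon-collector partial sum summed
    over the n rows.
    """
    if L < 0:
        raise ValueError("need L >= 0")
    return n * (1 << k) * (1 - (1 - 2.0 ** (-k)) ** L)


def monte_carlo_filled(
    n: int, k: int, L: int, reps: int = 100_000, seed: int | None = None
) -> tuple[float, float]:
    """Monte Carlo oracle for :func:`expected_filled`.

    Simulates the ball-throwing process ``reps`` times and returns the
    sample mean of distinct filled cells and its standard error.
    """
    rng = np.random.default_rng(seed)
    m = 1 << k
    if L == 0:
        return 0.0, 0.0
    # (reps, n, L) uniform cell choices; count distinct per row via bincount trick
    draws = rng.integers(0, m, size=(reps, n, L))
    # distinct cells per (rep, row): number of unique values along axis 2
    filled = np.zeros(reps)
    for row in range(n):
        cells = draws[:, row, :]
        onehot = np.zeros((reps, m), dtype=bool)
        onehot[np.repeat(np.arange(reps), L), cells.ravel()] = True
        filled += onehot.sum(axis=1)
    mean = float(filled.mean())
    se = float(filled.std(ddof=1) / math.sqrt(reps))
    return mean, se


def expected_search_space(n: int, k: int, L: int) -> tuple[float, float]:
    """Expected residual number of networks after L distinct transitions.

    C(n,k)**n * 2**(n * 2**k * (1 - 2**-k)**L): the regulator-set factor
    times two to the expected number of still-unfilled truth-table
    cells.  Returns the value and its log10 (the value can overflow a
    float for large n, k).
    """
    if L < 0:
        raise ValueError("need L >= 0")
    reg_factor = math.comb(n, k) ** n
    exponent = n * (1 << k) * (1 - 2.0 ** (-k)) ** L
    log10 = math.log10(reg_factor) + exponent * math.log10(2)
    value = 10.0**log10 if log10 < 300 else math.inf
    return value, log10


def expected_transitions(k: int) -> tuple[float, int]:
    """Expected distinct transitions to fill m-1 of the m cells per row.

    Solves n*m*(1 - (1-1/m)**L) = n*(m-1) for L with m = 2**k, giving
    L_ex = log(1/m) / log((m-1)/m).  Returned as the real value and its
    integer floor.
    """
    m = 1 << k
    if m < 2:
        raise ValueError("need k >= 1")
    value = math.log(1 / m) / math.log((m - 1) / m)
    return value, math.floor(value)


def singleton_attractor_ratio(N: int, only_one: bool = False) -> float:
    """Fraction of random networks on N states with singleton attractors.

    Among all N**N self-maps of the state space, the fraction whose
    attractors are all fixed points is (N+1)**(N-1) / N**N; the fraction
    with exactly one attractor, a fixed point, is N**(N-1) / N**N = 1/N.
    """
    if N < 1:
        raise ValueError("need N >= 1")
    if only_one:
        return 1 / N
    return (N + 1) ** (N - 1) / N**N


def _cycle_lengths(succ: tuple[int, ...]) -> list[int]:
    """Lengths of the cycles of a functional map given as a tuple."""
    N = len(succ)
    color = [0] * N
    lengths: list[int] = []
    for s0 in range(N):
        if color[s0]:
            continue
        path = []
        u = s0
        while color[u] == 0:
            color[u] = 1
            path.append(u)
            u = succ[u]
        if color[u] == 1:
            lengths.append(len(path) - path.index(u))
        for v in path:
            color[v] = 2
    return lengths


def brute_force_attractor_census(N: int) -> tuple[int, int, int]:
    """Enumerate all N**N self-maps and classify their cycle structure.

    Returns (number of maps whose cycles are all singletons, number with
    exactly one cycle which is a singleton, total N**N).  Exhaustive
    oracle for :func:`singleton_attractor_ratio`; limited to N <= 6.
    """
    if not 1 <= N <= 6:
        raise ValueError("census enumeration limited to 1 <= N <= 6")
    all_singleton = 0
    exactly_one = 0
    total = 0
    for succ in product(range(N), repeat=N):
        total += 1
        lengths = _cycle_lengths(succ)
        if all(l == 1 for l in lengths):
            all_singleton += 1
            if len(lengths) == 1:
                exactly_one += 1
    return all_singleton, exactly_one, total


def summary_table(n: int, k: int, L: int) -> dict[str, float | int]:
    """All closed-form quantities for one (n, k, L) in a flat dict."""
    value, log10 = expected_search_space(n, k, L)
    lex, lex_floor = expected_transitions(k)
    N = 1 << n
    return {
        "n": n,
        "k": k,
        "L": L,
        "count_unconstrained": count_unconstrained(n),
        "count_constrained": count_constrained(n, k),
        "expected_filled": expected_filled(n, k, L),
        "expected_search_space": value,
        "expected_search_space_log10": log10,
        "L_ex": lex,
        "L_ex_floor": lex_floor,
        "singleton_attractor_ratio": singleton_attractor_ratio(N),
        "only_one_singleton_ratio": singleton_attractor_ratio(N, only_one=True),
    }
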