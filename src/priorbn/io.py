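"""Expression-matrix I/O, Otsu binarization, and network serialization.

Expression matrices are genes x time-points tables (TSV/CSV, first
column gene names, header row time labels).  Each gene is binarized
independently with an exact one-dimensional Otsu threshold — every
midpoint between consecutive sorted unique values is evaluated and the
one maximizing the between-class variance is kept — because a handful
of time points is far too few for the classic 256-bin histogram
variant, and microarray genes have incomparable dynamic ranges so a
global threshold would be meaningless.

Networks round-trip through a small versioned JSON document and can be
exported to a BoolNet-style ``targets, factors`` logic file (each
gene's rule written as the disjunctive normal form of its truth table)
and to TSV/DOT state-transition-graph dumps.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import TransitionSequence
from .network import (
    BooleanNetwork,
    TruthTable,
    ValidationError,
    Wiring,
    build_stg,
    encode_state,
)

__all__ = [
    "otsu_threshold",
    "binarize",
    "read_expression",
    "write_network",
    "read_network",
    "network_to_dict",
    "network_from_dict",
    "export_boolnet",
    "export_stg_tsv",
    "export_stg_dot",
    "read_paths",
    "write_paths",
    "to_networkx",
]

NETWORK_FORMAT = "priorbn-network"
NETWORK_VERSION = 1


def otsu_threshold(values: Sequence[float]) -> float:
    """Exact 1-D Otsu threshold for a small sample.

    Evaluates every midpoint between consecutive sorted unique values
    and returns the one maximizing the between-class variance
    w0*w1*(mu0-mu1)**2 (equivalently minimizing within-class variance);
    ties go to the smaller threshold.  Values <= threshold binarize to
    0, values > threshold to 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least two values to threshold")
    uniq = np.unique(v)
    if uniq.size < 2:
        raise ValidationError("all values identical; gene is uninformative")
    best_t = None
    best_var = -np.inf
    for t in (uniq[:-1] + uniq[1:]) / 2:
        lo = v[v <= t]
        hi = v[v > t]
        w0 = lo.size / v.size
        w1 = hi.size / v.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:  # strict: ties keep the earlier, smaller threshold
            best_var = var
            best_t = t
    return float(best_t)


def binarize(
    frame: pd.DataFrame,
    constant_policy: str = "zero",
) -> tuple[TransitionSequence, pd.Series]:
    """Binarize a genes x time-points matrix into a transition sequence.

    Each gene (row) is thresholded with :func:`otsu_threshold` on its
    own time series; each column then becomes one network state with the
    first gene as most significant bit.  Genes with identical values at
    every time point have no Otsu threshold; ``constant_policy`` decides
    their fate: ``"zero"`` (default) marks them OFF throughout with a
    warning, ``"error"`` raises.

    Returns the transition sequence and the per-gene thresholds
    (NaN for constant genes under the ``"zero"`` policy).
    """
    if frame.shape[1] < 2:
        raise ValidationError("need at least two time points")
    if frame.isna().any().any():
        raise ValidationError("expression matrix contains missing values")
    n = frame.shape[0]
    bits = np.zeros(frame.shape, dtype=np.uint8)
    thresholds = pd.Series(np.nan, index=frame.index, dtype=float)
    for i, (gene, row) in enumerate(frame.iterrows()):
        vals = row.to_numpy(dtype=float)
        try:
            t = otsu_threshold(vals)
        except ValidationError:
            if constant_policy == "zero":
                warnings.warn(f"gene {gene!r} is constant; binarized to all zeros")
                continue
            raise ValidationError(f"gene {gene!r}: constant expression") from None
        thresholds.iloc[i] = t
        bits[i] = vals > t
    states = tuple(encode_state(bits[:, j]) for j in range(frame.shape[1]))
    return TransitionSequence(states, n), thresholds


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x time-points expression table (TSV or CSV).

    First column holds gene names, the header row time labels; all
    remaining cells must be numeric with no missing values.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: need at least two time-point columns")
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric expression values: {exc}") from exc
    if frame.isna().any().any():
        raise ValidationError(f"{path}: missing values are not supported")
    return frame


def network_to_dict(bn: BooleanNetwork) -> dict:
    names = bn.gene_names or tuple(f"g{i}" for i in range(bn.n))
    return {
        "format": NETWORK_FORMAT,
        "version": NETWORK_VERSION,
        "n": bn.n,
        "k": bn.wiring.k,
        "gene_names": list(names),
        "regulators": [list(row) for row in bn.wiring.regulators],
        "fixed_mask": [[int(b) for b in row] for row in bn.wiring.fixed_mask],
        "tables": ["".join(str(int(b)) for b in row) for row in bn.table.outputs],
    }


def network_from_dict(doc: dict) -> BooleanNetwork:
    if doc.get("format") != NETWORK_FORMAT:
        raise ValidationError(f"not a {NETWORK_FORMAT} document")
    if doc.get("version") != NETWORK_VERSION:
        raise ValidationError(f"unsupported version {doc.get('version')!r}")
    try:
        n, k = int(doc["n"]), int(doc["k"])
        regulators = tuple(tuple(int(r) for r in row) for row in doc["regulators"])
        mask = tuple(
            tuple(bool(b) for b in row) for row in doc.get("fixed_mask") or ()
        )
        tables = doc["tables"]
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"malformed network document: {exc}") from exc
    if len(tables) != n or any(len(t) != (1 << k) for t in tables):
        raise ValidationError("table strings inconsistent with n, k")
    if any(c not in "01" for t in tables for c in t):
        raise ValidationError("table strings must be binary")
    outputs = np.array([[int(c) for c in t] for t in tables], dtype=np.uint8)
    names = tuple(doc.get("gene_names") or ()) or None
    return BooleanNetwork(
        Wiring(n, k, regulators, mask), TruthTable(outputs), gene_names=names
    )


def write_network(bn: BooleanNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network_to_dict(bn), indent=2) + "\n")


def read_network(path: str | Path) -> BooleanNetwork:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: invalid JSON: {exc}") from exc
    return network_from_dict(doc)


def export_boolnet(bn: BooleanNetwork) -> str:
    """BoolNet-style ``targets, factors`` logic rules (export only).

    Each gene's rule is the disjunctive normal form of its truth table:
    one conjunction per table row with output 1.  Constant rules are
    written as the gene's own fixed value via tautology/contradiction on
    the first regulator, keeping the file loadable by logic parsers that
    lack literal constants.
    """
    names = bn.gene_names or tuple(f"g{i}" for i in range(bn.n))
    k = bn.wiring.k
    lines = ["targets, factors"]
    for g in range(bn.n):
        regs = bn.wiring.regulators[g]
        ones = [row for row in range(1 << k) if bn.table.outputs[g, row]]
        if not ones:
            rule = f"{names[regs[0]]} & !{names[regs[0]]}"
        elif len(ones) == (1 << k):
            rule = f"{names[regs[0]]} | !{names[regs[0]]}"
        else:
            terms = []
            for row in ones:
                lits = []
                for j, r in enumerate(regs):
                    bit = (row >> (k - 1 - j)) & 1
                    lits.append(names[r] if bit else f"!{names[r]}")
                terms.append("(" + " & ".join(lits) + ")")
            rule = " | ".join(terms)
        lines.append(f"{names[g]}, {rule}")
    return "\n".join(lines) + "\n"


def export_stg_tsv(bn: BooleanNetwork) -> str:
    """State transition graph as a two-column TSV of decimal states."""
    lines = ["source\ttarget"]
    lines += [f"{s}\t{t}" for s, t in build_stg(bn)]
    return "\n".join(lines) + "\n"


def export_stg_dot(bn: BooleanNetwork) -> str:
    """State transition graph in DOT format for graphviz rendering."""
    n = bn.n
    lines = ["digraph stg {"]
    for s, t in build_stg(bn):
        sb = format(s, f"0{n}b")
        tb = format(t, f"0{n}b")
        lines.append(f'  "{sb}" -> "{tb}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_networkx(bn: BooleanNetwork):
    """State transition graph as a :class:`networkx.DiGraph`."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_edges_from(build_stg(bn))
    return g


def read_paths(path: str | Path, n: int) -> list[TransitionSequence]:
    """Read transition paths: one state per line, blank line between paths.

    States may be binary strings of width n or decimal integers.
    """
    blocks: list[list[int]] = [[]]
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            if blocks[-1]:
                blocks.append([])
            continue
        if set(line) <= {"0", "1"} and len(line) == n:
            state = int(line, 2)
        else:
            try:
                state = int(line)
            except ValueError:
                raise ValidationError(f"{path}: unparseable state line {line!r}") from None
        blocks[-1].append(state)
    if not blocks[-1]:
        blocks.pop()
    if not blocks:
        raise ValidationError(f"{path}: no states found")
    return [TransitionSequence(tuple(b), n) for b in blocks]


def write_paths(paths: Sequence[TransitionSequence], path: str | Path) -> None:
    chunks = []
    for p in paths:
        chunks.append("\n".join(format(s, f"0{p.n}b") for s in p.states))
    Path(path).write_text("\n\n".join(chunks) + "\n")
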