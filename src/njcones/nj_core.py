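"""The neighbor-joining algorithm, instrumented for its full output space.

The implementation differs from a production tree builder in two deliberate
ways.  First, it never estimates branch lengths: the reduction formula is used
only to propagate the dissimilarity map, because the object of interest is
the *agglomerated tree* (topology plus join order), not the fitted metric.
Second, the forced two-way tie at the last step (when four boughs remain, the
Q-criterion is minimized simultaneously by a pair and its set complement) is
detected analytically rather than by a floating-point double-argmin, and the
run returns *both* tied agglomerated trees together with a representative
chosen by a pluggable policy:

``lexicographic``
    join the pair containing the lowest-index bough (the convention of the
    original NJ description);
``uniform``
    choose one of the two tied joins uniformly at random (one RNG draw);
``baggage``
    join the pair whose boughs together carry more original taxa, falling
    back to a uniform draw when the two sides carry the same number.

All arithmetic is generic: a map built from ``fractions.Fraction`` entries is
processed exactly, which the tie identity relies on in tests.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .trees import AgglomeratedTree, Clade, Topology, default_taxa, random_topology

__all__ = [
    "DissimilarityMap",
    "JoinEvent",
    "ExecutionTranscript",
    "POLICIES",
    "q_matrix",
    "reduce",
    "final_tie",
    "nj_run",
    "trees_from_transcript",
    "transcript_from_tree",
    "read_phylip",
    "read_csv",
    "tree_metric",
    "random_tree_metric",
]

POLICIES = ("lexicographic", "uniform", "baggage")

_REL_TOL = 1e-9  # relative tolerance for float comparisons of Q values


class DissimilarityMap:
    """A symmetric nonnegative map over the active boughs.

    ``ids`` lists the active boughs in creation order: original taxa first
    (their order fixes the lexicographic tie-break), then bouquets, whose
    integer ids ``n + s`` double as the step at which they were created.
    ``baggage[i]`` is the set of original taxa carried by bough ``i``.
    Values may be floats or exact rationals.
    """

    __slots__ = ("ids", "index", "d", "baggage", "n_taxa")

    def __init__(self, ids, index, d, baggage, n_taxa):
        self.ids = ids          # list of active bough ids
        self.index = index      # id -> creation rank (stable across reductions)
        self.d = d              # id -> {other id -> value}
        self.baggage = baggage  # id -> frozenset of original taxa
        self.n_taxa = n_taxa

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_matrix(
        cls,
        labels: Sequence[str],
        matrix,
        check: bool = True,
        tol: float = 1e-9,
    ) -> "DissimilarityMap":
        labels = list(labels)
        k = len(labels)
        if len(set(labels)) != k:
            raise ValueError("duplicate taxon labels")
        rows = [list(r) for r in matrix]
        if len(rows) != k or any(len(r) != k for r in rows):
            raise ValueError(f"matrix must be {k}x{k}")
        if check:
            scale = max((abs(x) for r in rows for x in r), default=1) or 1
            for i in range(k):
                if abs(rows[i][i]) > tol * scale:
                    raise ValueError(f"nonzero diagonal at {labels[i]}")
                for j in range(i + 1, k):
                    if abs(rows[i][j] - rows[j][i]) > tol * scale:
                        raise ValueError(
                            f"asymmetric entry ({labels[i]},{labels[j]})"
                        )
                    if rows[i][j] < -tol * scale:
                        raise ValueError(
                            f"negative entry ({labels[i]},{labels[j]})"
                        )
        d = {a: {} for a in labels}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    d[a][b] = rows[i][j]
        index = {a: i for i, a in enumerate(labels)}
        baggage = {a: frozenset((a,)) for a in labels}
        return cls(list(labels), index, d, baggage, k)

    def copy(self) -> "DissimilarityMap":
        return DissimilarityMap(
            list(self.ids),
            dict(self.index),
            {a: dict(row) for a, row in self.d.items()},
            dict(self.baggage),
            self.n_taxa,
        )

    # -- views -------------------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.ids)

    def value(self, a, b):
        return 0 if a == b else self.d[a][b]

    def values(self) -> np.ndarray:
        """Dense matrix aligned with ``ids`` (dtype object for exact entries)."""
        k = self.k
        exact = any(
            not isinstance(v, float) for row in self.d.values() for v in row.values()
        )
        out = np.zeros((k, k), dtype=object if exact else float)
        for i, a in enumerate(self.ids):
            for j, b in enumerate(self.ids):
                if i != j:
                    out[i, j] = self.d[a][b]
        return out

    def __repr__(self) -> str:
        return f"DissimilarityMap(k={self.k}, n_taxa={self.n_taxa})"


# ---------------------------------------------------------------------------
# the Q-criterion and the reduction step
# ---------------------------------------------------------------------------


def _row_sums(D: DissimilarityMap) -> dict:
    return {a: sum(D.d[a].values()) for a in D.ids}


def q_matrix(D: DissimilarityMap) -> np.ndarray:
    """The Q-criterion ``Q(a,b) = (k-2) D(a,b) - sum_c D(a,c) - sum_c D(b,c)``.

    Sums run over all active boughs ``c`` (the ``D(a,b)`` terms they contain
    cancel pairwise, which is what forces the final-step tie).  Returned as a
    dense matrix aligned with ``D.ids``; the diagonal is set to 0 and carries
    no meaning.
    """
    k = D.k
    if k < 3:
        raise ValueError("Q-criterion needs at least 3 boughs")
    R = _row_sums(D)
    exact = any(not isinstance(v, float) for v in R.values())
    out = np.zeros((k, k), dtype=object if exact else float)
    for i, a in enumerate(D.ids):
        for j in range(i + 1, k):
            b = D.ids[j]
            q = (k - 2) * D.d[a][b] - R[a] - R[b]
            out[i, j] = q
            out[j, i] = q
    return out


def reduce(D: DissimilarityMap, a, b, new_id=None) -> DissimilarityMap:
    """Join boughs *a*, *b* into a bouquet via ``D(c,u) = (D(a,c)+D(b,c)-D(a,b))/2``.

    Returns a new map with ``a``/``b`` replaced by the bouquet; other entries
    are untouched and the bouquet inherits the union of both baggage sets.
    """
    if a == b:
        raise ValueError("cannot join a bough with itself")
    if a not in D.d or b not in D.d:
        raise ValueError("inactive bough")
    if new_id is None:
        new_id = _next_id(D)
    dab = D.d[a][b]
    new_row = {}
    for c in D.ids:
        if c in (a, b):
            continue
        v = (D.d[a][c] + D.d[b][c] - dab) / 2
        new_row[c] = v
    d = {x: {y: v for y, v in row.items() if y not in (a, b)} for x, row in D.d.items() if x not in (a, b)}
    for c, v in new_row.items():
        d[c][new_id] = v
    d[new_id] = new_row
    ids = [x for x in D.ids if x not in (a, b)] + [new_id]
    index = dict(D.index)
    index[new_id] = max(index.values()) + 1
    baggage = {x: s for x, s in D.baggage.items() if x not in (a, b)}
    baggage[new_id] = D.baggage[a] | D.baggage[b]
    return DissimilarityMap(ids, index, d, baggage, D.n_taxa)


def _next_id(D: DissimilarityMap) -> int:
    used = [i for i in D.ids if isinstance(i, int)]
    return (max(used) + 1) if used else D.n_taxa + 1


# ---------------------------------------------------------------------------
# pair selection
# ---------------------------------------------------------------------------


def _q_pairs(D: DissimilarityMap) -> dict:
    """Q values keyed by id pairs (a, b) with index(a) < index(b)."""
    k = D.k
    R = _row_sums(D)
    out = {}
    ids = sorted(D.ids, key=D.index.__getitem__)
    for i, a in enumerate(ids):
        ra = R[a]
        da = D.d[a]
        for b in ids[i + 1:]:
            out[(a, b)] = (k - 2) * da[b] - ra - R[b]
    return out

def _argmin_pair(q: dict, index: Mapping) -> tuple:
    """Minimal pair; numeric near-ties broken lexicographically on indices."""
    m = min(q.values())
    tol = _REL_TOL * max(1.0, abs(float(m))) if isinstance(m, float) else 0
    best = None
    for pair, v in q.items():
        if v - m <= tol:
            key = (index[pair[0]], index[pair[1]])
            if best is None or key < best[0]:
                best = (key, pair)
    return best[1]


def final_tie(D: DissimilarityMap):
    """The analytic two-way tie of the four-bough step.

    Returns ``(pair, complement)`` where *pair* minimizes Q and contains the
    lowest-index bough of the minimizing pair/complement split; the
    complement attains exactly the same Q value (verified, exactly for
    rational input and to relative tolerance for floats).
    """
    if D.k != 4:
        raise ValueError("final_tie needs exactly 4 boughs")
    q = _q_pairs(D)
    pair = _argmin_pair(q, D.index)
    rest = sorted((i for i in D.ids if i not in pair), key=D.index.__getitem__)
    comp = (rest[0], rest[1])
    qa, qb = q[pair], q[comp]
    diff = qa - qb
    if isinstance(diff, float):
        scale = max(1.0, abs(float(qa)))
        if abs(diff) > 1e-6 * scale:
            raise AssertionError(f"final-step tie violated: {qa} vs {qb}")
    elif diff != 0:
        raise AssertionError(f"final-step tie violated exactly: {qa} vs {qb}")
    # orient the result so the first pair contains the overall lowest index
    lowest = min(D.ids, key=D.index.__getitem__)
    if lowest in comp:
        pair, comp = comp, pair
    return pair, comp


# ---------------------------------------------------------------------------
# transcripts and full runs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JoinEvent:
    step: int
    pair: tuple
    new_id: int


@dataclass
class ExecutionTranscript:
    """A full record of one NJ execution.

    ``events`` has ``n - 3`` entries; the last one is the representative's
    final join.  ``final_pair``/``final_complement`` are the two analytically
    tied options at the four-bough step (the first contains the lowest-index
    bough), and ``chosen`` is whichever the policy selected.
    """

    taxa: tuple
    events: tuple
    final_pair: tuple
    final_complement: tuple
    policy: str
    chosen: tuple

    @property
    def n(self) -> int:
        return len(self.taxa)

    def to_json(self) -> str:
        return json.dumps(
            {
                "taxa": list(self.taxa),
                "events": [
                    {"step": e.step, "pair": [str(x) for x in e.pair], "new_id": e.new_id}
                    for e in self.events
                ],
                "final_pair": [str(x) for x in self.final_pair],
                "final_complement": [str(x) for x in self.final_complement],
                "policy": self.policy,
                "chosen": [str(x) for x in self.chosen],
            },
            indent=2,
        )


def _tree_from_joins(taxa, joins) -> AgglomeratedTree:
    n = len(taxa)
    sub: dict = {t: t for t in taxa}
    order: list = list(taxa)
    for s, (a, b) in enumerate(joins, start=1):
        node = Clade(s, (sub.pop(a), sub.pop(b)))
        order = [x for x in order if x not in (a, b)]
        uid = n + s
        sub[uid] = node
        order.append(uid)
    assert len(order) == 3
    root = Clade(None, tuple(sub[x] for x in order))
    return AgglomeratedTree(root, validate=False)


def trees_from_transcript(tr: ExecutionTranscript) -> tuple[AgglomeratedTree, AgglomeratedTree]:
    """Rebuild the two tied agglomerated trees recorded in a transcript."""
    common = [e.pair for e in tr.events[:-1]]
    t1 = _tree_from_joins(tr.taxa, common + [tr.final_pair])
    t2 = _tree_from_joins(tr.taxa, common + [tr.final_complement])
    return t1, t2


def nj_run(
    D: DissimilarityMap,
    policy: str = "lexicographic",
    rng: Union[None, int, np.random.Generator] = None,
):
    """Run neighbor joining, returning both tied trees and the transcript.

    Returns ``((tree_pair, tree_complement), transcript)`` where the two
    agglomerated trees differ only in the final join (they always share a
    topology), and ``transcript.chosen`` identifies the policy's
    representative.  Pre-final numeric ties (a measure-zero event for generic
    input) are broken lexicographically on bough indices.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    n = D.k
    if n < 4:
        raise ValueError("n must be >= 4")
    if D.k != D.n_taxa:
        raise ValueError("nj_run expects a fresh map over original taxa")
    if policy != "lexicographic" and not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    cur = D
    events = []
    for s in range(1, n - 3):
        q = _q_pairs(cur)
        a, b = _argmin_pair(q, cur.index)
        uid = n + s
        cur = reduce(cur, a, b, new_id=uid)
        events.append(JoinEvent(s, (a, b), uid))

    pair, comp = final_tie(cur)
    if policy == "lexicographic":
        chosen = pair  # final_tie puts the lowest-index bough in `pair`
    elif policy == "uniform":
        chosen = pair if rng.integers(2) == 0 else comp
    else:  # baggage
        wa = len(cur.baggage[pair[0]]) + len(cur.baggage[pair[1]])
        wb = len(cur.baggage[comp[0]]) + len(cur.baggage[comp[1]])
        if wa != wb:
            chosen = pair if wa > wb else comp
        else:
            chosen = pair if rng.integers(2) == 0 else comp

    s = n - 3
    uid = n + s
    events.append(JoinEvent(s, chosen, uid))
    tr = ExecutionTranscript(
        taxa=tuple(D.ids),
        events=tuple(events),
        final_pair=pair,
        final_complement=comp,
        policy=policy,
        chosen=chosen,
    )
    common = [e.pair for e in events[:-1]]
    t1 = _tree_from_joins(tr.taxa, common + [pair])
    t2 = _tree_from_joins(tr.taxa, common + [comp])
    return (t1, t2), tr


def transcript_from_tree(t: AgglomeratedTree) -> ExecutionTranscript:
    """Reconstruct the join transcript encoded by an agglomerated tree.

    The node labeled ``s`` joined its two children at step ``s``; the node
    labeled ``n - 3`` records the final (chosen) join, and the tie complement
    is the remaining pair of boughs at the central node.
    """
    taxa = t.leaves
    n = len(taxa)

    # bough id of a subtree: taxon name, or n + label of its top node
    def bough_id(node):
        return node if isinstance(node, str) else n + node.label

    joins: dict[int, tuple] = {}

    def rec(node):
        if isinstance(node, str):
            return
        a, b = node.children
        joins[node.label] = (bough_id(a), bough_id(b))
        rec(a)
        rec(b)

    for c in t.root.children:
        rec(c)
    events = tuple(
        JoinEvent(s, joins[s], n + s) for s in range(1, n - 2)
    )
    chosen = joins[n - 3]
    others = tuple(bough_id(c) for c in t.root.children if bough_id(c) != n + (n - 3))
    assert len(others) == 2
    # creation rank: taxa in sorted order, then bouquets by step
    rank = {x: i for i, x in enumerate(taxa)}
    rank.update({n + s: n + s for s in range(1, n - 2)})
    comp = tuple(sorted(others, key=rank.__getitem__))
    pair, complement = chosen, comp
    lowest = min(
        (pair[0], pair[1], comp[0], comp[1]), key=rank.__getitem__
    )
    if lowest in comp:
        pair, complement = comp, chosen
    return ExecutionTranscript(
        taxa=tuple(taxa),
        events=events,
        final_pair=pair,
        final_complement=complement,
        policy="reconstructed",
        chosen=chosen,
    )


# ---------------------------------------------------------------------------
# input formats
# ---------------------------------------------------------------------------


def read_phylip(source: Union[str, os.PathLike, io.TextIOBase]) -> DissimilarityMap:
    """Read a square PHYLIP distance matrix (taxon count line, then rows)."""
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty PHYLIP input")
    try:
        k = int(lines[0].split()[0])
    except ValueError as exc:
        raise ValueError("first PHYLIP line must be the taxon count") from exc
    if len(lines) - 1 != k:
        raise ValueError(f"expected {k} matrix rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != k + 1:
            raise ValueError(f"row {parts[0] if parts else '?'} must have {k} values")
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DissimilarityMap.from_matrix(labels, rows)


def read_csv(source) -> DissimilarityMap:
    """Read a headered CSV distance matrix (first column = taxon labels)."""
    import pandas as pd

    df = pd.read_csv(source, index_col=0)
    labels = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != labels:
        raise ValueError("CSV row and column labels disagree")
    return DissimilarityMap.from_matrix(labels, df.to_numpy(dtype=float).tolist())


# ---------------------------------------------------------------------------
# additive (tree-metric) inputs for simulation
# ---------------------------------------------------------------------------


def tree_metric(top: Topology, weights: Mapping) -> DissimilarityMap:
    """Path-sum metric of *top* under nonnegative edge ``weights``.

    Weights are keyed by ``frozenset({u, v})`` per edge; missing edges get
    weight 1.
    """
    leaves = top.leaves
    dist = {}
    for src in leaves:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            v = stack.pop()
            for u in top.adjacency[v]:
                if u not in seen:
                    w = weights.get(frozenset((v, u)), 1.0)
                    seen[u] = seen[v] + w
                    stack.append(u)
        dist[src] = seen
    rows = [[dist[a][b] if a != b else 0.0 for b in leaves] for a in leaves]
    return DissimilarityMap.from_matrix(leaves, rows)


def random_tree_metric(
    n: int,
    rng: Union[int, np.random.Generator, None] = None,
    blen: tuple[float, float] = (0.1, 1.0),
) -> tuple[DissimilarityMap, Topology]:
    """An additive map from a random binary tree with U(blen) branch lengths."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    top = random_topology(default_taxa(n), rng)
    lo, hi = blen
    weights = {
        frozenset((u, v)): float(rng.uniform(lo, hi)) for u, v in top.edges()
    }
    return tree_metric(top, weights), top
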