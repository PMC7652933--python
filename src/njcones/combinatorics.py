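"""Counting the output space of neighbor joining via (weighted) Motzkin paths.

An intermediate NJ tree is summarized by its *bough vector* ``(l, r)`` — the
numbers of stems (leaf boughs) and bouquets (internal boughs).  Each join
moves the vector by one of three steps: ``alpha = (-2, 1)`` merges two stems,
``beta = (0, -1)`` merges two bouquets, ``gamma = (-1, 0)`` merges a stem
with a bouquet.  An *NJ path* for ``n`` taxa is a lattice path of length
``n - 4`` with these steps, starting at ``(n - 2, 1)`` (the first join is
always an alpha and is left implicit), never dropping below ``y = 1``, and
ending at one of ``(2, 1)``, ``(1, 2)``, ``(0, 3)``.  The linear map
``[[-1, -1], [0, 1]]`` carries the steps to the Motzkin steps up/down/
horizontal, so NJ paths biject with partial Motzkin paths and are counted by
the Motzkin triangle entry ``M(n-3, 1)``.

Weighting each step by the number of joins it represents — ``C(l, 2)`` stem
pairs, ``C(r, 2)`` bouquet pairs, ``l * r`` mixed — turns the path count into
the count of *agglomerated trees*

    Phi(n) = C(n,2) C(n-1,2) ... C(4,2) = n ((n-1)!)^2 / (3 * 2^(n-1)),

with the number of distinct NJ outputs (polyhedral cones) equal to
``Phi(n) / 2`` because of the forced final tie.  Everything here is exact
big-integer arithmetic; a brute-force enumeration of all join sequences
serves as an independent oracle for small ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb, factorial
from typing import Iterator

__all__ = [
    "LatticePath",
    "NJ_STEPS",
    "MOTZKIN_STEPS",
    "motzkin",
    "motzkin_closed_form",
    "motzkin_triangle",
    "motzkin_number",
    "catalan",
    "enumerate_nj_paths",
    "nj_path_count",
    "nj_to_motzkin",
    "motzkin_to_nj",
    "weights",
    "weighted_triangle",
    "phi",
    "brute_force_phi",
    "brute_force_agglomerated_trees",
    "cone_count",
    "double_factorial",
    "num_labeled_topologies",
]

NJ_STEPS = {"a": (-2, 1), "b": (0, -1), "g": (-1, 0)}
MOTZKIN_STEPS = {"u": (1, 1), "d": (1, -1), "h": (1, 0)}
_NJ_TO_MOTZKIN = {"a": "u", "b": "d", "g": "h"}
_MOTZKIN_TO_NJ = {v: k for k, v in _NJ_TO_MOTZKIN.items()}


@dataclass(frozen=True)
class LatticePath:
    """A finite lattice path: NJ flavor (steps ``a/b/g``) or Motzkin (``u/d/h``)."""

    alphabet: str  # "nj" or "motzkin"
    steps: tuple[str, ...]
    start: tuple[int, int]

    def step_vectors(self):
        table = NJ_STEPS if self.alphabet == "nj" else MOTZKIN_STEPS
        return [table[s] for s in self.steps]

    def points(self) -> list[tuple[int, int]]:
        pts = [self.start]
        for dx, dy in self.step_vectors():
            x, y = pts[-1]
            pts.append((x + dx, y + dy))
        return pts

    @property
    def end(self) -> tuple[int, int]:
        return self.points()[-1]

    def __str__(self) -> str:
        return "".join(self.steps)


# ---------------------------------------------------------------------------
# the Motzkin triangle
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _motzkin_entry(k: int, j: int) -> int:
    if j < 0 or j > k:
        return 0
    if k == 0:
        return 1
    return (
        _motzkin_entry(k - 1, j - 1)
        + _motzkin_entry(k - 1, j)
        + _motzkin_entry(k - 1, j + 1)
    )


def motzkin(k: int, j: int) -> int:
    """Motzkin triangle entry: partial Motzkin paths of length *k* ending at level *j*."""
    if k < 0 or j < 0 or j > k:
        raise ValueError(f"need 0 <= j <= k, got k={k}, j={j}")
    return _motzkin_entry(k, j)


def motzkin_closed_form(k: int, j: int) -> int:
    """Binomial closed form for the triangle entry (independent of the recursion).

    ``M(k, j) = sum_i C(k, i) [ C(k-i, (k+j-i)/2) - C(k-i, (k+j-i+2)/2) ]``
    with the convention that a binomial vanishes when its lower parameter is
    not a nonnegative integer (or exceeds the top).
    """

    def b(top: int, bottom2: int) -> int:
        # binomial with doubled bottom parameter: C(top, bottom2 / 2)
        if bottom2 % 2 or bottom2 < 0 or bottom2 // 2 > top:
            return 0
        return comb(top, bottom2 // 2)

    if j < 0 or j > k:
        raise ValueError("need 0 <= j <= k")
    total = 0
    for i in range(k + 1):
        total += comb(k, i) * (b(k - i, k + j - i) - b(k - i, k + j - i + 2))
    return total


def motzkin_triangle(kmax: int) -> list[list[int]]:
    """Rows 0..kmax of the plain Motzkin triangle."""
    return [[motzkin(k, j) for j in range(k + 1)] for k in range(kmax + 1)]


def motzkin_number(k: int) -> int:
    """The k-th Motzkin number (paths returning to the axis)."""
    return motzkin(k, 0)


def catalan(k: int) -> int:
    return comb(2 * k, k) // (k + 1)


# ---------------------------------------------------------------------------
# NJ paths
# ---------------------------------------------------------------------------

_NJ_ENDS = {(2, 1), (1, 2), (0, 3)}


def enumerate_nj_paths(n: int) -> list[LatticePath]:
    """All NJ paths for *n* taxa (length ``n - 4`` from ``(n - 2, 1)``).

    The forced first alpha step (star tree to first cherry) is implicit.
    Steps keep the stem count nonnegative and the bouquet count at least 1.
    """
    if n < 4:
        raise ValueError("NJ paths need n >= 4")
    start = (n - 2, 1)
    length = n - 4
    out: list[LatticePath] = []

    def rec(pos: tuple[int, int], steps: tuple[str, ...]) -> None:
        if len(steps) == length:
            if pos in _NJ_ENDS:
                out.append(LatticePath("nj", steps, start))
            return
        l, r = pos
        if l >= 2:
            rec((l - 2, r + 1), steps + ("a",))
        if r >= 2:
            rec((l, r - 1), steps + ("b",))
        if l >= 1:
            rec((l - 1, r), steps + ("g",))

    rec(start, ())
    return out


def nj_path_count(n: int) -> int:
    """Number of NJ paths for *n* taxa: the Motzkin triangle entry ``M(n-3, 1)``."""
    if n < 4:
        raise ValueError("NJ paths need n >= 4")
    return motzkin(n - 3, 1)


def nj_to_motzkin(p: LatticePath) -> LatticePath:
    """Map an NJ path to its partial Motzkin path (translated to start at (0, 0))."""
    if p.alphabet != "nj":
        raise ValueError("expected an NJ path")
    _check_nj(p)
    return LatticePath("motzkin", tuple(_NJ_TO_MOTZKIN[s] for s in p.steps), (0, 0))


def motzkin_to_nj(p: LatticePath, n: int) -> LatticePath:
    """Inverse of :func:`nj_to_motzkin` for the *n*-taxon starting point."""
    if p.alphabet != "motzkin":
        raise ValueError("expected a Motzkin path")
    q = LatticePath("nj", tuple(_MOTZKIN_TO_NJ[s] for s in p.steps), (n - 2, 1))
    _check_nj(q)
    return q


def _check_nj(p: LatticePath) -> None:
    for (l, r) in p.points():
        if l < 0 or r < 1:
            raise ValueError(f"invalid NJ path {p}: reaches ({l}, {r})")
    if p.end not in _NJ_ENDS:
        raise ValueError(f"invalid NJ path {p}: ends at {p.end}")


# ---------------------------------------------------------------------------
# weighted triangle and Phi(n)
# ---------------------------------------------------------------------------


def weights(s: int, j: int, n: int) -> tuple[int, int, int]:
    """Step multiplicities ``(a, b, c)`` at triangle position (s, j) for n taxa.

    ``a`` counts stem-pair joins ``C(n-s-j-2, 2)``, ``b`` bouquet-pair joins
    ``C(j+1, 2)``, ``c`` mixed joins ``(n-s-j-2)(j+1)``; zero outside
    ``0 <= s <= n - 4``, ``0 <= j <= s``.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not (0 <= s <= n - 4 and 0 <= j <= s):
        return (0, 0, 0)
    stems = n - s - j - 2
    bouquets = j + 1
    if stems < 0:  # position unreachable: no stems left
        stems = 0
    return (comb(stems, 2), comb(bouquets, 2), stems * bouquets)


def weighted_triangle(n: int) -> list[list[int]]:
    """The weighted Motzkin triangle whose terminal row sums to Phi(n).

    Row ``s`` holds ``M[s][j]`` for ``0 <= j <= s``; the seed ``M[0][0] =
    C(n, 2)`` absorbs the forced first join, and
    ``M[s+1][j] = a(s, j-1) M[s][j-1] + c(s, j) M[s][j] + b(s, j+1) M[s][j+1]``.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    rows = [[comb(n, 2)]]
    for s in range(n - 4):
        prev = rows[-1]
        nxt = []
        for j in range(s + 2):
            total = 0
            if j - 1 >= 0 and j - 1 < len(prev):
                a, _, _ = weights(s, j - 1, n)
                total += a * prev[j - 1]
            if j < len(prev):
                _, _, c = weights(s, j, n)
                total += c * prev[j]
            if j + 1 < len(prev):
                _, b, _ = weights(s, j + 1, n)
                total += b * prev[j + 1]
            nxt.append(total)
        rows.append(nxt)
    return rows


def phi(n: int, method: str = "formula") -> int:
    """Number of agglomerated trees on *n* taxa.

    ``method`` selects the route: the product-of-binomials closed form
    (``"formula"``), the weighted Motzkin triangle (``"triangle"``), or the
    exhaustive execution enumeration (``"brute"``, n <= 8).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if method == "formula":
        out = 1
        for m in range(4, n + 1):
            out *= comb(m, 2)
        assert out == n * factorial(n - 1) ** 2 // (3 * 2 ** (n - 1))
        return out
    if method == "triangle":
        last = weighted_triangle(n)[-1]
        return sum(last[:3])
    if method == "brute":
        return brute_force_phi(n)
    raise ValueError(f"unknown method {method!r}")


def cone_count(n: int) -> int:
    """Number of distinct NJ outputs: ``Phi(n) / 2`` (tied pairs of trees)."""
    p = phi(n)
    assert p % 2 == 0
    return p // 2


def double_factorial(m: int) -> int:
    out = 1
    while m > 1:
        out *= m
        m -= 2
    return out


def num_labeled_topologies(n: int) -> int:
    """``(2n - 5)!!`` labeled unrooted binary trees on n taxa."""
    if n < 3:
        raise ValueError("need n >= 3")
    return double_factorial(2 * n - 5)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_agglomerated_trees(n: int) -> Iterator[str]:
    """Canonical ordered-Newick strings of every possible NJ execution.

    Exhaustive DFS over all ``C(k, 2)`` joins at every step, from the star on
    ``n`` taxa down to three boughs.  Each execution yields a distinct
    agglomerated tree; guarded to ``n <= 8`` (529,200 executions).
    """
    if not 4 <= n <= 8:
        raise ValueError("brute force supported for 4 <= n <= 8 only")
    taxa = [chr(ord("a") + i) for i in range(n)]
    # bough = (canonical subtree string, min taxon)
    boughs = tuple((t, t) for t in taxa)

    def rec(bs: tuple, step: int) -> Iterator[str]:
        if len(bs) == 3:
            parts = sorted(bs, key=lambda x: x[1])
            yield "(" + ",".join(p[0] for p in parts) + ")"
            return
        k = len(bs)
        for i in range(k):
            si, mi = bs[i]
            for j in range(i + 1, k):
                sj, mj = bs[j]
                if mi < mj:
                    merged = (f"{step}({si},{sj})", mi)
                else:
                    merged = (f"{step}({sj},{si})", mj)
                rest = bs[:i] + bs[i + 1 : j] + bs[j + 1 :] + (merged,)
                yield from rec(rest, step + 1)

    yield from rec(boughs, 1)


def brute_force_phi(n: int) -> int:
    """Count distinct agglomerated trees by exhaustive execution (oracle)."""
    seen = set(brute_force_agglomerated_trees(n))
    return len(seen)
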