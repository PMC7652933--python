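"""NJ cones: H-representations and Monte-Carlo spherical fractions.

Every decision neighbor joining makes is a comparison of two Q-criterion
values, and both Q and the reduction step are linear in the input, so the set
of dissimilarity maps that reproduce a fixed execution transcript is a
polyhedral cone in ``R^(C(n,2))``.  This module derives those cones
explicitly (each inequality pushed back to original coordinates through the
composition of reduction maps, with exact rational coefficients) and
estimates their spherical fractions by uniform sampling of the intersection
of the unit ball with the positive orthant.  Because the two agglomerated
trees of a final-step tie pair share one cone, per-cone fractions are policy
independent, while per-tree fractions expose the representative bias of a
tie-breaking policy.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import nj_core
from .nj_core import DissimilarityMap, ExecutionTranscript, nj_run
from .trees import default_taxa, serialize

__all__ = [
    "ConeH",
    "ConeTally",
    "cone_of",
    "sample_input",
    "estimate_volumes",
    "compare_policies",
]


# ---------------------------------------------------------------------------
# H-representation
# ---------------------------------------------------------------------------


@dataclass
class ConeH:
    """Half-space description of one NJ cone.

    ``inequalities`` is an ``(m, d)`` float array with ``d = C(n, 2)``; a map
    ``D`` (flattened on ``coords``) lies in the cone iff every row dotted
    with ``D`` is ``<= 0``.  ``tie_equality`` is the final-step identity
    ``Q(pair) - Q(complement)``, which vanishes on all of input space.
    ``exact_inequalities`` carries the same rows as exact rationals.
    """

    n: int
    taxa: tuple
    coords: tuple  # C(n,2) taxon pairs, lexicographic
    tree_pair: tuple  # canonical ordered-Newick strings of the two tied trees
    inequalities: np.ndarray
    tie_equality: np.ndarray
    exact_inequalities: Optional[list] = field(default=None, repr=False)
    exact_tie: Optional[list] = field(default=None, repr=False)

    def flatten(self, D: DissimilarityMap) -> np.ndarray:
        return np.array(
            [float(D.d[a][b]) for a, b in self.coords], dtype=float
        )

    def contains(self, D: Union[DissimilarityMap, np.ndarray], eps: float = 1e-9) -> bool:
        x = D if isinstance(D, np.ndarray) else self.flatten(D)
        scale = max(1.0, float(np.abs(x).max()))
        return bool((self.inequalities @ x <= eps * scale).all())

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "taxa": list(self.taxa),
            "coordinates": [list(p) for p in self.coords],
            "tree_pair": list(self.tree_pair),
            "inequalities": self.inequalities.tolist(),
            "tie_equality": self.tie_equality.tolist(),
        }


def cone_of(tr: ExecutionTranscript, exact: bool = True) -> ConeH:
    """H-representation of the cone of inputs reproducing transcript *tr*.

    For each step with ``k`` boughs this emits the ``C(k, 2) - 1``
    comparisons ``Q(chosen) <= Q(other)`` in original coordinates; at the
    final four-bough step the comparison against the complement pair is an
    identity (the analytic tie) and is recorded separately as
    ``tie_equality`` instead of as an inequality.
    """
    taxa = sorted(tr.taxa)
    n = len(taxa)
    coords = tuple(itertools.combinations(taxa, 2))
    d = len(coords)
    pos = {frozenset(p): i for i, p in enumerate(coords)}
    zero = Fraction(0)

    # linear form of each active-pair entry in original coordinates
    V: dict[frozenset, list] = {}
    for p, i in pos.items():
        v = [zero] * d
        v[i] = Fraction(1)
        V[p] = v
    active = list(tr.taxa)

    def qvec(a, b) -> list:
        k = len(active)
        out = [x * (k - 2) for x in V[frozenset((a, b))]]
        for c in active:
            if c != a:
                out = [o - x for o, x in zip(out, V[frozenset((a, c))])]
            if c != b:
                out = [o - x for o, x in zip(out, V[frozenset((b, c))])]
        return out

    rows: list[list] = []
    tie_row: Optional[list] = None
    events = list(tr.events)
    if len(events) != n - 3:
        raise ValueError("incomplete transcript")
    for e in events:
        k = len(active)
        a, b = e.pair
        q_ab = qvec(a, b)
        is_final = k == 4
        comp = None
        if is_final:
            comp_ids = [x for x in active if x not in (a, b)]
            comp = frozenset(comp_ids)
            tie_row = [x - y for x, y in zip(q_ab, qvec(*comp_ids))]
        for c, cc in itertools.combinations(active, 2):
            if {c, cc} == {a, b}:
                continue
            if is_final and frozenset((c, cc)) == comp:
                continue
            rows.append([x - y for x, y in zip(q_ab, qvec(c, cc))])
        # reduction: new bouquet entries in original coordinates
        dab = V[frozenset((a, b))]
        u = e.new_id
        half = Fraction(1, 2)
        for c in active:
            if c in (a, b):
                continue
            vac = V[frozenset((a, c))]
            vbc = V[frozenset((b, c))]
            V[frozenset((c, u))] = [
                (x + y - z) * half for x, y, z in zip(vac, vbc, dab)
            ]
        active = [x for x in active if x not in (a, b)] + [u]

    t1, t2 = nj_core.trees_from_transcript(tr)
    cone = ConeH(
        n=n,
        taxa=tuple(taxa),
        coords=coords,
        tree_pair=tuple(sorted((serialize(t1), serialize(t2)))),
        inequalities=np.array([[float(x) for x in r] for r in rows], dtype=float),
        tie_equality=np.array([float(x) for x in tie_row], dtype=float),
        exact_inequalities=rows if exact else None,
        exact_tie=tie_row if exact else None,
    )
    return cone


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_input(
    n: int, rng: Union[int, np.random.Generator, None] = None
) -> DissimilarityMap:
    """A dissimilarity map uniform in (unit ball) ∩ (positive orthant).

    A standard normal direction with coordinates folded to be nonnegative is
    uniform on the sphere patch in the orthant; scaling by ``U^(1/d)`` makes
    the point uniform in the solid region (``d = C(n, 2)``).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = _sample_point(n, rng)
    return _as_map(n, x)


def _sample_point(n: int, rng: np.random.Generator) -> np.ndarray:
    d = n * (n - 1) // 2
    g = np.abs(rng.standard_normal(d))
    g /= np.linalg.norm(g)
    return g * rng.uniform() ** (1.0 / d)


def _as_map(n: int, x: np.ndarray) -> DissimilarityMap:
    taxa = default_taxa(n)
    d: dict = {a: {} for a in taxa}
    it = iter(x)
    for a, b in itertools.combinations(taxa, 2):
        v = float(next(it))
        d[a][b] = v
        d[b][a] = v
    index = {a: i for i, a in enumerate(taxa)}
    baggage = {a: frozenset((a,)) for a in taxa}
    return DissimilarityMap(list(taxa), index, d, baggage, n)


# ---------------------------------------------------------------------------
# Monte-Carlo volume estimation
# ---------------------------------------------------------------------------


@dataclass
class ConeTally:
    """Sample counts from a Monte-Carlo cone-volume run.

    ``tree_counts`` tallies the policy-chosen representative per agglomerated
    tree (canonical ordered Newick); ``cone_counts`` tallies the unordered
    tie pair, i.e. the cone, independent of the policy.
    """

    n: int
    samples: int
    policy: str
    seed: Optional[int]
    tree_counts: Counter = field(default_factory=Counter)
    cone_counts: Counter = field(default_factory=Counter)

    @property
    def fractions_defined(self) -> bool:
        return self.samples > 0

    def tree_fractions(self) -> dict:
        if not self.fractions_defined:
            return {}
        return {t: c / self.samples for t, c in self.tree_counts.items()}

    def cone_fractions(self) -> dict:
        if not self.fractions_defined:
            return {}
        return {t: c / self.samples for t, c in self.cone_counts.items()}

    def standard_error(self, count: int) -> float:
        """Binomial standard error of a fraction with this sample size."""
        if not self.fractions_defined:
            return float("nan")
        p = count / self.samples
        return math.sqrt(p * (1 - p) / self.samples)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (t1, t2), c in sorted(self.cone_counts.items()):
            rows.append(
                {
                    "tree_1": t1,
                    "tree_2": t2,
                    "count_1": self.tree_counts.get(t1, 0),
                    "count_2": self.tree_counts.get(t2, 0),
                    "cone_count": c,
                    "cone_percent": 100 * c / self.samples if self.samples else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def estimate_volumes(
    n: int,
    samples: int,
    policy: str = "lexicographic",
    seed: Union[int, np.random.Generator, None] = None,
) -> ConeTally:
    """Estimate per-tree and per-cone spherical fractions by sampling.

    Draws *samples* maps uniform in the orthant ball, runs NJ on each under
    the given final-step policy, and tallies the chosen representative (per
    agglomerated tree) and the unordered tie pair (per cone).
    """
    if not 4 <= n <= 8:
        raise ValueError("volume estimation supported for 4 <= n <= 8")
    if samples < 0:
        raise ValueError("samples must be >= 0")
    if policy not in nj_core.POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    # separate streams: the sampled points depend only on the seed, not on
    # how many draws the tie-breaking policy consumes, so per-cone counts are
    # identical across policies run with the same seed
    base = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rng_pts, rng_pol = base.spawn(2)
    tally = ConeTally(
        n=n,
        samples=samples,
        policy=policy,
        seed=seed if isinstance(seed, int) else None,
    )
    for _ in range(samples):
        D = _as_map(n, _sample_point(n, rng_pts))
        (t1, t2), tr = nj_run(D, policy=policy, rng=rng_pol)
        s1, s2 = serialize(t1), serialize(t2)
        chosen = s1 if tr.chosen == tr.final_pair else s2
        tally.tree_counts[chosen] += 1
        tally.cone_counts[tuple(sorted((s1, s2)))] += 1
    return tally


def compare_policies(
    n: int,
    samples: int,
    seed: Union[int, None] = None,
) -> pd.DataFrame:
    """Per-cone comparison of the three tie-breaking policies.

    One row per cone (tie pair of agglomerated trees); for each policy the
    percentage of samples assigned to each of the two representatives and
    their sum.  Row sums agree across policies up to Monte-Carlo error, since
    the policy only redistributes mass within a cone.
    """
    tallies = {
        p: estimate_volumes(n, samples, policy=p, seed=seed)
        for p in nj_core.POLICIES
    }
    cones = sorted(set().union(*(t.cone_counts for t in tallies.values())))
    rows = []
    for t1, t2 in cones:
        row: dict = {"tree_1": t1, "tree_2": t2}
        for p, tally in tallies.items():
            c1 = tally.tree_counts.get(t1, 0)
            c2 = tally.tree_counts.get(t2, 0)
            row[f"{p}_1"] = 100 * c1 / samples if samples else float("nan")
            row[f"{p}_2"] = 100 * c2 / samples if samples else float("nan")
            row[f"{p}_sum"] = row[f"{p}_1"] + row[f"{p}_2"]
        rows.append(row)
    return pd.DataFrame(rows)
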