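# Methods

## The algorithm and what is recorded

`nj_core.nj_run` implements classical neighbor joining on a symmetric
nonnegative dissimilarity map with zero diagonal.  At each step with `k`
active boughs it evaluates the Q-criterion
`Q(a,b) = (k-2) D(a,b) - Σ_c D(a,c) - Σ_c D(b,c)` (sums over all boughs,
including `a` and `b`; the self-terms cancel), joins the minimizing pair,
and propagates distances with the standard reduction
`D(c,u) = (D(a,c) + D(b,c) - D(a,b)) / 2`.  Branch lengths are deliberately
not estimated: the object under study is the execution record, and the
reduction formula is used only to drive later decisions.

Arithmetic is generic over the entry type.  Floats take the fast path;
`fractions.Fraction` entries are processed exactly, which the final-tie
identity test relies on.

### The final-step tie

When four boughs remain, expanding Q shows `Q(a,b) = Q(c,d)` identically
for every complementary pair of pairs — for *any* symmetric map, additive
or not.  A floating-point argmin would "resolve" this identity by rounding
noise and inherit whatever bias the arithmetic order induces, so the tie is
handled structurally: the minimizing pair is found, its complement is taken
as the tied partner, and the equality is asserted (exactly for rational
entries, to 1e-6 relative for floats).  Both tied agglomerated trees are
returned; a policy then selects a representative:

* `lexicographic` — the pair containing the lowest-index bough (index =
  creation order: input taxa in input order, then bouquets).  Deterministic,
  consumes no randomness.
* `uniform` — one Bernoulli(1/2) draw per run, nothing else, so a seeded
  run is reproducible draw-for-draw.
* `baggage` — the pair whose boughs carry more original taxa in total;
  the two sides always sum to `n`, so ties occur only at `|A|+|B| = n/2`,
  where a uniform draw decides.

Pre-final ties (several pairs within 1e-9 relative of the minimum) are
broken lexicographically on index pairs.  For generic (continuously
sampled) input they occur with probability zero; the convention only
matters for hand-crafted symmetric inputs, where determinism is worth more
than any particular choice.

## Trees, orders, canonical form

`trees` stores an agglomerated tree rooted at its central (∞) node: three
subtrees at the root, two at every labeled node, labels `1..n-3` strictly
decreasing toward the leaves.  The ASCII ordered-Newick grammar puts each
label immediately before its parenthesis (`(3(c,1(a,b)),2(e,f),d)`); the
central node is unlabeled.  Taxon names may not start with a digit or
contain `( ) , ;`, which keeps the grammar unambiguous.  The canonical
serialization sorts every node's children by smallest descendant taxon;
on exhaustive enumeration at n ≤ 6 it is verified injective, so canonical
strings serve as set keys everywhere (brute-force counts, cone tallies).

Topologies (orders erased) compare by their nontrivial split sets, so
equality is independent of internal vertex bookkeeping.  `enumerate_orders`
tries every internal vertex as the central node and enumerates decreasing
labelings as linear extensions of the rooted internal forest — exhaustive
and intended for n ≤ ~10, which covers every use here.  Topology
generation is the textbook leaf-insertion recursion over `(2n-5)!!` trees;
unlabeled shape counting canonicalizes each tree by the minimum AHU string
over all internal rootings.

## Counting: Motzkin machinery

`combinatorics` is exact integer arithmetic throughout (`math.comb`,
Python big ints); no floats touch any count.  NJ paths use the step
alphabet α=(-2,1), β=(0,-1), γ=(-1,0) on bough vectors (stems, bouquets),
start at `(n-2, 1)` with the forced first α implicit, keep the bouquet
count ≥ 1, and end at `(2,1)`, `(1,2)` or `(0,3)`.  The linear map
`[[-1,-1],[0,1]]` carries them to partial Motzkin paths; both directions
are implemented and round-trip tested.  The Motzkin triangle is computed by
its three-term recursion and cross-checked against the binomial closed form
(k ≤ 20) and the Motzkin–Catalan sum identities (k ≤ 12).

For Φ(n), the weighted triangle assigns step multiplicities
`a = C(stems,2)`, `b = C(bouquets,2)`, `c = stems·bouquets` at each lattice
position, with the seed `M[0][0] = C(n,2)` absorbing the forced first join;
Φ(n) is the sum of the three terminal entries.  One convention is worth
noting: the weight-sum identity `a+b+c = C(n-s-1, 2)` holds at *reachable*
positions (nonnegative stem count).  Positions with `j ≤ s` but
`n-s-j-2 < 0` are unreachable — no path attains them, the triangle entry
is zero there — and the implementation clamps their stem count to zero
rather than evaluating generalized binomials; tests check the identity over
the reachable range.  The telescoping row-sum lemma (factor `C(s+2,2)` with
the parity-dependent truncation bound) is verified numerically for
n = 6..12.

`brute_force_phi` is the independent oracle: a DFS over every possible join
sequence (all `C(k,2)` choices at each level) that collects canonical
strings.  Each execution yields a distinct agglomerated tree, and the count
matches formula and triangle for n = 4..8.  The n = 8 case enumerates
529 200 executions in a couple of seconds.

## Cones and Monte-Carlo volumes

Both Q and the reduction are linear in the input, so each active-pair entry
at any step is a known linear functional of the original `C(n,2)`
coordinates (lexicographic over sorted taxon pairs).  `cone_of` replays a
transcript symbolically with exact dyadic-rational coefficients, emitting
`C(k,2) - 1` inequalities `Q(chosen) ≤ Q(other)` per step; at the final
step the comparison against the complement is the tie identity — the zero
functional — and is stored separately rather than as a (vacuous)
inequality.  Membership checks use a 1e-9 relative tolerance.

`sample_input` draws points uniform in (unit ball) ∩ (positive orthant) of
`R^(C(n,2))`: fold a standard normal direction into the orthant by absolute
value, scale by `U^(1/d)`.  This is exact by the spherical symmetry of the
Gaussian and avoids rejection, whose acceptance rate `2^-d` would be
hopeless already at n = 5 (d = 10).  Because Q is homogeneous, the radius
never changes the output — one of the property tests.

`estimate_volumes` tallies, per sample, the policy's representative (per
agglomerated tree) and the unordered tie pair (per cone).  The generator is
split into two independent child streams, one for sample points and one for
policy draws, so runs with the same seed see the *identical* point set
under every policy and per-cone counts are exactly policy-invariant; only
the within-cone split varies.  Fractions come with binomial standard
errors; an empty run is flagged rather than dividing by zero.

### Study conditions and what the tests show

The default simulation matches the published design — uniform sampling in
the orthant ball — at 100 000 samples in the acceptance checks (the
published run used 1 000 000; 10⁵ keeps a desk-scale runtime while the
binomial standard errors, ≈ 0.15 points for a 33% cone and ≈ 0.04 points
for a 1.7% tree, sit comfortably inside the 0.5- and 0.3-point bands being
checked; `--samples` overrides).  Uniform orthant-ball sampling weights
every direction of input space equally; it emulates no evolutionary model,
so these experiments measure the *geometry* of the NJ partition (cone
sizes and representative bias), not performance on tree-like data.
Consistency on additive data is tested separately: maps generated from
random binary topologies (uniform by random leaf insertion) with branch
lengths uniform in (0.1, 1), on which NJ must recover the generating
topology exactly.

Reference implementations resolve the final tie with floating-point
argmins, and published tallies show the resulting artifacts (a
lexicographic-intended run leaving ~4% of mass on the "wrong"
representatives, small residuals under the baggage rule).  Those artifacts
are implementation noise, not mathematics, and this package intentionally
does not reproduce them: with analytic tie detection, deterministic
policies concentrate all of a cone's mass on one representative.

## Known limitations

* Enumeration (`enumerate_orders`, `enumerate_topologies`,
  `brute_force_phi`) and volume estimation are exhaustive/per-sample and
  sized for small n (≤ 8–10); the closed form and triangle scale to any n.
* No V-representation (extreme rays) of the cones is attempted, and no
  closed form for the number of orders on a *fixed* topology is known —
  only the brute-force count is provided.
* Branch lengths, BIONJ-style weighting, and O(n²) accelerations are out
  of scope.
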