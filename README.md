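# njcones

Neighbor joining (NJ) is the workhorse distance-based method of molecular
phylogenetics: given a dissimilarity map `D` on `n` taxa it repeatedly joins
the pair of "boughs" minimizing the Q-criterion

    Q(a,b) = (k-2) D(a,b) - Σ_c D(a,c) - Σ_c D(b,c)

and propagates distances with `D(c,u) = (D(a,c) + D(b,c) - D(a,b)) / 2`
until three boughs remain.  Because every decision is a linear comparison,
NJ partitions the input space `R^(n choose 2)` into polyhedral cones — one
per possible *execution*, not per output topology.  `njcones` is a toolkit
for studying that partition.  It is aimed at people analyzing algorithmic
bias in distance methods rather than at routine tree building (it
deliberately computes no branch lengths).

Three things make an NJ execution subtle to count:

* **Agglomeration orders.**  Recording the step at which each internal node
  is created labels the `n-2` internal nodes with `{∞, 1, ..., n-3}` so that
  labels decrease from the central node to every leaf.  A binary tree with
  such a labeling (an *agglomerated tree*, written in *ordered Newick* such
  as `(3(c,1(a,b)),2(e,f),d)`) is the faithful record of one execution.
* **The forced final tie.**  With four boughs left, `Q` is always minimized
  simultaneously by a pair and its complement — an exact algebraic identity,
  not a numerical accident — so every input yields *two* agglomerated trees
  sharing one topology, and implementations silently pick a representative.
  `njcones` detects the tie analytically and supports three representative
  policies: `lexicographic`, `uniform`, and `baggage` (join the side
  carrying more taxa).
* **Counting by lattice paths.**  Tracking only the numbers of leaf boughs
  and internal boughs turns executions into lattice paths that biject with
  partial Motzkin paths; weighting the steps by the number of joins they
  represent gives the exact census

      Φ(n) = C(n,2) C(n-1,2) ... C(4,2) = n ((n-1)!)² / (3 · 2^(n-1))

  agglomerated trees (so `Φ(n)/2` distinct NJ outputs): 6, 60, 900, 18 900,
  529 200 for n = 4..8.  The package computes Φ three independent ways
  (closed form, weighted Motzkin triangle, exhaustive execution
  enumeration) and exposes the cone H-representations plus a Monte-Carlo
  estimator of each cone's spherical fraction.

## Worked example

`example.phy` is a 5-taxon PHYLIP square matrix (taxa a..e, with
D(b,c) = 10 the only two-digit entry):

```
5
a 0 3 5 4 7
b 3 0 10 3 7
c 5 10 0 6 5
d 4 3 6 0 2
e 7 7 5 2 0
```

```sh
$ njcones nj --input example.phy --policy baggage
ordered_newick_1	(1(a,b),2(c,e),d)
ordered_newick_2	(2(1(a,b),d),c,e)
representative	(((a,b),d),c,e);
```

NJ first joins the cherry `(a,b)` (step ①).  At the final step the tie is
between joining `(c,e)` and joining `d` with the `(a,b)` bouquet: the two
ordered Newick lines are those two tied agglomerated trees (identical
unrooted topology, different orders).  The baggage policy joins the side
carrying more taxa, so the representative is `((d,(a,b)),c,e)` — printed
here in canonical child order.  The library equivalent is
`nj_run(D, policy="baggage")`.

Counting the output space for six taxa:

```sh
$ njcones count --n 6
taxa	6
labeled_topologies	105
nj_outputs	450
ordered_newick_strings	900
```

and the five NJ lattice paths behind those 900 orders (`a`/`b`/`g` steps,
the forced first join implicit; `ag` is the α-α-γ execution):

```sh
$ njcones paths --n 6
aa
ab
ag
ga
gg
total	5
```

Other subcommands: `enumerate` (agglomeration orders on a given topology),
`simulate` (Monte-Carlo cone volumes, CSV), `cone` (H-representation of the
cone of an ordered Newick tree, JSON).

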