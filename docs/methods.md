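# Methods

## The fingerprint model

The package treats the repeatome as a bag of repeat families shared, to a
varying degree, among the studied species.  Pooled comparative clustering
groups reads family-wise; within a cluster, the number of similarity edges
between reads of species *a* and *b* measures how similar the two species'
copies of that family still are.  The observed/expected ratio
*r<sub>ab</sub> = m<sub>ab</sub>/exp<sub>ab</sub>* removes the dependence on
how many reads each species happens to contribute to the cluster;
*exp<sub>ab</sub> = 2E·q<sub>a</sub>q<sub>b</sub>* (diagonal
*E·q<sub>a</sub>²*) distributes the cluster's edge total *E* over species
pairs by the product of edge-endpoint proportions
*q<sub>a</sub> = (2m<sub>aa</sub> + Σ<sub>b≠a</sub> m<sub>ab</sub>)/(2E)*.
Because Σ*q* = 1, the expectations sum back to *E* exactly; this
conservation is asserted in the test suite for every cluster of every test
graph.  This product form is one concrete reading of "expected edges from
the proportions of edges per species pair"; it is adopted here because it is
the simplest form that is both symmetric and exactly conserving.

Each cluster matrix is turned into a dissimilarity by *d = 1/(v + 1)*.  The
+1 exists so that species pairs sharing a cluster but no direct edges map to
the finite maximum *d* = 1 rather than a division by zero; the transform is
strictly decreasing, so more shared similarity always means less distance.
(Descriptions of this step sometimes state the reverse order,
invert-then-add; only add-then-invert serves the stated purpose, and that
order is used throughout.)  Summing the inverted matrices over clusters
gives the master matrix — the repeatomic fingerprint.  Two downstream roles:

* **distance role (PCoA):** off-diagonal cells square-rooted, diagonal set
  to 0; classical scaling with negative eigenvalues reported, not corrected;
* **variable-table role (NJ, NeighborNet):** each species column (diagonal
  included, as informative intra-species signal) is one variable; Gower
  distance = mean over positive-range columns of |Δ|/range.

The inverse-genome-size read budget
*n<sub>i</sub> = N(1/G<sub>i</sub>)/Σ(1/G<sub>j</sub>)* (largest-remainder
rounding, exact total, optional per-species floor) counteracts the
self-interconnection bias of large genomes: with budgets proportional to
1/G, repeat-rich genomes contribute fewer reads and inter-species edges
become correspondingly more likely.  The harmonic form is the simplest one
satisfying the stated indirect proportionality while keeping the pooled
total exact; budgets are invariant to rescaling all genome sizes (exactly so
for power-of-two factors; an arbitrary factor can flip one
largest-remainder tie by ±1 read).

## Parameters that matter

| parameter | default | units / meaning |
|---|---|---|
| `min_identity` | 0.90 | minimum identity of a qualifying read overlap |
| `min_overlap_frac` | 0.55 | minimum overlap as a fraction of read length |
| `kmer` | 13 | seed k-mer length for candidate pair generation |
| `trim_to` | 100 | nt kept from each read |
| `resolution` | 1.0 | Louvain resolution |
| `min_cluster_size` | 2 | smallest read count for a reported cluster |
| `rdna_min_hit` | 0.01 | strict lower bound on annotation proportion for subsets |
| `bootstrap` | 1000 | cluster-resampling replicates |
| `floor` | 0 | minimum reads per species in budgeting |

The edge rule (90%/55%) defines what "similar" means and therefore which
divergences are visible at all: species whose repeat copies have diverged
beyond ~10% no longer share edges, their clusters become species-specific or
NA-ridden, and the method loses signal — the documented behavior at deep
taxonomic levels.  The k-mer seeding is the only approximation relative to
exhaustive all-pairs scoring: a qualifying alignment containing no exact
13-mer match can be missed (as with any seeded aligner); the test suite
verifies exact agreement with brute force at a seed length where candidate
generation is complete.

## The simulator: what it emulates, what it does not

`repeatfp.simulate` generates repeat families evolving by JC69 — per site,
Poisson(rate × branch length) substitution events, each to a uniformly
chosen different base, giving the closed-form divergence
*p = ¾(1 − e^(−4d/3))* asserted against simulation in the tests.  Tandem
families are emitted as concatenated monomer arrays (so reads cross monomer
junctions and 5S-like low-divergence satellites produce the characteristic
ring-shaped cluster graphs); dispersed families as independent copies.  Each
copy receives extra intra-genomic divergence (default 0.01 subs/site)
emulating imperfect homogenization.  Hybrids inherit each repeat copy from
the maternal pool with probability *w* (0.8 for Canina-type meiosis, where
the egg contributes four chromosome sets and the pollen one) and the hybrid
genome size interpolates the parents'.

Background (single-copy) reads are i.i.d. random sequence: at genome-skim
coverage the non-repetitive fraction essentially never overlaps itself, so
this models its one relevant property — contributing unclustered reads.  The
default 60% background fraction puts the "repetitive" read share near 40%,
the range typical of the plant genomes this method targets.

Not modeled: indels, recombination, concerted evolution dynamics, TE
insertion-site preferences, horizontal transfer, sequencing quality
profiles, paired ends.  Passing tests therefore demonstrate that the
*pipeline arithmetic and inference chain* are correct and that the method
recovers known structure under clean JC69 divergence; they do not
demonstrate robustness to the messier mutation processes of real repeatomes.

### Default study conditions

The default study (`simulate.default_study`) fixes six species of equal
genome size on the balanced cherry tree
`((A:0.01,B:0.01):0.015,(C:0.01,D:0.01):0.015,(E:0.01,F:0.01):0.015)` with
20 families: 14 dispersed 600-bp elements (30 copies), four 170-bp
satellites (60 copies), one 45S-like 400-bp array (40 copies) and one
5S-like 120-bp low-rate array (80 copies); 2000 error-free 100-nt reads per
species.  Branch lengths are chosen so that the deepest cross-species read
divergence (~7% including intra-genomic divergence) stays inside the 90%
edge threshold — a precondition of the method, since only shared clusters
carry signal.  The end-to-end tests run 20 replicates of this study (about
6 s each); scaled-down variants (200–800 reads/species) are used for unit
and smoke tests.

## Numerical and design choices

* **Overlap ceiling.** `ceil(0.55·100)` is evaluated with an epsilon guard:
  the float product is 55.000000000000007 and a naive ceiling would silently
  demand 56 nt.
* **Edge weight** = matches = overlap × identity of the best qualifying
  offset, strands merged into one undirected edge.
* **Louvain** is python-igraph's C implementation, seeded through Python's
  `random` module (igraph's default RNG) with state save/restore; cluster
  ids are assigned by decreasing size, ties by smallest member index.
  Modularity is recomputed independently and checked against networkx in the
  tests.  Edges cut by the partition belong to no cluster; per-cluster edge
  totals plus cut edges reconcile exactly with the graph total.
* **Cluster records** are only built for clusters of ≥2 reads; singletons
  are unclustered (non-repetitive) reads, and the "repetitive fraction"
  reported in logs and manifests is the share of reads in non-singleton
  clusters.
* **NA semantics.** An obs/exp cell is NA whenever its expectation is zero —
  ordinarily because a species has no reads in the cluster; the degenerate
  case of a species with reads but no incident edges is also NA (0/0).
  Filtering removes a cluster once, by the first matching reason in the
  order species-specific → contamination → NA; the report arithmetic
  (kept + removed = total) is tested over all eight predicate toggles.
  Optional NA imputation (off by default): `one_edge_equivalent` fills
  1/(1+E), `row_mean` the mean of the row's non-NA cells.
* **Edges-side analyses** keep NA-flagged clusters (edge counts are always
  defined), so the edges master typically sums more clusters than the obs
  master.
* **Summation order.** Master-matrix cells sum value-sorted addends, making
  the result independent of cluster order to the last ulp.
* **PCoA determinism.** Axis signs are fixed by making each axis's
  largest-magnitude loading positive; eigenvalues below 1e−10 of the
  spectrum's magnitude are not treated as positive axes.
* **NJ.** Studier–Keppler Q-criterion; ties broken by the lexicographically
  smallest pair of subtree labels, so output is invariant to input order;
  negative branch estimates are clamped to zero and the clamped total
  reported.
* **Bootstrap unit.** Whole clusters are resampled (the independent
  replication unit of the fingerprint); column resampling of the master
  table is available behind `unit="column"`.  Replicate draws index a
  canonical (byte-sorted) cluster ordering, so supports do not depend on
  list order.
* **NeighborNet.** Bryant–Moulton agglomeration (cluster selection by the NJ
  Q-criterion on average cluster distances, node selection by the analogous
  criterion over remaining clusters plus pair members, 3-node path reduction
  with the 2/3–1/3 distance updates), final ≤3 clusters closed into the
  cheapest cycle, reductions expanded in reverse; split weights by
  non-negative least squares over the circular splits, dropping weights
  below 1e−10.  On additive inputs this returns exactly the tree's splits
  with branch-length weights; on circular metrics it reproduces the input
  distances to NNLS precision.
* **Archive dialect.** Minimal well-formed HTML: two captioned tables
  (observed edges; observed/expected with literal `NA` tokens) plus an
  annotations table, one `dir_CL<n>/index.html` per cluster, and a
  `COMPARATIVE_ANALYSIS_COUNTS.csv`.  The parser locates tables by caption
  first, position second, and skips malformed pages with a logged warning.
  Floats are serialized at 17 significant digits, so write→parse round
  trips are bit-exact.

## Known limitations

* At shallow read depth the master matrix's diagonal (intra-species) terms
  are noisy, and because the Gower variable table retains the diagonal,
  range normalization can let that noise dominate: on the default study the
  Gower→NJ chain needs roughly the full 2000 reads/species to recover the
  topology reliably, even though the raw master matrix already ranks true
  sister pairs closest at a third of that depth.  The PCoA (distance-role)
  path is insensitive to the diagonal.
* Under the symmetric default tree the three cherry contrasts produce
  near-equal leading eigenvalues, so *which* contrast becomes PCoA axis 1 is
  unstable between replicates — the low-and-equal-variance-per-axis regime
  also seen in real ordinations of weakly structured groups.  Axis-1
  readouts (e.g. hybrid betweenness) consequently fail in a small minority
  of replicates even when the full-dimensional signal is correct; the split
  networks and Gower distances are the stabler readouts.
* Species diverged beyond the edge threshold contribute only NA/species-
  specific clusters and drop out of the obs-side analysis entirely;
  abundance-based (read-count) phylogenetics is out of scope — counts are
  exported in the archive but not analyzed.
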