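# Methods

## From scans to a signed network

One observation is a (day, scan, individual) row carrying either planar
metre coordinates or a directly recorded nearest neighbour (plus optionally
a nearest facility and a behaviour label). In coordinate mode the nearest
neighbour of each visible individual at each scan is the other visible
individual at minimum 2-D Euclidean distance; exact ties are broken towards
the smallest identifier so runs are reproducible. The relation is directed:
A's nearest neighbour need not reciprocate. Scans with fewer than two
visible individuals contribute nothing. Night scans can be dropped with a
clock-hour window (`filter_daylight`); scan→hour mapping defaults to uniform
spacing from a configured session start because field protocols state the
interval, not the anchoring.

Nearest-neighbour distance (NND) cut-offs reduce the influence of fixed
locations (territorial individuals are "nearest" to their fixed neighbours
without any social preference). Both field conventions are supported:
inclusive ("a maximum NND of 5 m", `<=`) and strict ("less than 1 m", `<`),
via a flag. NND summary statistics default to the population standard
deviation (divide by N); `ddof=1` switches to the sample convention.

## The association statistic

Counts are tallied into the directed I × I focal × neighbour matrix with a
structurally zero diagonal. Expected counts use the Pearson contingency
convention e = (row total × column total)/n. Because the diagonal is
structural, the plain product leaves a little expected mass on the diagonal
(so Σe over off-diagonal cells is slightly below n); an iterative-
proportional-fitting variant (`method="ipf"`) fits the off-diagonal table to
both margins exactly and makes Σ(o − e) vanish. The margins product is the
default because it is the standard chi-square convention and the IPF
correction is small at realistic sizes; both are exposed.

Cell evidence is the standardized residual SR = (o − e)/√e; cells with
e = 0 and o = 0 give SR = 0, and e = 0 with o > 0 is an error naming the
cell. Σ SR² over cells equals the Pearson chi-square statistic (verified in
tests against an independent implementation). Significance is strict
|SR| > 1.96: equality at the boundary is not significant — tie cases are
measure-zero in practice and the strictness is documented rather than
consequential. No multiple-testing correction is applied by default, the
tradition for these small exploratory sociograms; a Bonferroni option
adjusts the threshold over the off-diagonal cell count for users who want
it.

SR is computed on the *directed* matrix. An undirected dyad is significant
when either direction passes; the edge weight is the larger directed
residual, and the edge records which directions passed (one-way/two-way).
This directed-then-project rule is a documented design choice: whether
legacy matrix tools symmetrized first is not recoverable, and the
one-arrow/two-arrow distinction is behaviourally meaningful (who seeks
whom).

The simple ratio index is provided as the classical alternative:
(c[i,j] + c[j,i]) / (2 × scans with both members observed), so a dyad that
is mutually nearest in every joint scan scores 1. With full visibility it is
a constant rescaling of the symmetrized counts — identical rankings — which
is why the count matrix is the default input. When only per-individual
totals are available the joint count falls back to min(nᵢ, nⱼ), exact under
full visibility.

The identical machinery applies to the 2-mode individual × facility table
(no structural diagonal, so no correction subtleties).

## Network metrics

Metrics are computed on the unweighted undirected projection; SR weights are
carried for display and export only. Rationale: the printed node tables this
package mirrors are integers consistent with unweighted computation, and
unweighted metrics are robust to the residual scale.

* degree — incident edge count.
* betweenness — unnormalized Freeman betweenness over unordered pairs with
  fractional credit for tied geodesics.
* farness — sum of geodesic distances to all other nodes; every unreachable
  pair contributes a distance equal to the node count n (flag for the n − 1
  alternative). The n convention is adopted because it reproduces published
  worked values exactly (isolated node in a 15-node network: 14 × 15 = 210;
  four-node path component: endpoint 1+2+3+11×15 = 171, interior 169).
  Closeness is 1/farness.
* cutpoints — articulation nodes: removal increases the component count
  among the remaining nodes.
* blocks — biconnected components of each component with at least one edge,
  ordered deterministically by smallest member. Cutpoints belong to every
  block they delimit; isolated nodes to none.
* node table — one row per node plus an arithmetic-mean row; the means of
  the 0/1 cutpoint/block columns are proportions.
* density — edges / (n(n−1)/2) over all individuals, isolates included.

All four structural metrics are tested against independent oracles
(Floyd–Warshall distances, explicit geodesic enumeration, node-removal brute
force, igraph biconnectivity) on batches of random graphs.

Not every published node table is reproducible: one printed 9-horse table
(density 0.21 with mean degree 2.00) and one hen farness value (57 in an
8-node network) are inconsistent with any single directed/undirected
convention tried here; the bear table is fully consistent. The documented
convention is implemented and the discrepancy flagged rather than guessing
a legacy tool's internals.

## Stability

The Mantel statistic is the Pearson correlation over corresponding
off-diagonal cells; the null distribution permutes rows and columns of one
matrix jointly. The sampled p-value uses the +1 correction,
p = (1 + #extreme)/(1 + permutations), hence p ≥ 1/(permutations + 1); an
exact mode enumerates all n! permutations for n ≤ 8 and is tested against
an independent enumeration. The default tail is one-sided upper —
significantly *positive* correlation is what implies stability — with
two-sided and lower available. Permutations default to 10,000; the CLI
makes the seed mandatory.

Daily matrices are symmetrized (c + cᵀ) before correlating, since a day's
directed asymmetries are mostly sampling noise; a flag keeps the raw
directed tally. The series correlates consecutive day pairs plus first vs
last; the stability index averages the *consecutive* correlations only,
excluding first-vs-last. That exclusion is validated by recomputation: the
published cross-species stability column is recovered (to its printed
2-decimal rounding) from the published consecutive-day series only when
first-vs-last is excluded.

## Comparison report

Per group: positive density, negative density, their sum, the positive
share of total density in percent, and the stability index. All quantities
are computed unrounded and rounded only at rendering (2 decimals) — the
published table this mirrors visibly rounded after computing, e.g. printed
components 0.21 + 0.31 beside a printed total 0.51.

## Synthetic herds

The generator emulates multi-day scan sampling of an identified group in a
rectangular arena. Positions are independent snapshots rather than
trajectories: at ~10-minute scan intervals pen and pasture animals re-mix
between scans, so near-independent draws are defensible and keep the
generator analyzable.

* `home_centers="uniform"` (default): every position is an i.i.d. uniform
  draw over the arena — ideal free mixing. Under this null the NN counts
  are exchangeable across dyads and the flagged-cell fraction sits at the
  nominal tail (measured ≈ 5.3% vs 5% over 20 replicates at 20 individuals,
  5 × 100 scans). An earlier clipped-Gaussian "roaming" default left real
  per-individual spatial preference and badly inflated the null flag rate;
  free mixing is therefore the default and homes are opt-in.
* `home_centers="random"` or an explicit array: fixed centres plus
  isotropic Gaussian noise (`home_sd`, metres), clipped to the arena. Small
  `home_sd` gives territorial individuals (flagged as such in the ground
  truth when below 10% of the arena's larger side) whose NN network
  reflects geography — the confound the NND cut-off exists to mitigate.
* affinity pair (i, j, strength): with probability = strength per scan the
  lower-indexed member relocates to its partner's position plus a 1 m
  Gaussian offset. This reproduces the key signature — inflated mutual-NN
  frequency — without simulating locomotion.
* avoidance pair (i, j, min_distance): positions re-sampled (≤ 20 attempts)
  until the pair is at least min_distance apart; failures are counted in
  the dataset metadata, not fatal.
* facilities are fixed named points; the nearest one is recorded per
  visible individual. Visibility is i.i.d. Bernoulli per (scan, individual)
  with `p_invisible` (default 0.05).

Identical seeds give byte-identical datasets. Defaults (50 × 50 m arena,
5 days × 100 scans, 20 individuals, 10 m avoidance distance) are the
package's reference study conditions for recovery experiments.

What the generator does *not* emulate: autocorrelated trajectories,
dominance hierarchies, diurnal activity rhythms, demographic turnover, and
observation error in identity or position. Passing recovery tests therefore
show that the inference chain is correct under clean scan-sampling
assumptions, not that it is robust to real-world tracking noise.

## Known limitation: margin distortion under strong bonded pairs

Recovery experiments with many strong affinity pairs expose an intrinsic
bias of the margins-product (equivalently IPF — verified to give identical
flags here) expected counts: members of strong pairs direct ~90% of their
NN nominations at their partners, so the *unpaired* individuals' column
totals collapse, their dyads' expected counts fall far below the
free-mixing level, and every unpaired–unpaired dyad is flagged positive
(SR ≈ +8 at the reference conditions) — including planted avoidance dyads.
With 8 strength-0.9 pairs among 20 individuals, recall of planted pairs is
1.0 in every replicate but positive precision plateaus near 0.6: no
product-form null can represent partner concentration. In practice the
spurious edges carry much smaller weights than the planted ones (≈ 10 vs
≈ 50), so weight-ranking separates them; users screening for bonded pairs
should inspect weights, not only the 1.96 flag. The corresponding
acceptance test states the precision target and fails honestly under these
conditions.

## Numerical and degenerate-input choices

* Constant matrices make the Mantel correlation undefined: an error, not a
  NaN. Days with no NN pairs are skipped from the stability series with a
  warning.
* Expected-count cells with zero margins are zero; SR is 0 when o = e = 0.
* Empty inferred edge sets have undefined precision, reported as 1.0 with
  an explicit flag (a method that flags nothing makes no false claims).
* Zero-joint-observation dyads score 0 in the simple ratio index with a
  warning.
* Pipeline artifacts contain no timestamps, so identical (input, config,
  seed) reruns are byte-identical; per-comparison Mantel seeds are spawned
  deterministically from the pipeline seed.
* Floats are written with repr-faithful formatting; CSV round-trips are
  exact.
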