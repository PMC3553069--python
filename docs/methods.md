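# Methods

## Model and procedure

Crosstalk between two gene groups is the number of network links joining
them (inter), or within one group (intra). Significance is assessed against
an empirical null: the network is randomized *N* times under a
degree-sequence-preserving model, the pair's link count is tallied in each
instance, and the observed count is standardized by the null sample mean and
sample standard deviation (ddof = 1):

    z = (n_obs − mean) / sd,    p = 1 − Φ(z).

The key assumption is that the null counts are approximately normal, which
holds when the expected number of links is not too small (in practice ≳ 5).
Each pair therefore carries a reduced chi-squared diagnostic (below), and
significance requires all of: BH-adjusted p < α, reduced χ² ≤ 1, and z > 0.

### p-value sidedness

The p-value is the **one-sided upper tail** (enrichment). This matches the
significance rule's `z > 0` requirement and keeps depletion visible through
the sign of z rather than through a second test. A two-sided reading would
double every p and break the `p < fdr` relationship users expect from the
enrichment screen.

### sd = 0 nulls

When all N null counts are equal the z-score is undefined. Such results are
reported with `NA` in z/p/fdr, excluded from the BH family (imputing 0 or
±∞ would corrupt the step-up procedure), and can never be significant. This
arises for structurally forced networks (e.g. the triangle, whose degree
sequence has a unique realization) and for node permutation when no two
nodes share a connectivity bin.

## Randomization algorithms

All four methods preserve the degree sequence exactly, return simple graphs
(no self-links, no duplicate links), and are deterministic functions of
(network, method, seed). Per-instance streams in a screen are derived as
`seed + instance_index`.

**LP (link permutation).** Two links are drawn uniformly from the current
network; if they share no node and neither rewired link exists, they are
swapped. The two legal rewirings {a,c}/{b,d} and {a,d}/{b,c} are chosen
with equal probability. Swapping continues until every *original* link has
been removed by some swap, or until `max_attempt_factor × |links|`
(default 100×) consecutive proposals fail — "no further swap possible" is
not cheaply decidable, so this bound is an explicit termination heuristic.

**NP (node permutation).** Node labels are shuffled uniformly at random
within connectivity bins `B(d) = round(ln d + 1)` (round half away from
zero; the natural-log bin collects nodes of similar degree). The unlabeled
topology is untouched, so assortativity and the s-metric are preserved
exactly; only group membership effectively moves.

**LA (link assignment).** A configuration-model rebuild: each node
contributes one stub per unit of degree, the stub multiset is shuffled and
paired; self-pairs and duplicate pairs are rejected and re-shuffled
(up to 30 rounds). Stub-uniform sampling — nodes weighted by residual
degree — is the standard configuration-model choice. Any residual degrees
left by rejection are completed by the swap-based repair below. Sampling
plus rejection makes the output distribution close to (but, because repair
is local rather than a full restart, not exactly) uniform over simple
realizations of the degree sequence; on exhaustively enumerable sequences
the per-realization frequency error is within ±0.02 at 3000 draws, and the
test suite budgets ±0.05 for Monte-Carlo error plus this bias.

**LA+S (link assignment + second-order conservation).** As LA, but each
original link {u,v} creates one "stub with a bin requirement" on each side:
u must gain a neighbor in v's connectivity bin and vice versa. Stubs are
therefore matched only between mirrored (owner-bin, required-bin) classes,
so a completed assignment reproduces every node's neighbor-degree-bin
multiset exactly (asserted by a bookkeeping oracle in the tests). When the
matching stalls, the repair relaxes the bin constraint for the residual
links only: the degree sequence is the hard constraint, second-order
structure the soft one.

**Degree repair.** For each pair of degree-deficient stubs (u, v): add
{u,v} if absent; otherwise probe random existing links {x,y} disjoint from
{u,v} with {u,x} and {v,y} absent, and replace {x,y} by {u,x}, {v,y}
(a move that raises the degrees of u and v by one and leaves x, y
unchanged). If no move is found within 500 probes the whole assignment
restarts with a fresh stream, up to `stall_retries` (default 10) times
before failing loudly — a degree-violating network is never returned.

## Reduced chi-squared construction

The diagnostic divides a Pearson χ² statistic by *N* − 3 degrees of freedom
(three constraints: mean, standard deviation, and the total count *N*).
The histogram construction is: unit-width bins centred on integers spanning
the observed range of the null counts; expected masses from CDF differences
of the fitted normal, scaled by *N*; adjacent bins pooled left-to-right
until each pooled bin has expected mass ≥ 1 (a trailing remainder merges
into the last pooled bin). With the *N* − 3 divisor the statistic is
lenient for small-count nulls — a Poisson-shaped null at mean ≲ 5 typically
still passes χ² ≤ 1 — so the *expected-links > 5* tag matters when
interpreting borderline results; pairs with `n_exp < 5` are reported but
tagged low-expectation, never silently dropped. A stricter alternative
divisor, (pooled-bin-count − 3), is available via `RunConfig(chi2_dof="bins")`
for sensitivity analysis.

## Counting modes for overlapping groups

Groups may share members, which inflates naive inter counts. Two modes:

* `either` (default): skip links with **either** endpoint in the
  intersection;
* `both`: skip links only when **both** endpoints are in the intersection.

For any pair, `either` ≤ `both` ≤ unexcluded count, and the modes coincide
for disjoint groups. Intra links are always tallied.

## Synthetic test beds

The generators emulate the structure the method is used on, so every
statistical claim is testable without external data:

* **Barabási–Albert networks** (default m = 3) supply a heavy-tailed,
  scale-free background, like real interaction networks. Growth starts
  from an m-node seed clique; n = 3000 gives ≈ 9000 links (mean degree
  ≈ 6).
* **Degree-matched random groups** replace each member of a template with
  a uniformly drawn, distinct, non-template node from the same connectivity
  bin — groups with realistic degree composition and no signal; the
  negative control.
* **Planted modules** (default 20 disjoint modules of 30 genes, 40 extra
  intra links each) add unambiguous internal enrichment to the background;
  the positive control. The boost of 40 links (observed ≈ 41 intra vs ≈ 1
  expected) is deliberately strong so that recovery failures indicate
  implementation defects, not borderline power.
* **Balanced splits** cut a module into random halves for inter-crosstalk
  recovery.

What these beds do **not** emulate: the positive assortativity of real
functional-association networks (BA graphs are close to neutral), community
structure, and the degree bias of curated pathways. Consequently the
relative *ordering* of methods on conservation metrics differs from what an
assortative empirical network shows — on a BA background LP/LA push the
s-metric slightly above 1 instead of below — and the validation asserts the
direction-free property (LA+S and NP deviate least; LA+S retains the most
original links) rather than a dataset-specific ranking.

## Validation battery and problem sizes

`scripts/acceptance.py` (and the mirrored tests) run:

1. **NP topology preservation** — BA(2000, 3); the s-metric ratio must be
   exactly 1 and assortativity unchanged to machine precision.
2. **Planted-module recovery** — BA(3000, 3) + 20 modules (30 genes, boost
   40), each method at N = 100; percent of modules significant.
3. **Split recovery** — same bed, halves screened A×B per method; percent
   of half-pairs significant.
4. **Null calibration** — 66 degree-matched random groups (sizes 20–60) on
   BA(3000, 3), LA+S at N = 150, 2145 inter pairs: p-value bias ratio
   (count p < 0.05 over mean bin count at p ≥ 0.05), z moments.
5. **Normality pass rate** — same screen, percent of pairs with expected
   links > 5 passing χ² ≤ 1.

These sizes give tight positive/negative controls while the whole battery
runs in under a minute on one CPU.

### Known small-count behavior of the null calibration

At this bed's density the expected inter counts are small (≈ 0.5–7), and
the exact null is a right-skewed, Poisson-like counting distribution. The
one-sided normal transform therefore slightly overfills the extreme tail
even when the z moments are perfectly calibrated (z mean ≈ 0, sd ≈ 1.0):
the bias ratio's replicate-level expectation is ≈ 1.3 with sd ≈ 0.15, and a
pure-Poisson simulation (no network code at all) reproduces the same excess
at the same count scale, shrinking toward 1 as expected counts grow. This
is an inherent property of z-based p-values on small-count nulls — the very
regime the expected-links > 5 guidance exists for — not a property of the
randomizers.

## Numerical and interface conventions

* Sample SD uses ddof = 1 throughout.
* Floats in TSV output are printed at 6 significant digits; undefined
  statistics print `NA`.
* `connectivity_bin` rounds half away from zero (documented fixed choice;
  ln(d)+1 is never exactly half-integral for the integer degrees that
  occur, but the convention avoids platform-dependent banker's rounding).
* The hypergeometric GEA p-value is the upper tail P(X ≥ k) — a point-mass
  probability is not monotone in enrichment and would not be a test.
* All outputs are byte-reproducible given identical inputs and seeds.

## Limitations

* Crosstalk statistics are defined for undirected, unweighted simple
  graphs; scores are used only to threshold links at load time.
* The z → p transform is unreliable for pairs with few expected links; use
  the low-expectation tag and the χ² diagnostic, and prefer larger N.
* The LP stall bound and the LA/LA+S repair are termination heuristics;
  they guarantee degree preservation but not exact uniformity over
  realizations.
* p-values from a permutation test (rank of the observed count among null
  counts) are deliberately out of scope; they converge far more slowly
  than the z-score.
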