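# Methods

This note documents the models behind `ccnet`, the parameters that matter,
the numerical conventions, and what the synthetic benchmark does and does
not demonstrate.

## Network inference

### Mutual information

MI is estimated under a bivariate Gaussian model, MI = −½ ln(1 − ρ²), with
Pearson correlation by default (`spearman_gaussian` substitutes rank
correlation for monotone but non-linear dependence).  The closed form gives
analytic test oracles and is monotone in |ρ|, which is all C3Net's argmax
rule consumes.  |ρ| is clamped at 1 − 10⁻¹² so degenerate (perfectly
collinear) pairs produce a large finite MI rather than infinity.
Zero-variance genes get an all-zero MI row with a logged warning: a flat
profile carries no information, and erroring out would make single bad probes
fatal.

### C3Net significance screen

The MI threshold is the empirical (1 − α) quantile of a null pool built by
independently permuting each gene's sample order (destroying all gene–gene
dependence, preserving marginals).  Default α = 0.05; the number of
permutations defaults to whatever gives a pool of at least 10⁵ null MI
values, so small matrices get more permutation rounds automatically.  The
screen is deliberately parameterised — different published C3Net variants
use different screens, and none is canonical.

### BC3Net

Each of B bootstrap datasets resamples the *samples* (columns) with
replacement; genes are never resampled.  Each bootstrap network is a fresh
C3Net run with its own threshold.  Edge counts over the ensemble are tested
one-sided against Binomial(B, p₀).  p₀ defaults to the mean number of edges
per ensemble network divided by p(p − 1)/2 — the probability a uniformly
thrown edge hits a given pair — and is configurable, since the published
method names the binomial test but not its null.  BH (FDR) correction is
applied over all edges observed at least once; edges with adjusted p < 0.05
are retained.  B defaults to 100 in the CLI (the conventional choice) and
to 20 in the desk-scale pipeline configuration, where the ensemble is small
enough to recompute in seconds and recovery is already stable.

The ensemble consensus rate of an edge is count/B exactly; it is symmetric
and lies in [0, 1].  The final network's edges are always a subset of the
aggregate network's (the test only removes).

C3Net argmax ties break to the lexicographically smallest partner id, so
results are independent of gene order.

## Enrichment statistics

Both hypergeometric tails (pair-level GPEA and gene-level) are computed in
log space from log-gamma binomial coefficients and summed over the upper
tail with logsumexp; agreement with exact integer enumeration is 10⁻¹⁰
relative (verified exhaustively for all instances with population ≤ 60).
Bit-exactness across platforms is not promised; 10⁻¹⁰ relative is.

GPEA conventions: N and n come from the *network's* gene universe and edge
count; terms are first restricted to network genes, then filtered to sizes
3..999 inclusive (equivalent to "larger than 2 and less than 1000"); the
per-term giant-component size of the induced subnetwork is reported.
Census-gene enrichment uses the network gene set as its universe, dropping
census genes absent from it, with BH at α = 0.05.

## Chromosome cooperativity

The permutation null permutes the gene → position assignment over all
positioned network genes, holding topology fixed.  This conserves the edge
total, the degree structure, and the uneven per-chromosome gene counts.
The p-value uses the strict inequality I(s⁽ᵉ⁾ > s) exactly as defined, so
p = 0 is possible; a (+1)/(E+1) pseudo-count variant exists but is off by
default to keep the estimator faithful to its definition.

**Discreteness caveat.**  With strict inequality the null exceedance
probability P(p < α) equals P(S ≥ q) for the smallest q with P(S > q) < α,
which strictly exceeds α whenever the count distribution has atoms.  In
sparse regimes (≲ 1 edge per chromosome pair) the raw p < 0.05 rate can
reach ~0.12; it approaches the nominal 0.05 as per-pair counts grow dense
(measured ~0.05 at ~55 edges/pair).  The null-calibration acceptance test
therefore runs at 3,000 genes over 8 chromosomes, a density regime
comparable to a genome-scale network's hundreds of edges per pair.  BH
correction is applied over all (C² − C)/2 + C tests, diagonal included.

## cis/trans and ensemble consensus sets

An edge is cis if both endpoints map to one chromosome, trans otherwise;
edges with an unpositioned endpoint are excluded from both counts as
"unmapped".  ECSᵐⁿ collects the ECR of every retained edge joining
chromosomes m and n (symmetric; C cis sets and C(C−1)/2 trans sets, empty
sets reported as missing, never zero).  The summary statistic is the median
over chromosomes of per-chromosome mean ECR — for cis, the mean of each
diagonal set; for trans, the mean of the pooled off-diagonal sets of each
chromosome (the integrated trans set excludes the diagonal, which belongs
to cis by definition).

## Sliding windows

Windows start at 1, 1 + step, 1 + 2·step, … while the start lies on the
chromosome; spans are clipped at chromosome ends (terminal genes stay
testable).  Defaults: window 1 Mb, step 500 Kb, so consecutive full windows
overlap by 500 Kb and each gene falls in at most ⌈window/step⌉ = 2 windows.
A gene is assigned to a window by a single anchor coordinate (its start by
default, midpoint optionally) to avoid double counting straddlers.  Windows
holding ≥ 2 network genes are tested with the GPEA statistic against the
whole-network pair universe, Bonferroni-corrected over tested windows;
windows whose induced subnetwork has a giant component of ≥ 10 genes are
annotated with their most significant term at BH α = 0.05.

## CSPNN

"All shortest paths" is implemented exactly: x lies on a shortest a–b path
iff d(a,x) + d(x,b) = d(a,b), evaluated from per-seed BFS distance maps, so
no path enumeration is needed.  Distances are unweighted — the inferred
network has no meaningful edge lengths.  Unreachable seed pairs contribute
no path nodes; seeds absent from the network are dropped with a warning.

## Graph descriptors

The mean shortest path is computed over unordered node pairs of the giant
component only (identical to ordered-pair averaging for a symmetric
metric); `network_summary` can approximate it from a node sample for very
large graphs, flagged in the log.  The power-law exponent is the discrete
maximum-likelihood estimate obtained by minimising the Hurwitz-zeta
negative log-likelihood over degrees ≥ d_min (default 1).  The widely used
closed form 1 + n/Σ ln(dᵢ/(d_min − ½)) is available as `method="approx"`
but underestimates the exponent badly at small d_min (≈ 2.0 for true 2.5),
so it is not the default.  Exponents are comparable only under a common
d_min convention; values fitted here are not expected to reproduce
exponents reported for other data under unknown conventions.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume:

* **Topology** — preferential attachment, one edge per new node; attachment
  probability ∝ degree + (a − 1) with strength a (default 1, pure linear
  PA).  Scale-free by construction, connected, heavy-tailed (fitted
  exponents ≈ 2.3 at 2,000 genes).
* **Positions** — chromosomes follow the 24 human chromosome lengths
  (proportionally truncated if fewer are requested); genes (nominal 10 Kb
  footprint) are placed uniformly, chromosome chosen ∝ length.  With
  probability `colocation_prob` (default 0.2) a true edge pulls its second
  endpoint within `colocation_span` (default 1 Mb — the window scale) of
  the first, creating cis enrichment; with the default, roughly a fifth to
  a quarter of true edges end up cis, the proportion seen in genome-scale
  co-expression networks.  Coordinates are 1-based inclusive.
* **Expression** — zero-mean Gaussian graphical model: the precision matrix
  has −ρ at true edges (`edge_partial_corr`, default 0.3 — an arbitrary
  but conventionally "moderate" coupling, as no effect-size information
  exists to calibrate against) and diagonal 1 + ρ·degree, which is
  diagonally dominant and hence positive definite for any graph.  Sampling
  uses a Cholesky solve, never an explicit inverse.  Note the *marginal*
  correlation of an edge shrinks with its endpoints' degrees (e.g. ≈ 0.25
  for a degree-1/degree-2 pair at ρ = 0.4), which the tests check against
  a matrix-inversion oracle.
* **Terms** — each of `n_terms` sets is, with probability
  `term_module_prob`, a breadth-first neighborhood of the truth network
  (edge-dense, GPEA-positive by construction) or otherwise a uniform draw
  (GPEA-null).  Generation modes are kept only in memory for test oracles
  and never serialised.  The census list is a uniform gene sample.

Every generator is byte-deterministic given the config seed; substreams are
derived with `SeedSequence` so stages are independent.

**What passing the synthetic suite does not show.**  The generator has no
microarray noise model (no probe effects, batch effects, heteroscedastic
noise, or non-Gaussian marginals), its true network is a tree-like PA graph
rather than a biological pathway structure, all edges share one coupling
strength, and census genes are unrelated to topology.  Calibration and
recovery results therefore validate the statistics' correctness and
direction, not their power or error rates on real tumour data.

## Problem sizes and defaults

The analysis drivers run at 300 genes × 200 samples with B = 20 and
E = 100,000 (cooperativity), completing in seconds; the acceptance tests
use 200 genes × 200 samples (recovery), 100 genes × 300 samples (ECR
contrast, co-location 0.9), and 3,000 genes / 8 chromosomes (cooperativity
calibration).  These desk-scale sizes were chosen so that every claim is
recomputed from scratch on every run; the statistics themselves are
size-agnostic and the CLI accepts genome-scale inputs.

## Known limitations

* The Gaussian MI estimator cannot see non-monotone dependence; the
  Spearman variant relaxes this only to monotone.
* Strict-inequality permutation p-values are anti-conservative under heavy
  discreteness (see above); use the pseudo-count option or a denser network
  when chromosome pairs carry few edges.
* p₀ for the binomial edge test is a modelling choice; very dense aggregate
  networks make the uniform-edge null questionable.
* Window tests inherit GPEA's assumption that edges are exchangeable across
  the pair universe; strong degree heterogeneity makes the null optimistic
  for windows containing hubs.
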