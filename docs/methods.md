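# Methods

This note documents the models and procedures `paleonet` implements, the
defaults it ships with and why, the numerical choices that matter, and what
the synthetic benchmark does and does not demonstrate.

## Data model

An *occurrence* is a (taxon, collection point) pair; a collection point is a
unique locus in geographic and stratigraphic space and belongs to exactly
one geologic formation. Taxa are body genera or ichnogenera and carry
nominal metadata (one of 8 taphonomic modes; one of 33 morphogroups for
body taxa or 24 architectural groups for traces; a lumped form category; an
optional paleocommunity label) plus a set of paleoenvironment codes drawn
from a 17-code, shallow-to-deep ordered vocabulary. Environment assignment
is per taxon (the union of codes observed over its occurrences), matching
how occurrence compilations typically record facies associations.

The controlled vocabularies are loaded from a packaged YAML file. The
shipped lists are constructed stand-ins with the documented category counts
(see the file header); validation therefore treats out-of-vocabulary codes
as reportable rather than fatal, so analyses never depend on the particular
stand-in lists.

**Index-taxon filter.** A taxon is retained when it (1) is not flagged as a
simple disc, possible taphomorph or possible pseudofossil, (2) is not on a
configurable exclusion list, and (3) co-occurs with at least one other
retained taxon at some collection point or within some formation. Criterion
(3) is applied to a fixed point — removing a taxon can isolate another — so
the filter is idempotent.

## Networks

Three structures are built from a filtered table:

* a unipartite genus network (link ⇔ co-occurrence at ≥ 1 collection
  point), whose modules read as paleocommunities;
* a bipartite taxa–environment network (link ⇔ environment in the taxon's
  set), whose modules read as biotopes;
* a bipartite taxa–formation network (link ⇔ ≥ 1 occurrence in the
  formation), whose modules read as assemblage biozones.

One-mode projections connect two same-class nodes iff they share at least
one neighbor. Projections are unweighted by default: the modularity
bookkeeping downstream assumes simple graphs, and a shared-neighbor-count
weighted variant is available but off by default. Self-loops, where present
in imported graphs, are excluded from degree centrality and from all
modularity terms. Betweenness is unnormalized with equal splitting across
tied shortest paths. Assortativity (degree or nominal) raises an explicit
`UndefinedMetricError` for zero-variance inputs (regular graphs,
single-category attributes) instead of returning 0 or NaN.

## Overlapping community detection

COPRA propagates *belonging coefficients*. Every node starts holding its
own label with coefficient 1. One step replaces each node's label map by
the coefficient-weighted average of its neighbors' maps; labels with
coefficients below 1/v are deleted and the rest renormalized; if every
label falls below the threshold, a single maximum-coefficient label is
retained, ties broken uniformly at random from the run's seeded generator.
With v = 1 this is crisp label propagation. Design choices:

* **Synchronous updates, two-phase on bipartite graphs.** All nodes update
  from the previous step's state. On bipartite graphs a fully synchronous
  update is 2-periodic (labels swap sides each step), so one class updates
  from the other, then the second from the refreshed first. Unipartite
  graphs use the plain synchronous update.
* **Termination.** Per-label running minima of membership counts are
  tracked; the run stops when an iteration leaves the minimum vector
  unchanged (which also catches oscillating cycles), bounded by
  `max_iters = 1000` with a warning and best-current-state return.
* **Threshold edge case.** A coefficient exactly equal to 1/v is retained.
  On a complete graph with v equal to the common degree this keeps a
  deterministic overlapping cover rather than collapsing to one community;
  for v below that, the random-fallback path applies and a single
  community results. This is a property of the algorithm, not a bug.
* **Extra-simplification.** After a run, any community whose node set is
  contained in another's is removed (equal sets collapse to the
  label that sorts first) and coefficients renormalize. Isolated nodes
  survive as singleton communities and are reported.
* **Restarts.** `copra_best` reruns the algorithm with counter-derived
  seeds and keeps the cover with the best modularity, recording the full
  score distribution. The default budget is 2,000 restarts; tests and the
  acceptance script use 20–200, which on the benchmark networks (~200
  nodes) recover the same structures.

**Scoring.** Crisp partitions are scored with Newman–Girvan modularity
Q = Σ_c [L_c/m − (d_c/2m)²]. Covers are scored with the product-form
overlap extension, Q_ov = (1/2m) Σ_c Σ_ij [A_ij − k_i k_j/2m] b_ic b_jc,
chosen because it reduces *exactly* to Q for crisp covers; it is the single
place a different published belonging function could be swapped in. Note
that splitting a node between communities shrinks the null term
quadratically, so an overlapping cover can legitimately out-score both
crisp alternatives. Restart selection ranks covers by the modularity of
the network that was actually partitioned — for bipartite networks the
bipartite graph itself under the standard null — while the modularity of
each one-mode projection (with induced memberships) is computed alongside
for reporting and significance testing. An earlier sum-of-projections
ranking was rejected: the dense formation projection can dominate it and
favor merging adjacent biozones that the propagation itself separates.

**Choosing v.** Leave-one-out jackknife: for every node, remove it, run
crisp detection (v = 1, best of `restarts_per_leave`), and record the
number of non-singleton communities *n*; v is the maximum *n* over the
distribution (whose length equals the node count).

## Statistical validation

**Randomization testing.** The null model preserves every node's degree:
double-edge swaps for unipartite graphs, class-respecting two-edge swaps
for bipartite graphs, 10·m successful swaps per draw (a standard mixing
heuristic). Degenerate degree sequences that admit only the input
realization return it with a warning. Each of `reps` (default 100) draws is
re-partitioned with the same v and restart budget; P is the fraction of
null modularities ≥ the observed one (ties count as exceeding; the observed
value is not added to its own null set, which would only shrink Z), and
Z = (observed − null mean)/null sd (sample sd). When the null collapses —
e.g. at high v every randomized network yields a single community with
Q = 0 exactly — Z is reported as undefined rather than infinite.

**Sensitivity analysis.** Links are subsampled uniformly (retaining
round(f·m), half-up); nodes losing all links are omitted and re-enter NMI
scoring as their own singleton modules. Each subnetwork is re-partitioned
at v = 1 and compared to the reference partition by NMI; the paired null
partitions two degree-matched randomizations (of the network and of the
subnetwork) identically. The null is rejected at a level when ≥ 95% of
observed NMI values exceed their paired nulls. Default level grid:
{1.0, 0.95, 0.9, 0.8, 0.7}.

**NMI.** Shannon mutual information with sum normalization 2I/(H_a + H_b)
(scikit-learn's arithmetic mean form); max and sqrt normalizations are
selectable. Two single-cluster partitions of the same node set are defined
to agree perfectly (NMI = 1).

## Dissimilarity, clustering, richness

Sample dissimilarity uses Jaccard (1 − a/(a+b+c)) or Kulczynski-2
(1 − ½(a/(a+b) + a/(a+c))). Average-linkage (UPGMA) clustering and
cophenetic distances come from SciPy; dendrogram fidelity is summarized by
the Pearson correlation between observed and cophenetic distances. Clade
support is a plain bootstrap proportion over taxa resampled with
replacement (1,000 reps by default); multiscale-bootstrap AU corrections
are deliberately not implemented — plain proportions are biased
conservative for small clades, and the difference is documented here
rather than approximated. Samples emptied by a resample use the convention
d = 1 against non-empty samples and 0 against each other.

Incidence-based richness uses the standard quantities Y_i (samples holding
taxon i) and Q_j (taxa in exactly j of N samples):

* rarefaction: S(n) = S_obs − Σ_i C(N−Y_i, n)/C(N, n), exact at n = N;
* extrapolation: S(N+m) = S_obs + Q̂₀·[1 − (1 − Q₁/(Q₁ + N·Q̂₀))^m] with
  Q̂₀ from Chao2; flat when Q₁ = 0; approaches the Chao2 asymptote;
* Chao2 classic S_obs + ((N−1)/N)·Q₁²/(2Q₂), bias-corrected
  Q₁(Q₁−1)/(2(Q₂+1)) when Q₂ = 0, with the classic variance formulas;
* jackknife-1/2, bootstrap, and ICE with the conventional 10-sample
  infrequent cutoff (coverage-undefined cases fall back to Chao2). The
  second-order jackknife can drop below S_obs when doubletons outnumber
  singletons; that is a property of its closed form and is not clamped.

**Unconditional variance.** Conditional intervals treat the reference
sample as fixed and collapse to zero width at full sampling; unconditional
intervals treat it as one random draw from an assemblage of estimated
(Chao2) total richness Ŝ and stay open. For interpolation the package uses
σ²(n) = Σ_i (1 − α_ni)² − S(n)²/Ŝ (clamped at 0), with
α_ni = C(N−Y_i, n)/C(N, n); at n = N this equals S_obs·Q̂₀/Ŝ, zero only
under complete sampling. For extrapolation a delta-method term is added:
σ²(N+m) = σ²(N) + f(m)²·var(Chao2), continuous at m = 0 and tending to the
Chao2 interval at large m. These are this package's analytic constructions
in the spirit of the published framework; confidence envelopes are normal,
±1.96 σ. Two biozones are called significantly different when their
unconditional 95% envelopes do not overlap at the smaller current sampling
level (touching intervals count as overlap). Estimator-vs-intensity curves
use subsampling without replacement (default 1,000 reps), percentile
conditional intervals for bootstrap/ICE/jackknife-2, and analytic
unconditional intervals for Chao2 and jackknife-2.

## Synthetic benchmark

The generator plants three signals in one occurrence table: *biozones*
(groups of formations drawing taxa from partially shared pools),
*biotopes* (each taxon gets a preference window on an ordered environment
gradient; collections sample only compatible taxa), and *sampling noise*
(per-taxon detection probability, variable collections per formation). The
default configuration — 4 biozones × 10 formations, 38 taxa per pool with
10% shared into the next biozone, 6 environments in 3 biotope windows,
10–20 collections per formation, detection probability 0.9, 15%
ichnogenera, 5% flagged taxa — loosely mirrors the scale of a global
Ediacaran-type compilation (~150 taxa, ~40 formations, ~600 collections)
and realizes an intra-/inter-biozone link-probability contrast of roughly
50:1. Ground truth records each taxon's biozone(s) (primary first),
biotope, and each formation's biozone; recovery is scored as NMI between
the crisped detected cover and the planted labels.

What passing the benchmark shows: the full pipeline (jackknife v,
best-of-restarts COPRA, significance testing) recovers clean planted
structure of realistic size and noise, and does not hallucinate structure
in degree-matched random graphs. What it does not show: robustness to the
pathologies of real compilations — monographic and geographic sampling
bias, taxonomic synonymy, abundance (rather than presence) structure,
gradational biozone boundaries, and preservational filters correlated with
environment. The generator's sharing is between adjacent biozones only,
and taxa shared across a boundary carry their first biozone as "truth",
which caps attainable NMI slightly below 1 by construction.

## Numerical conventions

Randomness flows from explicit integer seeds; multi-run procedures derive
per-run seeds by counter from a `SeedSequence`, so enlarging a restart
budget extends (never reshuffles) the stream, and best-cover ties resolve
to the earliest restart. Coefficient comparisons use an absolute tolerance
of 1e-12; cover validity (coefficients sum to 1, ≤ v labels) is enforced at
1e-9. UPGMA merge ties follow SciPy's deterministic ordering. Undefined
statistics raise `UndefinedMetricError` or are stored as `None`; they are
never silently zero.

## Known limitations

* Weighted-network COPRA is not implemented (unweighted projections are the
  default analysis path).
* The 13 alternative community-detection algorithms sometimes used for
  comparison are out of scope; Newman-modularity scoring doubles as the
  internal cross-check.
* AU (multiscale bootstrap) clade p-values and NMDS ordination are not
  provided.
* Rarefaction assumes exchangeable samples; no coverage-standardized
  variant is included.
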