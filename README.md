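# paleonet

Network-based biostratigraphy for fossil occurrence data.

Quantitative biostratigraphy asks which packages of rock are roughly
age-equivalent, based on the taxa preserved in them. `paleonet` implements a
network approach to that question, developed for the Ediacaran macrofossil
record but applicable to any occurrence compilation: taxa, paleoenvironments
and geologic formations become nodes; fossil occurrences become links; and
the modules of those networks are read as paleocommunities, biotopes
(environment-bound associations) and assemblage biozones (associations of
taxa plus the formations that contain them). The package is aimed at
paleontologists and anyone working with co-occurrence matrices who needs
overlapping community detection with honest significance testing.

## What it does

- **Occurrence handling** — read and validate occurrence CSVs (taxon,
  collection point, formation, environments, taphonomic metadata), apply the
  index-taxon filter (drop discs, taphomorphs, pseudofossils and taxa that
  never co-occur with others), and build taxa × samples incidence matrices.
- **Networks** — unipartite genus co-occurrence networks, bipartite
  taxa–environment and taxa–formation networks, one-mode projections, and
  descriptive metrics (degree, betweenness, nominal/degree assortativity).
- **Overlapping community detection** — the COPRA label-propagation
  algorithm with belonging coefficients: each node holds up to *v* community
  labels whose coefficients sum to 1; labels below 1/*v* are pruned and
  communities contained in others are removed (extra-simplification). The
  per-node budget *v* is selected by a leave-one-out jackknife: drop each
  node, partition crisply (*v* = 1), count non-singleton communities *n*,
  and set *v* = max *n*. Covers are scored with overlap modularity
  Q_ov = (1/2m) Σ_c Σ_ij [A_ij − k_i k_j / 2m] b_ic b_jc, which reduces
  exactly to Newman–Girvan Q for crisp partitions.
- **Validation** — degree-preserving randomization testing (one-sided *P*
  and *Z* per network projection) and link-subsampling sensitivity analysis
  scored by normalized mutual information against degree-matched null pairs.
- **Diversity** — Jaccard / Kulczynski-2 dissimilarity, average-linkage
  (UPGMA) clustering with cophenetic correlation and bootstrap clade
  support, analytical sample-based rarefaction and Chao2-anchored
  extrapolation with unconditional confidence envelopes, and the classic
  incidence estimators (Chao2, ICE, jackknife 1/2, bootstrap) for comparing
  biozone richness.
- **Synthetic data** — a generator that plants biozones (formation groups
  with partially shared taxon pools), biotopes (taxon preference windows on
  a depth gradient) and sampling noise, returning ground-truth labels so
  every stage can be scored for recovery.

## Worked example

```python
import paleonet as pn

# a planted dataset: 4 biozones, ~40 formations, ~150 taxa, ~600 collections
table, truth = pn.generate(pn.SyntheticConfig(seed=1))

net = pn.bipartite_network(table, partner="formations")
v, _ = pn.select_v(net, seed=0, restarts_per_leave=1)
cover = pn.copra_best(net, v=v, restarts=50, seed=0)
print(v, cover.n_communities, round(cover.q_ov, 3))
print(round(pn.recovery_score(cover, truth, layer="biozone"), 3))
```

prints

```
5 4 0.702
0.963
```

meaning: the jackknife selected a budget of 5 labels per node, COPRA found 4
modules with overlap modularity 0.702 on the bipartite network, and the
detected modules match the planted biozones at NMI 0.963 (1.0 would be
perfect recovery; values ≥ 0.9 indicate essentially correct biozonation
with disagreement confined to taxa shared between adjacent biozones).

The same analysis runs from the shell:

```bash
paleonet pipeline --seed 1 -d run/     # simulate + all ten stages
paleonet report -d run/                # Q/P/Z, clustering, diversity tables
```

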