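"""Significance and robustness testing of community structure.

Two procedures:

* randomization testing — compare the observed (projection) modularity with
  a null distribution from degree-preserving rewirings of the network,
  summarized as a one-sided P value and a Z score;
* sensitivity analysis — randomly subsample links, re-partition, and score
  agreement with the reference partition by normalized mutual information
  (NMI), against a null built from pairs of degree-matched random networks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.metrics import normalized_mutual_info_score

from .communities import Cover, copra_best
from .errors import InputDataError, ParameterError
from .networks import bipartite_sides, is_bipartite_typed

#: NMI normalization name -> sklearn average_method
_NMI_FORMS = {"sum": "arithmetic", "max": "max", "sqrt": "geometric"}


# ----------------------------------------------------------------------
# Degree-preserving randomization
# ----------------------------------------------------------------------

def _randomize_bipartite(net: nx.Graph, rng: np.random.Generator,
                         swaps_per_edge: int) -> nx.Graph:
    """Swap-based rewiring preserving both sides' degree sequences."""
    side0, _ = bipartite_sides(net)
    side0_set = set(side0)
    edges = [
        (u, w) if u in side0_set else (w, u) for u, w in net.edges()
    ]
    edge_set = set(edges)
    m = len(edges)
    target = swaps_per_edge * m
    done = 0
    tries = 0
    max_tries = 100 * target + 100
    while done < target and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        u1, w1 = edges[i]
        u2, w2 = edges[j]
        if u1 == u2 or w1 == w2:
            continue
        if (u1, w2) in edge_set or (u2, w1) in edge_set:
            continue
        edge_set.discard((u1, w1))
        edge_set.discard((u2, w2))
        edge_set.add((u1, w2))
        edge_set.add((u2, w1))
        edges[i] = (u1, w2)
        edges[j] = (u2, w1)
        done += 1
    if done == 0:
        warnings.warn(
            "bipartite degree sequence admits no rewiring; returning input",
            stacklevel=2,
        )
    R = nx.Graph(**net.graph)
    R.add_nodes_from(net.nodes(data=True))
    R.add_edges_from(edge_set)
    return R


def randomize_network(
    net: nx.Graph, seed: int | np.random.Generator = 0, swaps_per_edge: int = 10
) -> nx.Graph:
    """Random network with the exact degree sequence of the input.

    Unipartite graphs are rewired with double-edge swaps (no self-loops or
    multi-edges); bipartite graphs with two-edge swaps that keep every link
    across the two classes. If the degree sequence admits only the input
    realization (e.g. a triangle), the input is returned with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if is_bipartite_typed(net):
        return _randomize_bipartite(net, rng, swaps_per_edge)
    R = net.copy()
    m = R.number_of_edges()
    if m < 2:
        warnings.warn("too few links to rewire; returning input", stacklevel=2)
        return R
    nswap = swaps_per_edge * m
    try:
        nx.double_edge_swap(
            R, nswap=nswap, max_tries=100 * nswap,
            seed=int(rng.integers(0, 2**31)),
        )
    except nx.NetworkXError:
        warnings.warn(
            "degree sequence admits no (further) rewiring; "
            "returning partially rewired network",
            stacklevel=2,
        )
    return R


# ----------------------------------------------------------------------
# Modularity significance
# ----------------------------------------------------------------------

@dataclass
class NullModularityResult:
    """Observed vs. null modularity for one network.

    For bipartite networks each one-mode projection has its own observed
    value, null distribution, P and Z. P counts null values >= observed
    (ties exceed, observed excluded from its null set); Z is the observed
    value's distance from the null mean in null standard deviations
    (undefined, stored as None, when the null has zero spread).
    """

    observed_q: dict
    null_q: dict
    p_value: dict
    z_score: dict
    reps: int
    observed_cover: Cover | None = None
    significance: dict = field(default_factory=dict)

    ALPHAS = (0.10, 0.05, 0.01)

    def summarize(self) -> dict:
        return {
            "observed_q": self.observed_q,
            "p_value": self.p_value,
            "z_score": self.z_score,
            "reps": self.reps,
            "significant_at": self.significance,
        }


def _q_by_projection(net: nx.Graph, cover: Cover) -> dict:
    if is_bipartite_typed(net) and cover.projection_q:
        return dict(cover.projection_q)
    return {"network": cover.q_ov}


def modularity_significance(
    net: nx.Graph,
    v: int,
    reps: int = 100,
    restarts: int = 100,
    seed: int = 0,
    max_iters: int = 1000,
) -> NullModularityResult:
    """Randomization test of community structure.

    Each rep rewires the network degree-preservingly, re-partitions it with
    the same ``v`` and restart budget, and records the best (projection)
    modularity. One-sided P and Z are computed per projection.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    ss = np.random.SeedSequence(seed).generate_state(2 * reps + 1) % (2**31)
    observed = copra_best(net, v=v, restarts=restarts, seed=int(ss[0]),
                          max_iters=max_iters)
    obs_q = _q_by_projection(net, observed)
    null_q: dict = {k: [] for k in obs_q}
    for r in range(reps):
        R = randomize_network(net, seed=int(ss[1 + 2 * r]))
        cov = copra_best(R, v=v, restarts=restarts, seed=int(ss[2 + 2 * r]),
                         max_iters=max_iters)
        for k, val in _q_by_projection(R, cov).items():
            null_q[k].append(float(val))
    p_value, z_score = {}, {}
    for k, obs in obs_q.items():
        nulls = np.asarray(null_q[k], dtype=float)
        p_value[k] = float(np.mean(nulls >= obs))
        sd = float(np.std(nulls, ddof=1)) if reps > 1 else 0.0
        z_score[k] = (float((obs - nulls.mean()) / sd) if sd > 0 else None)
    significance = {
        alpha: all(p <= alpha for p in p_value.values())
        for alpha in NullModularityResult.ALPHAS
    }
    return NullModularityResult(
        observed_q=obs_q,
        null_q=null_q,
        p_value=p_value,
        z_score=z_score,
        reps=reps,
        observed_cover=observed,
        significance=significance,
    )


# ----------------------------------------------------------------------
# Link subsampling and NMI
# ----------------------------------------------------------------------

def subsample_links(
    net: nx.Graph, fraction: float, seed: int | np.random.Generator = 0
) -> tuple[nx.Graph, set]:
    """Retain round(fraction * m) uniformly chosen links (half-up rounding).

    Nodes losing every link are dropped from the subnetwork and returned as
    the omitted set.
    """
    if not (0 < fraction <= 1):
        raise ParameterError("fraction must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = sorted(net.edges(), key=lambda e: (str(e[0]), str(e[1])))
    m = len(edges)
    k = int(np.floor(fraction * m + 0.5))
    if k == 0:
        raise InputDataError("subsampling would retain zero links")
    keep_idx = rng.choice(m, size=k, replace=False)
    sub = nx.Graph(**net.graph)
    sub.add_nodes_from(net.nodes(data=True))
    sub.add_edges_from(edges[i] for i in keep_idx)
    omitted = {n for n in sub.nodes if sub.degree(n) == 0}
    sub.remove_nodes_from(omitted)
    return sub, omitted


def nmi(a, b, universe=None, normalization: str = "sum") -> float:
    """Normalized mutual information between two crisp clusterings.

    ``a`` and ``b`` are node -> label maps (or crisp Covers). Nodes of the
    universe missing from a clustering count as their own singleton module.
    The default normalization is the sum form 2 I / (H_a + H_b); ``max`` and
    ``sqrt`` forms are available. Two single-cluster partitions of the same
    set are identical clusterings and score 1.
    """
    if normalization not in _NMI_FORMS:
        raise ParameterError(f"unknown NMI normalization {normalization!r}")
    if isinstance(a, Cover):
        a = a.to_partition()
    if isinstance(b, Cover):
        b = b.to_partition()
    if universe is None:
        universe = set(a) | set(b)
    universe = sorted(universe, key=str)
    if not universe:
        raise InputDataError("empty node universe")

    def labels_for(part, tag):
        out = []
        for node in universe:
            if node in part:
                out.append(("c", str(part[node])))
            else:
                out.append(("singleton", tag, str(node)))
        return out

    la = labels_for(a, "a")
    lb = labels_for(b, "b")
    if len(set(la)) == 1 and len(set(lb)) == 1:
        return 1.0  # both trivial over the same universe
    codes_a = {l: i for i, l in enumerate(dict.fromkeys(la))}
    codes_b = {l: i for i, l in enumerate(dict.fromkeys(lb))}
    return float(
        normalized_mutual_info_score(
            [codes_a[l] for l in la],
            [codes_b[l] for l in lb],
            average_method=_NMI_FORMS[normalization],
        )
    )


# ----------------------------------------------------------------------
# Sensitivity profile
# ----------------------------------------------------------------------

@dataclass
class LevelResult:
    """Sensitivity outcome at one link-sampling level."""

    level: float
    nmi_scores: list = field(default_factory=list)
    omitted_counts: list = field(default_factory=list)
    null_nmi_scores: list = field(default_factory=list)
    verdict: str = "untested"
    error: str | None = None

    def exceed_fraction(self) -> float:
        obs = np.asarray(self.nmi_scores)
        nul = np.asarray(self.null_nmi_scores)
        if obs.size == 0:
            return float("nan")
        return float(np.mean(obs > nul))


@dataclass
class SensitivityProfile:
    levels: dict
    reference: dict
    reps: int

    def summarize(self) -> dict:
        out = {}
        for lv, res in self.levels.items():
            out[lv] = {
                "median_nmi": (
                    float(np.median(res.nmi_scores)) if res.nmi_scores else None
                ),
                "median_omitted": (
                    float(np.median(res.omitted_counts))
                    if res.omitted_counts else None
                ),
                "exceed_fraction": res.exceed_fraction(),
                "verdict": res.verdict,
                "error": res.error,
            }
        return out


DEFAULT_LEVELS = (1.0, 0.95, 0.9, 0.8, 0.7)


def sensitivity_profile(
    net: nx.Graph,
    levels=DEFAULT_LEVELS,
    reps: int = 100,
    restarts: int = 100,
    seed: int = 0,
    max_iters: int = 1000,
) -> SensitivityProfile:
    """Robustness of the v=1 partition to random link loss.

    Per level and rep: subsample links, re-partition the subnetwork (v=1),
    and score NMI against the reference partition with omitted nodes as
    singletons. The matched null draws a degree-preserving randomization of
    the network and of the subnetwork, partitions both identically, and
    scores their NMI. The null is rejected at a level ("robust") when at
    least 95% of observed NMI values exceed their paired null values.
    """
    ss = np.random.SeedSequence(seed)
    base = ss.generate_state(1)[0] % (2**31)
    reference = copra_best(
        net, v=1, restarts=restarts, seed=int(base), max_iters=max_iters
    ).to_partition()
    universe = set(net.nodes)
    out: dict = {}
    streams = ss.spawn(len(levels))
    for level, stream in zip(levels, streams):
        res = LevelResult(level=level)
        seeds = stream.generate_state(5 * reps) % (2**31)
        try:
            for r in range(reps):
                s0, s1, s2, s3, s4 = (int(x) for x in seeds[5 * r: 5 * r + 5])
                sub, omitted = subsample_links(net, level, seed=s0)
                if sub.number_of_edges() == 0:
                    raise InputDataError("edgeless subnetwork")
                part = copra_best(
                    sub, v=1, restarts=restarts, seed=s1, max_iters=max_iters
                ).to_partition()
                res.nmi_scores.append(nmi(part, reference, universe=universe))
                res.omitted_counts.append(len(omitted))
                null_a = randomize_network(net, seed=s2)
                null_b = randomize_network(sub, seed=s3)
                pa = copra_best(
                    null_a, v=1, restarts=restarts, seed=s4, max_iters=max_iters
                ).to_partition()
                pb = copra_best(
                    null_b, v=1, restarts=restarts, seed=s4, max_iters=max_iters
                ).to_partition()
                res.null_nmi_scores.append(nmi(pa, pb, universe=universe))
            res.verdict = (
                "robust" if res.exceed_fraction() >= 0.95 else "not_robust"
            )
        except InputDataError as exc:
            res.error = str(exc)
            res.verdict = "error"
        out[level] = res
    return SensitivityProfile(levels=out, reference=reference, reps=reps)
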