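"""Dissimilarity, clustering, rarefaction, and richness estimators."""
import itertools

import numpy as np
import pandas as pd
import pytest

import paleonet as pn
from conftest import incidence_from_dict


@pytest.fixture
def chao_example():
    """S_obs = 10, N = 10, Q1 = 4, Q2 = 2."""
    taxa_sets = {}
    samples = [f"s{j}" for j in range(10)]
    for i in range(4):
        taxa_sets[f"sing{i}"] = {samples[i]}
    taxa_sets["dbl1"] = {samples[0], samples[1]}
    taxa_sets["dbl2"] = {samples[2], samples[3]}
    for i in range(4):
        taxa_sets[f"common{i}"] = set(samples[:6])
    return incidence_from_dict(taxa_sets, samples)


def random_incidence(rng, n_taxa=8, n_samples=6):
    while True:
        mat = rng.random((n_taxa, n_samples)) < 0.45
        if mat.any(axis=1).all() and mat.any(axis=0).all():
            return pn.IncidenceMatrix(pd.DataFrame(
                mat,
                index=[f"t{i}" for i in range(n_taxa)],
                columns=[f"s{j}" for j in range(n_samples)],
            ))


class TestDissimilarity:
    def test_worked_example_jaccard(self):
        inc = incidence_from_dict(
            {"x": {"A"}, "y": {"A", "B"}, "z": {"A", "B"}, "w": {"B"}},
            ["A", "B"],
        )
        D = pn.pairwise_dissimilarity(inc, "jaccard")
        assert D.matrix[0, 1] == pytest.approx(0.5)  # 1 - 2/4

    def test_worked_example_kulczynski2(self):
        inc = incidence_from_dict(
            {"x": {"A"}, "y": {"A", "B"}, "z": {"A", "B"}, "w": {"B"}},
            ["A", "B"],
        )
        D = pn.pairwise_dissimilarity(inc, "kulczynski2")
        assert D.matrix[0, 1] == pytest.approx(1 / 3)  # 1 - (2/3 + 2/3)/2

    @pytest.mark.parametrize("index", ["jaccard", "kulczynski2"])
    def test_metric_properties(self, index):
        rng = np.random.default_rng(3)
        inc = random_incidence(rng)
        D = pn.pairwise_dissimilarity(inc, index).matrix
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert ((D >= 0) & (D <= 1)).all()
        cols = inc.data.to_numpy().T
        for i, j in itertools.combinations(range(len(cols)), 2):
            identical = (cols[i] == cols[j]).all()
            assert (D[i, j] == 0) == identical

    def test_empty_sample_signalled(self):
        mat = pd.DataFrame(
            {"A": [True, True], "B": [False, False]}, index=["x", "y"]
        )
        with pytest.raises(pn.UndefinedMetricError):
            pn.pairwise_dissimilarity(pn.IncidenceMatrix(mat))


class TestUpgma:
    def test_hand_worked_merge_order(self):
        D = pn.DissimilarityMatrix(
            labels=["a", "b", "c"],
            matrix=np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float),
            index="jaccard",
        )
        tree = pn.upgma(D)
        assert list(tree.linkage[:, 2]) == [1.0, 4.0]
        assert frozenset({"a", "b"}) in tree.clades()

    def test_two_items(self):
        D = pn.DissimilarityMatrix(
            labels=["a", "b"], matrix=np.array([[0, 0.3], [0.3, 0]]),
            index="jaccard",
        )
        tree = pn.upgma(D)
        assert tree.linkage[0, 2] == pytest.approx(0.3)

    def test_ultrametric_input_is_fixed_point(self):
        D = pn.DissimilarityMatrix(
            labels=["a", "b", "c"],
            matrix=np.array([[0, .1, .4], [.1, 0, .4], [.4, .4, 0]]),
            index="jaccard",
        )
        tree = pn.upgma(D)
        assert np.allclose(tree.cophenetic(), D.condensed())
        assert pn.cophenetic_correlation(D, tree) == pytest.approx(1.0)

    def test_cophenetic_ultrametric_inequality(self):
        rng = np.random.default_rng(7)
        inc = random_incidence(rng, n_taxa=10, n_samples=7)
        tree = pn.upgma(pn.pairwise_dissimilarity(inc))
        from scipy.spatial.distance import squareform
        C = squareform(tree.cophenetic())
        n = C.shape[0]
        for x, y, z in itertools.permutations(range(n), 3):
            assert C[x, z] <= max(C[x, y], C[y, z]) + 1e-12

    def test_cophenetic_matches_brute_force_pearson(self):
        rng = np.random.default_rng(1)
        inc = random_incidence(rng)
        D = pn.pairwise_dissimilarity(inc)
        tree = pn.upgma(D)
        obs, coph = D.condensed(), tree.cophenetic()
        expected = np.corrcoef(obs, coph)[0, 1]
        assert pn.cophenetic_correlation(D, tree) == pytest.approx(expected)

    def test_too_few_labels(self):
        D = pn.DissimilarityMatrix(
            labels=["a", "b"], matrix=np.array([[0, .2], [.2, 0]]),
            index="jaccard",
        )
        with pytest.raises(pn.UndefinedMetricError):
            pn.cophenetic_correlation(D, pn.upgma(D))

    def test_newick_export_parses(self):
        rng = np.random.default_rng(2)
        inc = random_incidence(rng)
        tree = pn.upgma(pn.pairwise_dissimilarity(inc))
        import io

        from Bio import Phylo
        parsed = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == inc.samples


class TestBootstrapSupport:
    def test_separated_clusters_high_support(self):
        taxa_sets = {f"left{i}": {"A", "B"} for i in range(8)}
        taxa_sets.update({f"right{i}": {"C", "D"} for i in range(8)})
        taxa_sets["bridge"] = {"A", "B", "C", "D"}
        inc = incidence_from_dict(taxa_sets, ["A", "B", "C", "D"])
        support = pn.bootstrap_support(inc, reps=100, seed=0)
        assert support[frozenset({"A", "B"})] >= 0.95
        assert support[frozenset({"C", "D"})] >= 0.95

    def test_noise_gives_lower_support(self):
        rng = np.random.default_rng(5)
        inc = random_incidence(rng, n_taxa=12, n_samples=6)
        support = pn.bootstrap_support(inc, reps=100, seed=1)
        assert min(support.values()) < 0.95
        assert all(0 <= v <= 1 for v in support.values())


class TestRarefaction:
    def test_hand_worked_expectation(self):
        inc = incidence_from_dict(
            {"A": {"s1", "s2", "s3"}, "B": {"s1"}}, ["s1", "s2", "s3"]
        )
        assert pn.rarefy(inc, 1).richness == pytest.approx(4 / 3)

    def test_endpoint_equals_observed_richness(self, chao_example):
        point = pn.rarefy(chao_example, chao_example.N)
        assert point.richness == chao_example.S_obs
        assert point.kind == "observed"

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration(self, seed):
        from paleonet.diversity import rarefy_exhaustive
        rng = np.random.default_rng(seed)
        inc = random_incidence(rng, n_taxa=6, n_samples=6)
        for n in range(1, inc.N + 1):
            assert pn.rarefy(inc, n).richness == pytest.approx(
                rarefy_exhaustive(inc, n), abs=1e-9
            )

    def test_matches_monte_carlo_subsampling(self, chao_example):
        rng = np.random.default_rng(0)
        n = 4
        reps = 1000
        draws = np.empty(reps)
        samples = list(chao_example.samples)
        for r in range(reps):
            chosen = rng.choice(samples, size=n, replace=False)
            draws[r] = chao_example.subset_samples(chosen).S_obs
        se = draws.std(ddof=1) / np.sqrt(reps)
        assert abs(pn.rarefy(chao_example, n).richness - draws.mean()) < 3 * se

    def test_out_of_range(self, chao_example):
        with pytest.raises(pn.ParameterError):
            pn.rarefy(chao_example, 0)
        with pytest.raises(pn.ParameterError):
            pn.rarefy(chao_example, chao_example.N + 1)

    def test_curve_monotone_and_continuous(self, chao_example):
        curve = pn.rarefaction_curve(chao_example)
        values = [p.richness for p in curve.points]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert curve.at(chao_example.N).richness == chao_example.S_obs

    def test_unconditional_ci_positive_at_full_sampling(self, chao_example):
        # undetected taxa remain (Q1 > 0), so the envelope must not close
        point = pn.rarefy(chao_example, chao_example.N)
        assert point.variance > 0


class TestExtrapolation:
    def test_no_singletons_flat(self):
        taxa_sets = {f"t{i}": {"s1", "s2", "s3"} for i in range(5)}
        inc = incidence_from_dict(taxa_sets, ["s1", "s2", "s3"])
        assert pn.extrapolate(inc, 10).richness == inc.S_obs

    def test_limit_is_chao2_asymptote(self, chao_example):
        chao2 = {
            e.estimator: e.value for e in pn.richness_estimators(chao_example)
        }["chao2"]
        assert pn.extrapolate(chao_example, 10**7).richness == pytest.approx(chao2)

    def test_extrapolation_extends_monotonically(self, chao_example):
        s_n = pn.rarefy(chao_example, chao_example.N).richness
        s_n1 = pn.extrapolate(chao_example, 1).richness
        s_n2 = pn.extrapolate(chao_example, 2).richness
        assert s_n <= s_n1 <= s_n2

    def test_variance_grows_with_extrapolation(self, chao_example):
        v1 = pn.extrapolate(chao_example, 1).variance
        v20 = pn.extrapolate(chao_example, 20).variance
        assert v20 >= v1 >= pn.rarefy(chao_example, chao_example.N).variance


class TestRichnessEstimators:
    def test_chao2_closed_form(self, chao_example):
        ests = {e.estimator: e for e in pn.richness_estimators(chao_example)}
        # 10 + (9/10) * 16 / 4
        assert ests["chao2"].value == pytest.approx(13.6)

    def test_jackknife1_closed_form(self):
        samples = [f"s{j}" for j in range(20)]
        taxa_sets = {f"sing{i}": {samples[i]} for i in range(5)}
        taxa_sets.update({f"com{i}": set(samples[:10]) for i in range(5)})
        inc = incidence_from_dict(taxa_sets, samples)
        ests = {e.estimator: e for e in pn.richness_estimators(inc)}
        assert ests["jackknife1"].value == pytest.approx(14.75)

    def test_bootstrap_ubiquitous_species(self):
        inc = incidence_from_dict({"only": {"s1", "s2", "s3"}}, ["s1", "s2", "s3"])
        ests = {e.estimator: e for e in pn.richness_estimators(inc)}
        assert ests["bootstrap"].value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_correction_estimators_at_least_observed(self, seed):
        # note: jackknife2's closed form can dip below S_obs when doubletons
        # outnumber singletons, so it is checked against its formula instead
        rng = np.random.default_rng(seed)
        inc = random_incidence(rng)
        ests = {e.estimator: e.value for e in pn.richness_estimators(inc)}
        for name in ("chao2", "jackknife1", "ice"):
            assert ests[name] >= inc.S_obs - 1e-9
        N, Q1, Q2 = inc.N, inc.q(1), inc.q(2)
        expected_j2 = (
            inc.S_obs + Q1 * (2 * N - 3) / N - Q2 * (N - 2) ** 2 / (N * (N - 1))
        )
        assert ests["jackknife2"] == pytest.approx(expected_j2)
        if Q1 >= Q2:
            assert ests["jackknife2"] >= inc.S_obs - 1e-9

    def test_complete_sampling_returns_observed(self):
        taxa_sets = {f"t{i}": {"s1", "s2", "s3", "s4"} for i in range(6)}
        inc = incidence_from_dict(taxa_sets, ["s1", "s2", "s3", "s4"])
        for est in pn.richness_estimators(inc):
            assert est.value == pytest.approx(inc.S_obs)

    def test_chao2_bias_corrected_when_no_doubletons(self):
        samples = [f"s{j}" for j in range(6)]
        taxa_sets = {f"sing{i}": {samples[i]} for i in range(3)}
        taxa_sets.update({f"com{i}": set(samples) for i in range(4)})
        inc = incidence_from_dict(taxa_sets, samples)
        ests = {e.estimator: e.value for e in pn.richness_estimators(inc)}
        # 7 + (5/6) * 3*2/2
        assert ests["chao2"] == pytest.approx(7 + (5 / 6) * 3)

    def test_single_sample_undefined(self):
        inc = incidence_from_dict({"a": {"s1"}, "b": {"s1"}}, ["s1"])
        with pytest.raises(pn.UndefinedMetricError):
            pn.richness_estimators(inc)


class TestEstimatorCurves:
    def test_final_intensity_equals_full_matrix(self, chao_example):
        curves = pn.estimator_curves(chao_example, reps=30, seed=0)
        full = {e.estimator: e.value for e in pn.richness_estimators(chao_example)}
        for name, frame in curves.items():
            last = frame.iloc[-1]
            assert last["intensity"] == chao_example.N
            assert last["mean"] == pytest.approx(full[name])
            # conditional interval collapses at the full sampling level
            assert last["cond_ci_high"] - last["cond_ci_low"] == pytest.approx(0)

    def test_unconditional_open_at_full_intensity(self, chao_example):
        curves = pn.estimator_curves(chao_example, reps=30, seed=0)
        last = curves["chao2"].iloc[-1]
        assert last["uncond_ci_high"] - last["uncond_ci_low"] > 0

    def test_reproducible_under_seed(self, chao_example):
        a = pn.estimator_curves(chao_example, reps=10, seed=42)
        b = pn.estimator_curves(chao_example, reps=10, seed=42)
        for name in a:
            pd.testing.assert_frame_equal(a[name], b[name])


class TestCompareBiozones:
    def test_identical_curves_not_distinguishable(self, chao_example):
        curve = pn.rarefaction_curve(chao_example)
        result = pn.compare_biozones(curve, curve)
        assert result.verdict == "not_distinguishable"
        assert result.richness_ratio == pytest.approx(1.0)

    def test_touching_intervals_count_as_overlap(self):
        from paleonet.diversity import CurvePoint
        a = pn.RarefactionCurve(label="a", N=3, S_obs=5, points=[
            CurvePoint(3, 5.0, 1.0, 4.0, 6.0, "observed")
        ])
        b = pn.RarefactionCurve(label="b", N=3, S_obs=8, points=[
            CurvePoint(3, 8.0, 1.0, 6.0, 10.0, "observed")
        ])
        assert pn.compare_biozones(a, b).verdict == "not_distinguishable"

    def test_disjoint_intervals_significant(self):
        from paleonet.diversity import CurvePoint
        a = pn.RarefactionCurve(label="a", N=3, S_obs=5, points=[
            CurvePoint(3, 5.0, 1.0, 4.0, 5.9, "observed")
        ])
        b = pn.RarefactionCurve(label="b", N=3, S_obs=8, points=[
            CurvePoint(3, 8.0, 1.0, 6.0, 10.0, "observed")
        ])
        result = pn.compare_biozones(a, b)
        assert result.verdict == "significantly_different"
        assert result.richness_ratio == pytest.approx(8 / 5)
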