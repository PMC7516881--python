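"""Mixture model, centroids, clustering, simplification, classification."""

import math

import numpy as np
import pytest

from gaussfr import (
    DGMM,
    Gaussian,
    agglomerate,
    bregman_left_centroid,
    classify_points,
    dgmm_logpdf,
    dgmm_sample,
    fit_dgmm,
    fr_centroid,
    kl_monte_carlo,
    learn_components,
    linkage_distance,
    make_gaussian,
    simplify,
)
from gaussfr.synthetic import make_planted_dgmm


def uv_mix(weights, params):
    """Univariate DGMM from (mu, sigma) pairs."""
    comps = tuple(make_gaussian([m], [[s * s]]) for m, s in params)
    return DGMM(np.asarray(weights, float), comps)


class TestDensity:
    def test_single_standard_component(self):
        f = uv_mix([1.0], [(0.0, 1.0)])
        assert dgmm_logpdf(f, [0.0]) == pytest.approx(math.log(1 / math.sqrt(2 * math.pi)))

    def test_zero_weight_component_ignored(self):
        f = uv_mix([1.0, 0.0], [(0.0, 1.0), (5.0, 2.0)])
        g = uv_mix([1.0], [(0.0, 1.0)])
        for x in (-1.0, 0.3, 2.0):
            assert dgmm_logpdf(f, [x]) == pytest.approx(dgmm_logpdf(g, [x]))

    def test_symmetric_mixture_density_symmetric(self):
        f = uv_mix([0.5, 0.5], [(-2.0, 1.0), (2.0, 1.0)])
        for x in (0.5, 1.7):
            assert dgmm_logpdf(f, [x]) == pytest.approx(dgmm_logpdf(f, [-x]))


class TestSampling:
    def test_reproducible_and_respects_weights(self):
        f = uv_mix([0.7, 0.3], [(-10.0, 1.0), (10.0, 1.0)])
        X1 = dgmm_sample(f, 2000, seed=42)
        X2 = dgmm_sample(f, 2000, seed=42)
        np.testing.assert_array_equal(X1, X2)
        frac = float((X1[:, 0] > 0).mean())
        # binomial 4-sigma band around 0.3
        assert abs(frac - 0.3) < 4 * math.sqrt(0.3 * 0.7 / 2000)

    def test_degenerate_weights(self):
        f = uv_mix([1.0, 0.0], [(3.0, 0.5), (-3.0, 0.5)])
        X = dgmm_sample(f, 500, seed=0)
        assert (X[:, 0] > 0).all()
        assert X[:, 0].mean() == pytest.approx(3.0, abs=4 * 0.5 / math.sqrt(500))


class TestKL:
    def test_identical_mixtures_give_exact_zero(self):
        f = uv_mix([0.4, 0.6], [(0.0, 1.0), (3.0, 2.0)])
        est = kl_monte_carlo(f, f, n=200, seed=1)
        assert est.value == 0.0 and est.std_error == 0.0

    def test_two_gaussians_closed_form(self):
        delta = 1.5
        f = uv_mix([1.0], [(0.0, 1.0)])
        g = uv_mix([1.0], [(delta, 1.0)])
        est = kl_monte_carlo(f, g, n=20000, seed=3)
        assert abs(est.value - delta**2 / 2) < 3 * est.std_error

    def test_nonnegative_within_noise(self):
        rng = np.random.default_rng(9)
        for k in range(5):
            f = uv_mix([0.5, 0.5], [(rng.normal(), 1.0), (rng.normal(), 2.0)])
            g = uv_mix([0.5, 0.5], [(rng.normal(), 1.5), (rng.normal(), 1.0)])
            est = kl_monte_carlo(f, g, n=4000, seed=k)
            assert est.value > -3 * est.std_error


class TestCentroids:
    def test_single_member_is_fixed_point(self):
        g = make_gaussian([1.0, -2.0], np.diag([0.25, 4.0]))
        for fn in (fr_centroid, bregman_left_centroid):
            c = fn([(1.0, g)])
            assert c.close_to(g, tol=1e-9)

    def test_symmetric_pair_values(self):
        a = make_gaussian([-1.0], [[1.0]])
        b = make_gaussian([1.0], [[1.0]])
        c = fr_centroid([(0.5, a), (0.5, b)])
        assert c.mu[0] == pytest.approx(0.0, abs=1e-12)
        assert c.sigma[0, 0] == pytest.approx(1.5, rel=1e-10)  # sqrt(1.5)^2
        c = bregman_left_centroid([(0.5, a), (0.5, b)])
        assert c.mu[0] == pytest.approx(0.0, abs=1e-12)
        assert c.sigma[0, 0] == pytest.approx(2.0, rel=1e-12)

    def test_permutation_invariance(self):
        comps = [
            (0.2, make_gaussian([0.0, 1.0], np.diag([1.0, 2.0]))),
            (0.5, make_gaussian([2.0, -1.0], np.diag([0.5, 1.0]))),
            (0.3, make_gaussian([-1.0, 0.5], np.diag([2.0, 0.25]))),
        ]
        c1 = fr_centroid(comps)
        c2 = fr_centroid(comps[::-1])
        assert c1.close_to(c2, tol=1e-10)

    def test_fr_centroid_mean_in_convex_hull(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            comps = [
                (float(rng.uniform(0.1, 1)), make_gaussian(rng.uniform(-3, 3, 2), np.diag(rng.uniform(0.2, 2, 2))))
                for _ in range(4)
            ]
            c = fr_centroid(comps)
            mus = np.stack([g.mu for _, g in comps])
            assert (c.mu >= mus.min(axis=0) - 1e-9).all()
            assert (c.mu <= mus.max(axis=0) + 1e-9).all()

    def test_bregman_centroid_is_kl_optimal_merge(self):
        # KL(cluster mixture || centroid) is a local minimum over perturbations
        cluster = [
            (0.6, make_gaussian([0.0], [[1.0]])),
            (0.4, make_gaussian([2.0], [[0.5]])),
        ]
        c = bregman_left_centroid(cluster)
        f = DGMM(np.array([0.6, 0.4]), tuple(g for _, g in cluster))

        def kl_to(g):
            return kl_monte_carlo(f, DGMM(np.array([1.0]), (g,)), n=20000, seed=11).value

        base = kl_to(c)
        rng = np.random.default_rng(2)
        for _ in range(6):
            pert = make_gaussian(
                c.mu + 0.15 * rng.standard_normal(1),
                [[float(c.sigma[0, 0] * math.exp(0.15 * rng.standard_normal()))]],
            )
            assert base <= kl_to(pert) + 1e-3

    def test_empty_cluster_rejected(self):
        for fn in (fr_centroid, bregman_left_centroid):
            with pytest.raises(ValueError):
                fn([])


class TestLinkage:
    def test_singletons_all_kinds_equal(self):
        from gaussfr import dist_diagonal

        a = make_gaussian([0.0], [[1.0]])
        b = make_gaussian([2.0], [[1.0]])
        d = dist_diagonal(a, b)
        for kind in ("single", "complete", "average"):
            assert linkage_distance([a], [b], kind) == pytest.approx(d)
        assert linkage_distance([a], [a], "complete") == 0.0

    def test_order_statistics_ordering(self):
        A = [make_gaussian([x], [[1.0]]) for x in (0.0, 0.5)]
        B = [make_gaussian([x], [[1.0]]) for x in (3.0, 5.0)]
        single = linkage_distance(A, B, "single")
        average = linkage_distance(A, B, "average")
        complete = linkage_distance(A, B, "complete")
        assert single <= average <= complete


class TestAgglomerate:
    def test_single_component_empty_tree(self):
        f = uv_mix([1.0], [(0.0, 1.0)])
        tree = agglomerate(f)
        assert tree.merges == () and tree.partition(1) == [[0]]

    def test_identical_components_merge_first(self):
        f = uv_mix([0.3, 0.3, 0.4], [(0.0, 1.0), (0.0, 1.0), (8.0, 1.0)])
        tree = agglomerate(f)
        i, j, d = tree.merges[0]
        assert (i, j) == (0, 1) and d == pytest.approx(0.0, abs=1e-12)

    def test_recovers_planted_groups(self):
        planted = make_planted_dgmm(n=2, groups=2, per_group=3, seed=0)
        tree = agglomerate(planted.mixture, "complete")
        parts = {tuple(p) for p in tree.partition(2)}
        assert parts == {tuple(g) for g in planted.partition}


class TestSimplify:
    def test_level_m_returns_input(self):
        f = uv_mix([0.25, 0.75], [(0.0, 1.0), (4.0, 2.0)])
        g = simplify(f, 2)
        assert g.m == 2 and np.isclose(g.weights.sum(), 1.0)
        assert {round(float(c.mu[0]), 9) for c in g.components} == {0.0, 4.0}

    def test_full_merge_uses_centroid(self):
        f = uv_mix([0.5, 0.5], [(-1.0, 1.0), (1.0, 1.0)])
        g = simplify(f, 1, centroid="fisher-rao")
        assert g.m == 1 and g.weights[0] == pytest.approx(1.0)
        assert g.components[0].mu[0] == pytest.approx(0.0, abs=1e-12)
        assert g.components[0].sigma[0, 0] == pytest.approx(1.5, rel=1e-9)

    def test_weights_sum_to_one_at_every_level(self):
        planted = make_planted_dgmm(n=3, groups=3, per_group=4, seed=1)
        f = planted.mixture
        tree = agglomerate(f)
        for l in range(1, f.m + 1):
            g = simplify(f, l, tree=tree)
            assert g.m == l
            assert g.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_level(self):
        f = uv_mix([1.0], [(0.0, 1.0)])
        with pytest.raises(ValueError):
            simplify(f, 2)


class TestLearnComponents:
    def test_huge_budget_gives_one_component(self):
        planted = make_planted_dgmm(n=2, groups=2, per_group=2, seed=3)
        l, g = learn_components(planted.mixture, tau=1e9, n_mc=500, seed=0)
        assert l == 1 and g.m == 1

    def test_duplicate_components_merge_for_free(self):
        f = uv_mix([0.3, 0.3, 0.4], [(0.0, 1.0), (0.0, 1.0), (9.0, 1.0)])
        l, g = learn_components(f, tau=1e-6, n_mc=2000, seed=0)
        assert l == 2

    def test_planted_groups_found_below_between_group_kl(self):
        planted = make_planted_dgmm(n=2, groups=3, per_group=3, seed=4)
        l, g = learn_components(planted.mixture, tau=0.2, n_mc=2000, seed=0)
        assert l <= 3


class TestClassify:
    def test_assigns_nearest_component_and_ignores_weights(self):
        comps = (
            make_gaussian([-5.0], [[1.0]]),
            make_gaussian([5.0], [[1.0]]),
        )
        f1 = DGMM(np.array([0.99, 0.01]), comps)
        f2 = DGMM(np.array([0.01, 0.99]), comps)
        X = [[-5.0], [5.0], [-1.0], [1.0]]
        np.testing.assert_array_equal(classify_points(f1, X), [0, 1, 0, 1])
        np.testing.assert_array_equal(classify_points(f1, X), classify_points(f2, X))

    def test_tie_goes_to_lowest_index(self):
        comps = (
            make_gaussian([-1.0], [[1.0]]),
            make_gaussian([1.0], [[1.0]]),
        )
        f = DGMM(np.array([0.5, 0.5]), comps)
        assert classify_points(f, [[0.0]])[0] == 0


class TestFitDGMM:
    def test_single_cluster_matches_moments(self):
        rng = np.random.default_rng(0)
        X = 2.0 + 0.5 * rng.standard_normal((2000, 2))
        f = fit_dgmm(X, 1, seed=0)
        np.testing.assert_allclose(f.components[0].mu, X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(
            np.diag(f.components[0].sigma), X.var(axis=0), rtol=1e-2
        )

    def test_planted_two_cluster_recovery(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [
                rng.standard_normal((500, 2)) * 0.5 + [-5, 0],
                rng.standard_normal((500, 2)) * 0.5 + [5, 0],
            ]
        )
        f = fit_dgmm(X, 2, seed=0)
        centers = sorted(float(c.mu[0]) for c in f.components)
        assert centers[0] == pytest.approx(-5, abs=0.1)
        assert centers[1] == pytest.approx(5, abs=0.1)

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError):
            fit_dgmm(np.zeros((2, 2)), 3)
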