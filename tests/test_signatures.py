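"""Local graph construction, SSD and the spectral comparator signatures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from graphsig import (
    ObservationBundle,
    build_local_graph,
    default_epsilon,
    dks,
    hks,
    multiscale_ssd,
    spectral_decompose,
    ssd,
    wks,
)
from graphsig.signatures import DegenerateScaleError


class TestBuildLocalGraph:
    def test_identical_features_give_unit_weights(self):
        bundle = ObservationBundle(np.ones((2, 3)))
        graph = build_local_graph(bundle, epsilon=1.0)
        assert np.allclose(graph.weights, 1.0)
        assert np.allclose(graph.transition, 0.5)

    def test_analytic_off_diagonal_weight(self):
        eps = 0.7
        bundle = ObservationBundle(np.array([[0.0], [np.sqrt(2 * eps)]]))
        graph = build_local_graph(bundle, eps)
        assert graph.weights[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_weights_match_bruteforce_distances(self, make_bundle, seed):
        bundle = make_bundle(m=5, d=6, seed=seed)
        eps = 0.9
        graph = build_local_graph(bundle, eps)
        F = bundle.features
        for k in range(5):
            for l in range(5):
                expected = np.exp(-np.sum((F[k] - F[l]) ** 2) / (2 * eps))
                assert graph.weights[k, l] == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs_rejected(self, make_bundle):
        with pytest.raises(ValueError):
            ObservationBundle(np.array([[np.nan, 1.0], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            build_local_graph(make_bundle(), epsilon=0.0)
        with pytest.raises(ValueError):
            build_local_graph(make_bundle(), epsilon=-1.0)


class TestDefaultEpsilon:
    def test_collinear_scalar_features(self):
        bundle = ObservationBundle(np.array([[0.0], [1.0], [2.0]]))
        # squared pairwise distances {1, 1, 4} -> median 1
        assert default_epsilon(bundle) == pytest.approx(1.0)

    def test_duplicated_rows_error(self):
        with pytest.raises(DegenerateScaleError):
            default_epsilon(ObservationBundle(np.ones((3, 4))))

    def test_matches_bruteforce_median(self, make_bundle):
        bundle = make_bundle(m=6, d=5, seed=7)
        F = bundle.features
        dists = sorted(
            np.sum((F[k] - F[l]) ** 2)
            for k in range(6)
            for l in range(k + 1, 6)
        )
        assert default_epsilon(bundle) == pytest.approx(np.median(dists), rel=1e-12)


class TestSSD:
    def test_uniform_for_all_ones_weights(self):
        graph = build_local_graph(ObservationBundle(np.zeros((4, 2))), 1.0)
        assert np.allclose(ssd(graph).values, 0.25)

    def test_two_node_graph_is_half_half(self, rng):
        bundle = ObservationBundle(rng.normal(size=(2, 5)))
        graph = build_local_graph(bundle, 0.3)
        assert np.allclose(ssd(graph).values, 0.5)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_power_iteration(self, make_graph, seed):
        graph = make_graph(m=6, seed=seed)
        pi = ssd(graph).values
        gen = np.random.default_rng(seed)
        start = gen.dirichlet(np.ones(6))
        iterated = start @ np.linalg.matrix_power(graph.transition, 500)
        assert np.allclose(pi, iterated, atol=1e-8)

    def test_positivity_normalization_stationarity(self, make_graph):
        for seed in range(25):
            graph = make_graph(m=5, seed=seed)
            pi = ssd(graph).values
            assert np.all(pi > 0)
            assert abs(pi.sum() - 1.0) < 1e-10
            assert np.max(np.abs(pi @ graph.transition - pi)) < 1e-10

    def test_convergence_monotone_in_t(self, make_graph):
        graph = make_graph(m=6, seed=11)
        lam = spectral_decompose(graph).eigenvalues
        assert lam[1] < 0.99
        pi = ssd(graph).values
        gen = np.random.default_rng(0)
        current = gen.dirichlet(np.ones(6))
        errors = []
        P = graph.transition
        for _ in range(1000):
            current = current @ P
            errors.append(np.abs(current - pi).sum())
        assert all(a >= b - 1e-14 for a, b in zip(errors, errors[1:]))
        assert errors[-1] < 1e-6

    def test_uniform_limit_at_large_epsilon(self, make_bundle):
        bundle = make_bundle(m=5, d=6, seed=2)
        scale = default_epsilon(bundle)
        graph = build_local_graph(bundle, 1e6 * scale)
        assert np.max(np.abs(ssd(graph).values - 0.2)) < 1e-4

    def test_degree_identity(self, make_graph):
        graph = make_graph(m=5, seed=9)
        for k in range(5):
            assert graph.transition[k, k] == pytest.approx(
                1.0 / graph.degrees[k], rel=1e-14
            )


class TestSpectralDecomposition:
    def test_all_ones_weights_rank_one(self):
        graph = build_local_graph(ObservationBundle(np.zeros((4, 2))), 1.0)
        lam = spectral_decompose(graph).eigenvalues
        assert lam[0] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(lam[1:], 0.0, atol=1e-10)

    def test_top_eigenpair_is_stochastic(self, make_graph):
        dec = spectral_decompose(make_graph(m=5, seed=1))
        assert dec.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        psi1 = dec.right_vectors[:, 0]
        assert np.allclose(psi1, psi1[0], atol=1e-10)  # constant right vector
        assert np.all(np.abs(dec.eigenvalues) <= 1 + 1e-10)

    @pytest.mark.parametrize("t", [1, 2, 3])
    def test_reconstructs_matrix_powers(self, make_graph, t):
        graph = make_graph(m=5, seed=5)
        dec = spectral_decompose(graph)
        direct = np.linalg.matrix_power(graph.transition, t)
        assert np.max(np.abs(dec.reconstruct(t) - direct)) < 1e-8

    def test_biorthogonality(self, make_graph):
        dec = spectral_decompose(make_graph(m=6, seed=8))
        gram = dec.right_vectors.T @ dec.left_vectors
        assert np.allclose(gram, np.eye(6), atol=1e-8)


class TestDKS:
    def test_t_zero_is_inverse_degrees(self, make_graph):
        graph = make_graph(m=5, seed=3)
        assert np.allclose(dks(graph, 0).values, 1.0 / graph.degrees, atol=1e-10)

    def test_t_one_proportional_to_inverse_ssd_squared(self, make_graph):
        for seed in range(5):
            graph = make_graph(m=5, seed=seed)
            pi = ssd(graph).values
            product = dks(graph, 1).values * pi**2
            assert np.max(np.abs(product - product.mean())) < 1e-8 * product.mean()

    def test_large_t_keeps_only_stationary_component(self, make_graph):
        graph = make_graph(m=5, seed=4)
        dec = spectral_decompose(graph)
        limit = dec.right_vectors[:, 0] ** 2
        assert np.allclose(dks(graph, 400).values, limit, atol=1e-10)

    def test_negative_t_rejected(self, make_graph):
        with pytest.raises(ValueError):
            dks(make_graph(), -1.0)


class TestHKS:
    def test_t_zero_matches_dks_t_zero(self, make_graph):
        graph = make_graph(m=5, seed=6)
        assert np.allclose(hks(graph, 0).values, dks(graph, 0).values)

    def test_small_t_approximates_dks(self, make_graph):
        for seed in range(3):
            graph = make_graph(m=5, seed=seed)
            t = 1e-3
            h = hks(graph, t).values
            k = dks(graph, t).values
            # agreement is first-order in t
            assert np.max(np.abs(h - k)) < t

    def test_two_level_spectrum_for_all_ones_weights(self):
        graph = build_local_graph(ObservationBundle(np.zeros((4, 2))), 1.0)
        dec = spectral_decompose(graph)
        t = 0.7
        expected = dec.right_vectors[:, 0] ** 2 + np.exp(-t) * (
            dec.right_vectors[:, 1:] ** 2
        ).sum(axis=1)
        assert np.allclose(hks(graph, t).values, expected, atol=1e-10)


class TestWKS:
    def test_flat_filter_limit(self, make_graph):
        graph = make_graph(m=5, seed=2)
        dec = spectral_decompose(graph)
        included = (1.0 - dec.eigenvalues) > 1e-12
        flat = (dec.right_vectors[:, included] ** 2).mean(axis=1)
        assert np.allclose(wks(graph, t=0.5, sigma=1e6).values, flat, atol=1e-8)

    def test_band_centered_on_second_eigenvalue(self, make_graph):
        graph = make_graph(m=6, seed=10)
        dec = spectral_decompose(graph)
        t = 1.0 - dec.eigenvalues[1]
        log_e = np.log(1.0 - dec.eigenvalues[1:])
        sigma = (log_e.max() - log_e.min()) / 7.0
        band = np.exp(-((np.log(t) - log_e) ** 2) / (2 * sigma**2))
        assert np.argmax(band) == 0  # band j=2 gets the maximal weight
        expected = (dec.right_vectors[:, 1:] ** 2) @ (band / band.sum())
        assert np.allclose(wks(graph, t).values, expected, atol=1e-10)

    def test_invalid_parameters(self, make_graph):
        with pytest.raises(ValueError):
            wks(make_graph(), t=0.0)
        with pytest.raises(ValueError):
            wks(make_graph(), t=1.0, sigma=-1.0)


class TestMultiscaleSSD:
    def test_singleton_equals_plain_ssd(self, make_bundle):
        bundle = make_bundle(seed=1)
        eps = default_epsilon(bundle)
        stack = multiscale_ssd(bundle, [eps])
        assert np.allclose(stack[0], ssd(build_local_graph(bundle, eps)).values)

    def test_rows_normalized_and_large_scale_uniform(self, make_bundle):
        bundle = make_bundle(m=5, seed=3)
        eps = default_epsilon(bundle)
        stack = multiscale_ssd(bundle, [eps / 10, eps, 1e8 * eps])
        assert np.allclose(stack.sum(axis=1), 1.0, atol=1e-10)
        assert np.max(np.abs(stack[-1] - 0.2)) < 1e-4

    def test_small_scale_concentrates_within_clusters(self):
        # two tight clusters of features far apart
        gen = np.random.default_rng(0)
        F = np.vstack([gen.normal(0, 0.1, (3, 4)), gen.normal(10, 0.1, (3, 4))])
        bundle = ObservationBundle(F)
        stack = multiscale_ssd(bundle, [0.1, 1e4])
        # per-scale rows equal brute-force normalized degrees
        for row, eps in zip(stack, [0.1, 1e4]):
            sq = ((F[:, None, :] - F[None, :, :]) ** 2).sum(-1)
            deg = np.exp(-sq / (2 * eps)).sum(axis=1)
            assert np.allclose(row, deg / deg.sum(), rtol=1e-10)
        # at the small scale, within-cluster mass dominates the profile:
        # degrees reflect only the 3 nearby features, so rows are ~1/6 with
        # far smaller cross-cluster contributions than at the large scale
        small, large = stack
        assert np.max(np.abs(large - 1 / 6)) < np.max(np.abs(small - 1 / 6)) + 1e-6

    def test_empty_scale_list_rejected(self, make_bundle):
        with pytest.raises(ValueError):
            multiscale_ssd(make_bundle(), [])


bundle_arrays = arrays(
    np.float64,
    st.tuples(st.integers(2, 6), st.integers(1, 5)),
    elements=st.floats(-5, 5, allow_nan=False, allow_infinity=False),
)


class TestPropertyBased:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(features=bundle_arrays)
    def test_ssd_is_a_stationary_distribution(self, features):
        graph = build_local_graph(ObservationBundle(features), epsilon=1.0)
        pi = ssd(graph).values
        assert np.all(pi > 0)
        assert abs(pi.sum() - 1.0) < 1e-10
        assert np.max(np.abs(pi @ graph.transition - pi)) < 1e-10

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(features=bundle_arrays, shift=st.floats(-100, 100))
    def test_translation_invariance(self, features, shift):
        base = ssd(build_local_graph(ObservationBundle(features), 1.0)).values
        moved = ssd(build_local_graph(
            ObservationBundle(features + shift), 1.0)).values
        assert np.allclose(base, moved, atol=1e-10)


class TestInvariances:
    def test_permutation_equivariance(self, make_bundle):
        bundle = make_bundle(m=6, seed=5)
        eps = default_epsilon(bundle)
        perm = np.random.default_rng(1).permutation(6)
        permuted = ObservationBundle(bundle.features[perm])
        for fn in (
            lambda g: ssd(g).values,
            lambda g: dks(g, 1.5).values,
            lambda g: hks(g, 0.8).values,
        ):
            base = fn(build_local_graph(bundle, eps))
            shuffled = fn(build_local_graph(permuted, eps))
            assert np.allclose(shuffled, base[perm], atol=1e-10)

    def test_isometry_invariance(self, make_bundle, rng):
        bundle = make_bundle(m=5, d=4, seed=6)
        eps = default_epsilon(bundle)
        shift = rng.normal(size=4)
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        moved = ObservationBundle((bundle.features + shift) @ q)
        assert np.allclose(
            ssd(build_local_graph(bundle, eps)).values,
            ssd(build_local_graph(moved, eps)).values,
            atol=1e-10,
        )
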