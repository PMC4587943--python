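import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

import fireweek as fw
from fireweek.model import (
    ANTHROME_LEVELS,
    RELIGION_LEVELS,
    cell_design_row,
    design_matrix,
    design_for_regions,
)
from conftest import labels_frame, make_single_region_panel


class TestModelSpec:
    @pytest.mark.parametrize(
        "text",
        ["R + W + A", "R + W + R:W + ICAR", "R + W + A + R:W + R:A + W:A + R:W:A + ICAR", "1"],
    )
    def test_string_round_trip(self, text):
        spec = fw.ModelSpec.from_string(text)
        assert fw.ModelSpec.from_string(spec.to_string()) == spec

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="requires main effects"):
            fw.ModelSpec(frozenset({"R", "R:W"}))

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown model terms"):
            fw.ModelSpec(frozenset({"Q"}))


class TestNbLogPmf:
    def test_zero_count_closed_form(self):
        mu, theta = 3.7, 2.2
        assert fw.nb_log_pmf(0, mu, theta) == pytest.approx(theta * np.log(theta / (mu + theta)))

    def test_unit_case(self):
        assert fw.nb_log_pmf(1, 1.0, 1.0) == pytest.approx(np.log(0.25))

    @pytest.mark.parametrize("seed", range(5))
    def test_normalizes_to_one(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(4):
            mu = rng.uniform(0.5, 30.0)
            theta = rng.uniform(0.3, 10.0)
            total = np.exp(fw.nb_log_pmf(np.arange(5001), mu, theta)).sum()
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_poisson_limit_at_large_theta(self):
        y = np.arange(101)
        mu = 7.3
        nb = fw.nb_log_pmf(y, mu, 1e9)
        np.testing.assert_allclose(nb, poisson.logpmf(y, mu), atol=1e-5)

    def test_moments_match_gamma_poisson_oracle(self):
        mu, theta = 8.0, 2.5
        rng = np.random.default_rng(0)
        draws = rng.poisson(rng.gamma(theta, mu / theta, size=1_000_000))
        assert draws.mean() == pytest.approx(mu, rel=0.01)
        assert draws.var() == pytest.approx(mu + mu**2 / theta, rel=0.01)
        # and the pmf agrees with the empirical frequencies
        vals, counts = np.unique(draws, return_counts=True)
        keep = counts > 5000
        np.testing.assert_allclose(
            counts[keep] / len(draws),
            np.exp(fw.nb_log_pmf(vals[keep], mu, theta)),
            rtol=0.05,
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fw.nb_log_pmf(-1, 1.0, 1.0)
        with pytest.raises(ValueError):
            fw.nb_log_pmf(1.5, 1.0, 1.0)
        with pytest.raises(ValueError):
            fw.nb_log_pmf(1, -1.0, 1.0)

    def test_no_overflow_at_huge_counts(self):
        assert np.isfinite(fw.nb_log_pmf(10_000_000, 1e6, 2.0))


def _full_factorial_labels():
    rows = []
    k = 0
    for rel in RELIGION_LEVELS:
        for ant in ANTHROME_LEVELS:
            rows.append((f"r{k}", rel, ant))
            k += 1
    return pd.DataFrame(rows, columns=["region_id", "religion_label", "anthrome_label"])


ALL_SPECS = [
    "R + W + A",
    "R + W + A + R:W",
    "R + W + A + R:W + R:A",
    "R + W + A + R:W + W:A",
    "R + W + A + R:W + R:A + W:A",
    "R + W + A + R:W + R:A + W:A + R:W:A",
    "R + W",
    "R + W + R:W",
]


class TestDesignMatrix:
    @pytest.mark.parametrize(
        "text, expected_cols",
        [
            ("R + W + A", 1 + 2 + 6 + 4),
            ("R + W + R:W", 1 + 2 + 6 + 12),
            ("R + W + A + R:W + R:A + W:A + R:W:A", 105),
        ],
    )
    def test_column_counts_under_corner_coding(self, text, expected_cols):
        labels = _full_factorial_labels()
        X, names = design_for_regions(labels, fw.ModelSpec.from_string(text))
        assert X.shape == (len(labels) * 7, expected_cols)
        assert len(names) == expected_cols
        assert names[0] == "Intercept"

    @pytest.mark.parametrize("text", ALL_SPECS)
    def test_full_column_rank_on_full_factorial(self, text):
        labels = _full_factorial_labels()
        X, _ = design_for_regions(labels, fw.ModelSpec.from_string(text))
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_saturated_design_spans_all_cell_means(self):
        """105 columns reproduce every 3·7·5 cell mean exactly (brute force)."""
        labels = _full_factorial_labels()
        spec = fw.ModelSpec.from_string("R + W + A + R:W + R:A + W:A + R:W:A")
        X, _ = design_for_regions(labels, spec)
        rng = np.random.default_rng(1)
        target = rng.normal(size=X.shape[0])  # arbitrary cell means, one row per cell
        coef, *_ = np.linalg.lstsq(X, target, rcond=None)
        np.testing.assert_allclose(X @ coef, target, atol=1e-8)

    def test_anthrome_terms_require_anthrome_labels(self):
        with pytest.raises(ValueError, match="anthrome"):
            design_matrix(
                np.array(["Christian"]), np.array([1]), fw.ModelSpec.from_string("R + W + A")
            )

    def test_cell_design_row_matches_design_matrix(self):
        spec = fw.ModelSpec.from_string("R + W + R:W")
        row = cell_design_row(spec, "Muslim", 5)
        X, _ = design_matrix(np.array(["Muslim"]), np.array([5]), spec)
        np.testing.assert_array_equal(row, X[0])


class TestLinearPredictor:
    def test_offset_only(self):
        X = np.ones((1, 1))
        mu = fw.linear_predictor(X, np.zeros(1), np.log([100.0]), return_mu=True)
        assert mu[0] == pytest.approx(100.0)

    def test_intercept_doubles_offset(self):
        X = np.ones((1, 1))
        mu = fw.linear_predictor(X, np.array([np.log(2.0)]), np.log([50.0]), return_mu=True)
        assert mu[0] == pytest.approx(100.0)

    def test_matches_observation_loop(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 4))
        alpha = rng.normal(size=4)
        off = rng.uniform(1, 3, size=12)
        z = rng.normal(size=12)
        eta = fw.linear_predictor(X, alpha, off, z)
        for i in range(12):
            expected = off[i] + sum(X[i, j] * alpha[j] for j in range(4)) + z[i]
            assert eta[i] == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            fw.linear_predictor(np.ones((2, 3)), np.zeros(2), np.zeros(2))


class TestIcarQuadratic:
    def test_constant_field_in_null_space(self):
        g = fw.build_adjacency(list("abcd"), edges=[("a", "b"), ("b", "c"), ("c", "d")])
        assert fw.icar_quadratic(np.full(4, 3.3), g) == 0.0

    def test_two_node_edge(self):
        g = fw.build_adjacency(["a", "b"], edges=[("a", "b")])
        assert fw.icar_quadratic(np.array([1.0, -1.0]), g) == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_laplacian_quadratic_form(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        n = 8
        ids = [f"n{i}" for i in range(n)]
        edges = [
            (ids[i], ids[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.4
        ]
        g = fw.build_adjacency(ids, edges=edges)
        z = rng.normal(size=n)
        Q = nx.laplacian_matrix(g.graph, nodelist=ids).toarray()  # D - W oracle
        assert fw.icar_quadratic(z, g) == pytest.approx(float(z @ Q @ z))

    def test_invariant_to_per_component_shift(self):
        ids = list("abcde")
        g = fw.build_adjacency(ids, edges=[("a", "b"), ("d", "e")])
        rng = np.random.default_rng(1)
        z = rng.normal(size=5)
        shifted = z.copy()
        shifted[:3] += 4.2  # component {a,b} plus isolated c
        shifted[3:] -= 1.7  # component {d,e}
        assert fw.icar_quadratic(shifted, g) == pytest.approx(fw.icar_quadratic(z, g))

    def test_log_density_rank_correction(self):
        ids = list("abcde")
        g = fw.build_adjacency(ids, edges=[("a", "b"), ("d", "e")])  # n=5, k=3
        z = np.array([0.5, -0.5, 0.0, 0.2, -0.2])
        for tau in (0.5, 2.0):
            expected = 0.5 * 2 * np.log(tau) - 0.5 * tau * fw.icar_quadratic(z, g)
            assert fw.icar_log_density(z, tau, g) == pytest.approx(expected)


class TestLogLikelihood:
    def test_single_cell_equals_pmf(self):
        panel = make_single_region_panel([3, 0, 0, 0, 0, 0, 0])
        labels = labels_frame(["r0"])
        spec = fw.ModelSpec(frozenset())
        params = fw.Parameters(alpha=np.array([-1.0]), theta=2.0)
        ll = fw.log_likelihood(panel, spec, params, labels, np.log([50.0]))
        mu = 50.0 * np.exp(-1.0)
        expected = fw.nb_log_pmf(3, mu, 2.0) + 6 * fw.nb_log_pmf(0, mu, 2.0)
        assert ll == pytest.approx(expected)

    def test_replicate_additivity(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 20, size=(1, 7, 1))
        single = fw.FireCountPanel(counts, ["r0"], [2003])
        double = fw.FireCountPanel(np.repeat(counts, 2, axis=2), ["r0"], [2003, 2004])
        labels = labels_frame(["r0"])
        spec = fw.ModelSpec(frozenset({"R", "W"}))
        params = fw.Parameters(alpha=rng.normal(0, 0.2, size=9), theta=1.7)
        la = np.log([80.0])
        ll1 = fw.log_likelihood(single, spec, params, labels, la)
        ll2 = fw.log_likelihood(double, spec, params, labels, la)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        n, T = 4, 2
        counts = rng.integers(0, 30, size=(n, 7, T))
        ids = [f"r{i}" for i in range(n)]
        panel = fw.FireCountPanel(counts, ids, [2003, 2004])
        labels = labels_frame(ids, religion=["Christian", "Muslim", "Mixed", "Christian"])
        spec = fw.ModelSpec(frozenset({"R", "W"}), include_icar=True)
        areas = rng.uniform(50, 150, size=n)
        z = rng.normal(0, 0.3, size=n)
        z -= z.mean()
        params = fw.Parameters(alpha=rng.normal(0, 0.2, size=9), theta=2.0, tau=1.0, z=z)
        ll = fw.log_likelihood(panel, spec, params, labels, np.log(areas))
        X, _ = design_for_regions(labels, spec)
        total = 0.0
        for i in range(n):
            for w in range(7):
                eta = np.log(areas[i]) + X[i * 7 + w] @ params.alpha + z[i]
                for t in range(T):
                    total += fw.nb_log_pmf(int(counts[i, w, t]), np.exp(eta), 2.0)
        assert ll == pytest.approx(total, abs=1e-10)


class TestLogPosterior:
    @pytest.fixture
    def setup(self):
        rng = np.random.default_rng(6)
        ids = ["a", "b", "c"]
        counts = rng.integers(0, 25, size=(3, 7, 2))
        panel = fw.FireCountPanel(counts, ids, [2003, 2004])
        labels = labels_frame(ids)
        graph = fw.build_adjacency(ids, edges=[("a", "b"), ("b", "c")])
        log_areas = np.log(rng.uniform(50, 150, size=3))
        return panel, labels, graph, log_areas

    def test_without_icar_independent_of_z_and_tau(self, setup):
        panel, labels, graph, la = setup
        spec = fw.ModelSpec(frozenset({"W"}))
        priors = fw.PriorSpec()
        base = fw.Parameters(alpha=np.zeros(7), theta=1.0, tau=1.0, z=np.zeros(3))
        other = fw.Parameters(alpha=np.zeros(7), theta=1.0, tau=9.0, z=np.ones(3))
        assert fw.log_posterior(panel, spec, base, priors, graph, labels, la) == pytest.approx(
            fw.log_posterior(panel, spec, other, priors, graph, labels, la)
        )

    def test_flat_prior_limit_tracks_likelihood_plus_icar(self, setup):
        panel, labels, graph, la = setup
        spec = fw.ModelSpec(frozenset({"W"}), include_icar=True)
        flat = fw.PriorSpec(alpha_sd=1e8, log_theta_sd=1e8, tau_shape=1.0, tau_rate=1e-12)
        z = np.array([0.3, -0.1, -0.2])
        p1 = fw.Parameters(alpha=np.zeros(7), theta=2.0, tau=1.5, z=z)
        p2 = fw.Parameters(alpha=np.full(7, 0.1), theta=3.0, tau=0.5, z=-z)
        def target(p):
            return (
                fw.log_likelihood(panel, spec, p, labels, la)
                + fw.icar_log_density(p.z, p.tau, graph)
            )
        lp_diff = fw.log_posterior(panel, spec, p1, flat, graph, labels, la) - fw.log_posterior(
            panel, spec, p2, flat, graph, labels, la
        )
        assert lp_diff == pytest.approx(target(p1) - target(p2), abs=1e-4)

    def test_tau_change_with_constant_z_is_analytic(self, setup):
        """Doubling τ on flat z changes only the rank-correction and prior terms."""
        panel, labels, graph, la = setup
        spec = fw.ModelSpec(frozenset({"W"}), include_icar=True)
        priors = fw.PriorSpec()
        z = np.zeros(3)
        p1 = fw.Parameters(alpha=np.zeros(7), theta=2.0, tau=1.0, z=z)
        p2 = fw.Parameters(alpha=np.zeros(7), theta=2.0, tau=2.0, z=z)
        n_minus_k = graph.n_minus_k
        expected = (
            0.5 * n_minus_k * np.log(2.0)
            + (priors.tau_shape - 1.0) * np.log(2.0)
            - priors.tau_rate * 1.0
        )
        got = fw.log_posterior(panel, spec, p2, priors, graph, labels, la) - fw.log_posterior(
            panel, spec, p1, priors, graph, labels, la
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_invalid_parameters_give_minus_inf(self, setup):
        panel, labels, graph, la = setup
        spec = fw.ModelSpec(frozenset({"W"}))
        bad = fw.Parameters(alpha=np.zeros(7), theta=-1.0)
        assert fw.log_posterior(panel, spec, bad, fw.PriorSpec(), graph, labels, la) == -np.inf
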