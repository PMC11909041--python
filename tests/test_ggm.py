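"""Network estimation: partial correlations, EBIC, glasso selection, walktrap."""

import numpy as np
import pytest

from netload import factor_sim, ggm
from netload.ggm import (
    EstimationError,
    Network,
    as_membership,
    detect_communities,
    ebic_score,
    ebicglasso,
    estimate_network,
    precision_to_partial,
)


def equicorrelation(p: int, r: float) -> np.ndarray:
    out = np.full((p, p), r)
    np.fill_diagonal(out, 1.0)
    return out


class TestPrecisionToPartial:
    def test_identity_precision_has_no_edges(self):
        assert np.all(precision_to_partial(np.eye(4)) == 0.0)

    def test_two_variables_partial_equals_marginal(self):
        partial = precision_to_partial(np.linalg.inv(equicorrelation(2, 0.4)))
        assert partial[0, 1] == pytest.approx(0.4)

    @pytest.mark.parametrize("p", range(3, 31))
    def test_equicorrelation_closed_form(self, p):
        # partials of an equicorrelated matrix: r / (1 + (p - 2) r)
        r = 0.5
        partial = precision_to_partial(np.linalg.inv(equicorrelation(p, r)))
        expected = r / (1 + (p - 2) * r)
        off = partial[~np.eye(p, dtype=bool)]
        assert np.allclose(off, expected, atol=1e-10)

    def test_non_spd_input_rejected(self):
        with pytest.raises(ValueError):
            precision_to_partial(np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError):
            precision_to_partial(np.array([[1.0, 0.5], [0.4, 1.0]]))


class TestEbicScore:
    def test_gamma_zero_reduces_to_bic(self, rng):
        s = equicorrelation(5, 0.3)
        theta = np.linalg.inv(s)
        n = 400
        _, logdet = np.linalg.slogdet(theta)
        n_edges = 10  # all upper-triangle entries nonzero
        bic = -n * (logdet - np.trace(s @ theta)) + n_edges * np.log(n)
        assert ebic_score(theta, s, n, gamma=0.0) == pytest.approx(bic)

    def test_diagonal_precision_has_no_penalty(self):
        theta = np.diag([1.0, 2.0, 0.5])
        s = np.eye(3)
        _, logdet = np.linalg.slogdet(theta)
        fit = -100 * (logdet - np.trace(s @ theta))
        assert ebic_score(theta, s, 100, gamma=1.0) == pytest.approx(fit)

    def test_penalty_arithmetic(self):
        # score - fit must equal E log n + 4 gamma E log p
        n, p, gamma = 500, 10, 0.5
        theta = np.eye(p)
        theta[0, 1] = theta[1, 0] = 0.2
        theta[3, 7] = theta[7, 3] = -0.1
        s = np.linalg.inv(theta)
        _, logdet = np.linalg.slogdet(theta)
        fit = -n * (logdet - np.trace(s @ theta))
        expected_penalty = 2 * (np.log(n) + 4 * gamma * np.log(p))
        assert ebic_score(theta, s, n, gamma) - fit == pytest.approx(
            expected_penalty
        )

    def test_non_pd_precision_rejected(self):
        with pytest.raises(ValueError):
            ebic_score(np.diag([1.0, -1.0]), np.eye(2), 100, 0.5)


class TestEbicglasso:
    def test_identity_correlation_gives_empty_network(self):
        network = ebicglasso(np.eye(5), n=200)
        assert np.all(network.weights == 0.0)

    def test_lambda_grid_endpoints(self):
        corr = equicorrelation(4, 0.6)
        grid = ggm._lambda_grid(corr, n_lambda=100, lambda_min_ratio=0.1)
        assert grid[0] == pytest.approx(0.6)
        assert grid[-1] == pytest.approx(0.06)
        assert len(grid) == 100

    def test_block_diagonal_population_stays_block_diagonal(self):
        # two orthogonal factors: no between-block partial correlations
        lam = np.zeros((8, 2))
        lam[:4, 0] = 0.6
        lam[4:, 1] = 0.6
        r_pop, _ = factor_sim.population_correlation(lam, np.eye(2))
        network = ebicglasso(r_pop, n=10_000)
        between = network.weights[:4, 4:]
        assert np.all(between == 0.0)
        within = network.weights[:4, :4][~np.eye(4, dtype=bool)]
        assert np.all(within > 0.0)


class TestEstimateNetwork:
    def test_well_separated_factors_keep_default_gamma(self, rng):
        spec = factor_sim.build_model(2, [4, 4], (0.55, 0.65), 0.0,
                                      "all_positive", 0.0, rng)
        data = factor_sim.generate_sample(spec, 5000, rng).data
        network = estimate_network(data)
        assert network.gamma_used == 0.5
        assert network.disconnected_nodes().size == 0

    def test_pure_noise_variable_triggers_gamma_fallback(self, rng):
        spec = factor_sim.build_model(2, [4, 4], (0.55, 0.65), 0.0,
                                      "all_positive", 0.0, rng)
        data = factor_sim.generate_sample(spec, 500, rng).data
        noisy = np.column_stack([data, rng.standard_normal(500)])
        network = estimate_network(noisy)
        assert network.gamma_used in (0.25, 0.0)

    def test_constant_column_is_named(self):
        data = np.random.default_rng(0).standard_normal((50, 4))
        data[:, 2] = 1.0
        with pytest.raises(ValueError, match="V03"):
            estimate_network(data)

    def test_sign_flip_equivariance_is_exact(self, rng):
        spec = factor_sim.build_model(2, [3, 3], (0.5, 0.7), 0.0,
                                      "all_positive", 0.3, rng)
        data = factor_sim.generate_sample(spec, 400, rng).data
        flipped = data.copy()
        flipped[:, 2] *= -1.0
        w_base = estimate_network(data).weights
        w_flip = estimate_network(flipped).weights
        conj = np.ones(6)
        conj[2] = -1.0
        assert np.array_equal(w_flip, w_base * np.outer(conj, conj))

    def test_permutation_equivariance(self, rng):
        spec = factor_sim.build_model(2, [3, 3], (0.5, 0.7), 0.0,
                                      "all_positive", 0.3, rng)
        data = factor_sim.generate_sample(spec, 400, rng).data
        perm = np.array([3, 0, 5, 1, 4, 2])
        w_base = estimate_network(data).weights
        w_perm = estimate_network(data[:, perm]).weights
        # equal up to solver tolerance: coordinate descent visits columns
        # in order, so permuted runs differ in the last decimals only
        assert np.allclose(w_perm, w_base[np.ix_(perm, perm)], atol=1e-4)
        assert np.array_equal(w_perm != 0, w_base[np.ix_(perm, perm)] != 0)


class TestCommunities:
    def test_two_disconnected_blocks(self, two_block_weights):
        w = two_block_weights.copy()
        w[2, 3] = w[3, 2] = 0.0
        network = Network(w, [f"V{i}" for i in range(6)], 0.5, 0.1)
        membership = detect_communities(network)
        assert len(np.unique(membership)) == 2
        assert len(set(membership[:3])) == 1 and len(set(membership[3:])) == 1

    def test_single_block_is_one_community(self):
        w = np.full((4, 4), 0.3)
        np.fill_diagonal(w, 0.0)
        network = Network(w, list("abcd"), 0.5, 0.1)
        assert len(np.unique(detect_communities(network))) == 1

    def test_empty_network_needs_manual_membership(self):
        network = Network(np.zeros((4, 4)), list("abcd"), 0.5, 0.0)
        with pytest.raises(EstimationError):
            detect_communities(network)

    def test_walktrap_recovers_simulated_factors(self, table1_run):
        membership = detect_communities(table1_run["network"])
        expected = as_membership(table1_run["membership"])
        assert len(np.unique(membership)) == 2
        # same partition up to label names
        for community in (1, 2):
            assert len(set(membership[expected == community])) == 1


def test_membership_canonicalization():
    assert list(as_membership(["b", "a", "b"])) == [2, 1, 2]
    assert list(as_membership([5, 2, 5, 9])) == [2, 1, 2, 3]
    with pytest.raises(ValueError):
        as_membership([1, 2], n_nodes=3)
    with pytest.raises(ValueError):
        as_membership([])


def test_network_and_membership_roundtrip(tmp_path, two_block_weights):
    network = Network(two_block_weights, [f"N{i}" for i in range(6)], 0.25, 0.12)
    path = tmp_path / "network.csv"
    ggm.write_network(path, network)
    loaded = ggm.read_network(path)
    assert np.allclose(loaded.weights, network.weights)
    assert loaded.node_names == network.node_names

    mpath = tmp_path / "membership.csv"
    ggm.write_membership(mpath, [1, 1, 1, 2, 2, 2], network.node_names)
    assert list(ggm.read_membership(mpath)) == [1, 1, 1, 2, 2, 2]
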