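"""Factor-model simulator: loading draws, population matrix, sampling."""

import numpy as np
import pytest

from netload import factor_sim
from netload.factor_sim import (
    ModelValidityError,
    build_model,
    constant_phi,
    generate_loading_matrix,
    generate_sample,
    population_correlation,
    sample_data,
)


class TestGenerateLoadingMatrix:
    def test_half_negative_three_per_factor_flips_exactly_one(self, rng):
        lam = generate_loading_matrix(
            2, [3, 3], (0.40, 0.70), 0.0, "half_negative", rng
        )
        for f, block in ((0, lam[:3, 0]), (1, lam[3:, 1])):
            assert np.sum(block < 0) == 1

    @pytest.mark.parametrize("size,expected_negatives", [(4, 2), (6, 3), (12, 6)])
    def test_half_negative_flips_floor_half(self, rng, size, expected_negatives):
        lam = generate_loading_matrix(
            1, [size], (0.40, 0.70), 0.0, "half_negative", rng
        )
        assert np.sum(lam[:, 0] < 0) == expected_negatives

    def test_zero_cross_sd_gives_exactly_zero_off_blocks(self, rng):
        lam = generate_loading_matrix(3, [4, 4, 4], (0.4, 0.7), 0.0,
                                      "all_positive", rng)
        membership = np.repeat([0, 1, 2], 4)
        for i in range(12):
            off = np.delete(lam[i], membership[i])
            assert np.all(off == 0.0)

    def test_dominant_draws_stay_inside_range(self, rng):
        # 10,000 dominant draws across repeated calls
        lo, hi = 0.30, 0.80
        draws = []
        for _ in range(100):
            lam = generate_loading_matrix(1, [100], (lo, hi), 0.05,
                                          "all_positive", rng)
            draws.append(lam[:, 0])
        draws = np.concatenate(draws)
        assert draws.min() > lo and draws.max() < hi

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dominant_range": (0.0, 0.7)},
            {"dominant_range": (0.7, 0.4)},
            {"variables_per_factor": [3, 0]},
            {"cross_sd": -0.1},
            {"sign_pattern": "sometimes_negative"},
        ],
    )
    def test_invalid_arguments_raise(self, rng, kwargs):
        base = dict(
            n_factors=2, variables_per_factor=[3, 3],
            dominant_range=(0.4, 0.7), cross_sd=0.0,
            sign_pattern="all_positive", rng=rng,
        )
        with pytest.raises(ValueError):
            generate_loading_matrix(**(base | kwargs))


class TestPopulationCorrelation:
    def test_single_factor_two_indicators(self):
        lam = np.array([[0.6], [0.6]])
        r_pop, uniqueness = population_correlation(lam, np.eye(1))
        assert r_pop[0, 1] == pytest.approx(0.36)
        assert np.all(np.diag(r_pop) == 1.0)
        assert uniqueness == pytest.approx([0.64, 0.64])

    def test_excess_communality_is_retriable(self):
        lam = np.array([[0.96], [0.5]])
        with pytest.raises(ModelValidityError):
            population_correlation(lam, np.eye(1))

    def test_correlated_single_indicator_factors(self):
        lam = np.array([[0.5, 0.0], [0.0, 0.5]])
        r_pop, _ = population_correlation(lam, constant_phi(2, 0.3))
        assert r_pop[0, 1] == pytest.approx(0.075)

    def test_dimension_mismatch_is_hard_error(self):
        with pytest.raises(ValueError):
            population_correlation(np.ones((4, 2)) * 0.5, np.eye(3))

    def test_uniqueness_complements_communality_exactly(self, rng):
        spec = build_model(3, [3, 5, 4], (0.40, 0.70), 0.05,
                           "all_positive", 0.3, rng)
        common = (
            spec.loading_matrix @ spec.factor_correlations
            @ spec.loading_matrix.T
        )
        assert np.all(spec.uniqueness + np.diag(common) == 1.0)


class TestSampleData:
    def test_same_seed_is_bitwise_identical(self):
        r_pop, _ = population_correlation(
            np.full((4, 1), 0.6), np.eye(1)
        )
        x1 = sample_data(r_pop, 100, rng=123)
        x2 = sample_data(r_pop, 100, rng=123)
        assert np.array_equal(x1, x2)

    def test_identity_population_gives_near_zero_correlations(self):
        x = sample_data(np.eye(5), 50_000, rng=5)
        corr = np.corrcoef(x, rowvar=False) - np.eye(5)
        assert np.max(np.abs(corr)) < 0.03

    def test_sample_correlation_converges_to_population(self):
        r_pop, _ = population_correlation(np.array([[0.6], [0.6]]), np.eye(1))
        x = sample_data(r_pop, 100_000, rng=6)
        assert np.corrcoef(x, rowvar=False)[0, 1] == pytest.approx(0.36, abs=0.01)
        # standardization of the generated columns
        assert np.allclose(x.mean(axis=0), 0.0, atol=0.02)
        assert np.allclose(x.std(axis=0, ddof=1), 1.0, atol=0.02)

    def test_non_positive_definite_input_fails(self):
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(np.linalg.LinAlgError):
            sample_data(bad, 10, rng=0)


class TestGenerateSample:
    def test_cholesky_reconstructs_population(self, rng):
        spec = build_model(2, [4, 4], (0.45, 0.65), 0.0, "all_positive",
                           0.3, rng)
        sample = generate_sample(spec, 50, rng)
        upper = sample.cholesky_factor
        assert np.allclose(upper, np.triu(upper))
        recon = upper.T @ upper
        assert np.linalg.norm(recon - sample.population_correlation) < 1e-10

    def test_membership_and_assigned_loadings(self, rng):
        spec = build_model(2, [3, 5], (0.45, 0.65), 0.0, "all_positive",
                           0.0, rng)
        assert list(spec.membership) == [1] * 3 + [2] * 5
        assert spec.assigned_loadings[0] == spec.loading_matrix[0, 0]
        assert spec.assigned_loadings[-1] == spec.loading_matrix[-1, 1]


def test_condition_and_sample_roundtrip(tmp_path, rng):
    path = tmp_path / "condition.yaml"
    factor_sim.save_condition(
        path, factors=2, variables_per_factor=[3, 3],
        loading_range=(0.45, 0.65), cross_sd=0.05, phi=0.3,
        sign_pattern="all_positive", n=500, seed=42,
    )
    loaded = factor_sim.load_condition(path)
    assert loaded["factors"] == 2 and loaded["loading_range"] == [0.45, 0.65]

    data = rng.standard_normal((20, 3))
    csv = tmp_path / "sample.csv"
    factor_sim.write_sample(csv, data)
    frame = factor_sim.read_sample(csv)
    assert list(frame.columns) == ["V01", "V02", "V03"]
    assert np.allclose(frame.to_numpy(), data)
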