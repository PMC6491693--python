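"""Scaling constants, rescaling, and the criterion-number sensitivity grids."""

import numpy as np
import pandas as pd
import pytest

from latentscale import (
    CFAModel,
    ErrorCovariance,
    FactorLoadings,
    LatentCovariance,
    MarkerError,
    ScalingPlan,
    build_plan,
    constancy_distance,
    criterion_sensitivity_table,
    effect_coding_constant,
    marker_constant,
    reference_constant,
    rescale,
    scaled_variance,
    sum_squares_constant,
)
from conftest import random_positive_model


class TestScalingConstants:
    @pytest.mark.parametrize(
        "column, index, expected",
        [((0.5, 0.8, 0.4), 0, 2.0), ((1.0, 0.7), 0, 1.0), ((0.4, 0.5), 1, 2.0)],
    )
    def test_marker(self, column, index, expected):
        assert marker_constant(column, index) == pytest.approx(expected)

    def test_marker_rejects_nonpositive_loading(self):
        with pytest.raises(MarkerError):
            marker_constant((-0.3, 0.6), 0)
        with pytest.raises(MarkerError):
            marker_constant((0.0, 0.6), 0)

    @pytest.mark.parametrize(
        "phi, target, expected",
        [(1.0, 1.0, 1.0), (4.0, 1.0, 2.0), (0.25, 1.0, 0.5), (2.0, 0.5, 2.0)],
    )
    def test_reference_group(self, phi, target, expected):
        assert reference_constant(phi, target) == pytest.approx(expected)

    @pytest.mark.parametrize("phi, target", [(-1.0, 1.0), (0.0, 1.0), (1.0, 0.0)])
    def test_reference_group_domain(self, phi, target):
        with pytest.raises(ValueError):
            reference_constant(phi, target)

    @pytest.mark.parametrize(
        "column, p_c, expected",
        [
            ((1.0, 1.0, 1.0, 1.0), 4.0, 1.0),
            ((0.5, 1.0, 1.5), 3.0, 1.0),
            ((0.2, 0.2, 0.2, 0.2), 4.0, 5.0),
        ],
    )
    def test_effect_coding(self, column, p_c, expected):
        assert effect_coding_constant(column, p_c) == pytest.approx(expected)

    def test_effect_coding_degenerate_sum(self):
        with pytest.raises(ValueError, match="not strictly positive"):
            effect_coding_constant((0.5, -0.5), 2.0)

    @pytest.mark.parametrize(
        "column, p_c, expected",
        [
            ((0.2, 0.2, 0.2, 0.2), 4.0, 5.0),
            ((0.5, 0.5), 0.5, 1.0),  # lambda'lambda already equals p_c
        ],
    )
    def test_sum_squares(self, column, p_c, expected):
        assert sum_squares_constant(column, p_c) == pytest.approx(expected)

    def test_sum_squares_all_zero_column(self):
        with pytest.raises(ValueError, match="zero"):
            sum_squares_constant((0.0, 0.0), 1.0)

    @pytest.mark.parametrize(
        "phi, c, expected", [(1.0, 5.0, 0.04), (3.7, 1.0, 3.7), (2.0, 2.0, 0.5)]
    )
    def test_scaled_variance(self, phi, c, expected):
        assert scaled_variance(phi, c) == pytest.approx(expected)

    def test_scaled_variance_requires_positive_constant(self):
        with pytest.raises(ValueError):
            scaled_variance(1.0, 0.0)

    def test_twelve_point_six_loadings_give_432_hundredths(self):
        # equal loadings of 0.6 on twelve indicators, criterion number 1
        column = np.full(12, 0.6)
        c = sum_squares_constant(column, 1.0)
        assert scaled_variance(1.0, c) == pytest.approx(4.32)


def one_factor_model(lam, phi=1.0):
    lam = np.asarray(lam, float)
    return CFAModel(
        loadings=FactorLoadings(lam[:, None]),
        latent_cov=LatentCovariance([[phi]]),
        error_cov=ErrorCovariance(np.full(lam.size, 0.3)),
    )


class TestBuildPlanAndRescale:
    def test_plan_delegates_per_factor(self):
        model = one_factor_model([0.5, 0.8])
        plan = build_plan(model, "sum_squares", [1.0])
        assert plan.constants[0] == pytest.approx(np.sqrt(1.0 / 0.89))

    def test_marker_plan_two_factors(self, rng):
        model = random_positive_model(rng, p=4, q=2)
        plan = build_plan(model, "marker", [0, 2])
        lam = model.loadings.values
        np.testing.assert_allclose(
            plan.constants, [1.0 / lam[0, 0], 1.0 / lam[2, 1]]
        )

    def test_error_names_offending_factor(self):
        model = CFAModel(
            loadings=FactorLoadings(np.array([[0.0, 0.5], [0.5, 0.5]])),
            latent_cov=LatentCovariance(np.eye(2)),
            error_cov=ErrorCovariance([0.3, 0.3]),
        )
        with pytest.raises(MarkerError, match="F1"):
            build_plan(model, "marker", [0, 0])

    def test_wrong_parameter_count(self, rng):
        model = random_positive_model(rng, p=4, q=2)
        with pytest.raises(ValueError):
            build_plan(model, "marker", [0])

    def test_identity_plan_is_noop(self, rng):
        model = random_positive_model(rng, p=5, q=2)
        plan = ScalingPlan(method="marker", constants=np.ones(2))
        solution = rescale(model, plan)
        np.testing.assert_array_equal(solution.loadings_star.values, model.loadings.values)
        np.testing.assert_array_equal(
            solution.latent_cov_star.values, model.latent_cov.values
        )

    def test_one_factor_marker_example(self):
        model = one_factor_model([0.5, 0.8])
        solution = rescale(model, build_plan(model, "marker", [0]))
        np.testing.assert_allclose(
            solution.loadings_star.values.ravel(), [1.0, 1.6], atol=1e-12
        )
        assert solution.latent_cov_star.values[0, 0] == pytest.approx(0.25)

    def test_correlated_factors_covariance_divided_by_both_constants(self):
        lam = np.array([[0.5, 0.0], [0.6, 0.0], [0.0, 0.7], [0.0, 0.8]])
        phi = np.array([[1.0, 0.4], [0.4, 1.0]])
        model = CFAModel(
            loadings=FactorLoadings(lam),
            latent_cov=LatentCovariance(phi),
            error_cov=ErrorCovariance(np.full(4, 0.3)),
        )
        plan = ScalingPlan(method="marker", constants=np.array([2.0, 4.0]))
        solution = rescale(model, plan)
        assert solution.latent_cov_star.values[0, 1] == pytest.approx(0.05)
        # true part preserved entrywise, by explicit multiplication
        star = (
            solution.loadings_star.values
            @ solution.latent_cov_star.values
            @ solution.loadings_star.values.T
        )
        np.testing.assert_allclose(star, lam @ phi @ lam.T, atol=1e-12)

    def test_theta_untouched(self, rng):
        model = random_positive_model(rng, p=4, q=1)
        solution = rescale(model, build_plan(model, "sum_squares", [2.0]))
        assert solution.as_model().error_cov is model.error_cov

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(ValueError):
            ScalingPlan(method="marker", constants=[1.0, -2.0])


METHOD_PARAMS = [
    ("marker", lambda rng, p: int(rng.integers(0, p))),
    ("reference_group", lambda rng, p: float(rng.uniform(0.5, 2.0))),
    ("effect_coding", lambda rng, p: float(rng.uniform(0.5, 2 * p))),
    ("sum_squares", lambda rng, p: float(rng.uniform(0.5, 2 * p))),
]


class TestConstancyAndPostconditions:
    def test_500_random_plans_preserve_true_part(self, rng):
        """Constancy plus each method's defining post-condition, 500 triples."""
        for trial in range(500):
            method, draw = METHOD_PARAMS[trial % 4]
            model = random_positive_model(rng, correlated=bool(trial % 2))
            params = [draw(rng, model.p) for _ in range(model.q)]
            plan = build_plan(model, method, params)
            solution = rescale(model, plan)
            assert constancy_distance(model, solution) < 1e-10
            lam_star = solution.loadings_star.values
            phi_star = solution.latent_cov_star.values
            for k, param in enumerate(params):
                if method == "marker":
                    assert lam_star[param, k] == pytest.approx(1.0, abs=1e-12)
                elif method == "reference_group":
                    assert phi_star[k, k] == pytest.approx(param, abs=1e-12)
                elif method == "effect_coding":
                    assert lam_star[:, k].sum() == pytest.approx(param, abs=1e-12)
                else:
                    assert lam_star[:, k] @ lam_star[:, k] == pytest.approx(
                        param, abs=1e-12
                    )

    def test_round_trip_restores_original(self, rng):
        for _ in range(20):
            model = random_positive_model(rng, correlated=True)
            plan = build_plan(
                model, "sum_squares", [float(rng.uniform(0.5, 5.0))] * model.q
            )
            back = rescale(rescale(model, plan).as_model(), plan.inverse())
            np.testing.assert_allclose(
                back.loadings_star.values, model.loadings.values, atol=1e-12
            )
            np.testing.assert_allclose(
                back.latent_cov_star.values, model.latent_cov.values, atol=1e-12
            )


class TestCriterionNumberEffects:
    def test_larger_criterion_smaller_scaled_variance(self, rng):
        """phi_sc decreases strictly as p_c grows, over a grid of 20 criteria."""
        column = rng.uniform(0.2, 0.9, size=6)
        phi = 1.3
        p_cs = np.linspace(0.5, 10.0, 20)
        values = [
            scaled_variance(phi, sum_squares_constant(column, pc)) for pc in p_cs
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_proportional_criterion_independent_of_p(self):
        """With p_c = r*p and equal loadings, phi_sc does not depend on p."""
        for r in (1.0, 0.5, 0.25):
            for lam in (0.2, 0.4, 0.6):
                values = {
                    round(
                        scaled_variance(
                            1.0, sum_squares_constant(np.full(p, lam), r * p)
                        ),
                        12,
                    )
                    for p in (4, 8, 12)
                }
                assert len(values) == 1


# printed reference grids: proportions x p in rows, loadings in columns
TABLE_PROPORTIONS = np.array(
    [
        [0.04, 0.16, 0.36],
        [0.04, 0.16, 0.36],
        [0.04, 0.16, 0.36],
        [0.08, 0.32, 0.72],
        [0.08, 0.32, 0.72],
        [0.08, 0.32, 0.72],
        [0.16, 0.64, 1.44],
        [0.16, 0.64, 1.44],
        [0.16, 0.64, 1.44],
    ]
)
TABLE_ABSOLUTE = np.array(
    [
        [0.160, 0.640, 1.440],
        [0.320, 1.280, 2.880],
        [0.480, 1.920, 4.320],
        [0.032, 0.128, 0.288],
        [0.064, 0.256, 0.576],
        [0.096, 0.384, 0.864],
        [0.016, 0.064, 0.144],
        [0.032, 0.128, 0.288],
        [0.048, 0.192, 0.432],
    ]
)


class TestSensitivityTable:
    def test_proportional_grid(self):
        grid = criterion_sensitivity_table(
            [0.2, 0.4, 0.6], [4, 8, 12], ["1/1", "1/2", "1/4"]
        )
        assert grid.shape == (9, 3)
        np.testing.assert_allclose(grid.to_numpy(), TABLE_PROPORTIONS, atol=5e-13)

    def test_absolute_grid(self):
        grid = criterion_sensitivity_table([0.2, 0.4, 0.6], [4, 8, 12], [1, 5, 10])
        np.testing.assert_allclose(grid.to_numpy(), TABLE_ABSOLUTE, atol=5e-13)

    def test_zero_loading_cell_is_zero(self):
        grid = criterion_sensitivity_table([0.0, 0.4], [4], [2.0])
        assert grid.iloc[0, 0] == 0.0
        assert grid.iloc[0, 1] > 0.0

    def test_nonpositive_criterion_rejected(self):
        with pytest.raises(ValueError):
            criterion_sensitivity_table([0.4], [4], [-1.0])

    def test_index_structure(self):
        grid = criterion_sensitivity_table([0.4], [4, 8], ["1/2"])
        assert isinstance(grid.index, pd.MultiIndex)
        assert list(grid.index) == [("1/2", 4), ("1/2", 8)]
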