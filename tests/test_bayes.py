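"""MAP and discrete-prior estimation against enumeration oracles."""

import math

import numpy as np
import pytest

from busudose import (
    IndividualParameters,
    NonparametricModelSpec,
    NpPrior,
    Observation,
    ParametricModelSpec,
    PatientCovariates,
    individual_auc_and_dose,
    map_fit,
    np_posterior,
    paci_typical_params,
    predict_concentration,
    residual_sd,
)
from busudose.bayes import map_objective
from busudose.models import bsv_omega, neely_params


class TestResidualSd:
    def test_nonparametric_linear_rule(self, np_spec):
        assert residual_sd(np_spec, 1.0) == pytest.approx(0.12)
        assert residual_sd(np_spec, 0.0) == pytest.approx(0.02)

    def test_parametric_combined_rule(self, par_spec):
        assert residual_sd(par_spec, 0.0) == pytest.approx(0.057)  # additive floor
        assert residual_sd(par_spec, 1.0) == pytest.approx(
            math.sqrt(0.0121 + 0.057**2)
        )
        assert residual_sd(par_spec, 1.0) == pytest.approx(0.1239, abs=5e-4)

    def test_negative_concentration_rejected(self, par_spec):
        with pytest.raises(ValueError):
            residual_sd(par_spec, -0.1)


class TestMapFit:
    def test_no_observations_returns_prior_mode(self, par_spec, median_child,
                                                full_course):
        fit = map_fit(par_spec, median_child, full_course, [])
        assert fit.eta.tolist() == [0.0, 0.0]
        typical = paci_typical_params(median_child, par_spec)
        assert fit.params.clearance == typical.clearance
        assert fit.converged

    def test_data_at_typical_prediction_barely_moves_eta(
        self, par_spec, median_child, full_course
    ):
        typical = paci_typical_params(median_child, par_spec)
        times = np.array([2.5, 4.0])
        obs = [
            Observation(float(t), float(c))
            for t, c in zip(
                times, predict_concentration(typical, full_course, times)
            )
        ]
        fit = map_fit(par_spec, median_child, full_course, obs)
        # prior holds eta near 0; only the ln sigma^2 bookkeeping term can
        # nudge it away from the data-perfect point
        assert np.all(np.abs(fit.eta) < 0.02)

    def test_solution_never_worse_than_prior_mode(self, par_spec, median_child,
                                                  full_course):
        obs = [Observation(2.5, 1.4), Observation(4.0, 0.9)]
        fit = map_fit(par_spec, median_child, full_course, obs)
        times = np.array([o.time for o in obs])
        conc = np.array([o.concentration for o in obs])
        typical = paci_typical_params(median_child, par_spec)
        at_zero = map_objective(
            np.zeros(2), par_spec, typical, full_course, times, conc
        )
        assert fit.objective <= at_zero + 1e-12

    def test_matches_brute_force_grid(self, par_spec, median_child, single_dose):
        """Optimizer solution within one 0.005 grid step of exhaustive search."""
        obs = [Observation(2.5, 1.25), Observation(4.0, 0.70)]
        fit = map_fit(par_spec, median_child, single_dose, obs)
        times = np.array([o.time for o in obs])
        conc = np.array([o.concentration for o in obs])
        typical = paci_typical_params(median_child, par_spec)

        grid = np.arange(-1.5, 1.5 + 1e-12, 0.005)
        e1, e2 = np.meshgrid(grid, grid, indexing="ij")
        cl = typical.clearance * np.exp(e1)
        v = typical.volume * np.exp(e2)
        k = cl / v
        event = single_dose.events[0]
        obj = (e1 / bsv_omega(par_spec.cl_cv)) ** 2 + (
            e2 / bsv_omega(par_spec.v_cv)
        ) ** 2
        for t, c in zip(times, conc):
            infused = min(max(t - event.start, 0.0), event.duration)
            decayed = max(t - event.start - event.duration, 0.0)
            pred = (
                event.rate / cl * (1 - np.exp(-k * infused)) * np.exp(-k * decayed)
            )
            s2 = (par_spec.residual_proportional * pred) ** 2 \
                + par_spec.residual_additive**2
            obj += (c - pred) ** 2 / s2 + np.log(s2)
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        assert abs(fit.eta[0] - grid[i]) <= 0.005 + 1e-12
        assert abs(fit.eta[1] - grid[j]) <= 0.005 + 1e-12

    def test_shrinkage_to_prior_with_uninformative_data(self, median_child,
                                                        full_course):
        # a huge *additive* SD: the likelihood flattens and the ln sigma^2
        # term becomes constant, so the prior mode must win
        inflated = ParametricModelSpec(residual_additive=500.0)
        obs = [Observation(2.5, 2.0), Observation(4.0, 1.5)]
        fit = map_fit(inflated, median_child, full_course, obs)
        assert np.all(np.abs(fit.eta) < 1e-3)

    def test_curve_through_points_in_small_noise_limit(self, median_child,
                                                       full_course, par_spec):
        """With residual SD scaled toward 0, MAP pierces the exact data."""
        truth = IndividualParameters(clearance=4.4, volume=9.5)
        times = np.array([2.5, 4.0])
        conc = predict_concentration(truth, full_course, times)
        obs = [Observation(float(t), float(c)) for t, c in zip(times, conc)]
        tight = ParametricModelSpec(
            residual_proportional=par_spec.residual_proportional * 1e-3,
            residual_additive=par_spec.residual_additive * 1e-3,
        )
        fit = map_fit(tight, median_child, full_course, obs)
        assert fit.params.clearance == pytest.approx(truth.clearance, rel=0.01)
        assert fit.params.volume == pytest.approx(truth.volume, rel=0.01)

    def test_all_zero_observations_warn(self, par_spec, median_child, full_course):
        with pytest.warns(UserWarning, match="zero"):
            map_fit(
                par_spec, median_child, full_course,
                [Observation(2.5, 0.0), Observation(4.0, 0.0)],
            )


def five_point_prior() -> NpPrior:
    points = np.array(
        [[0.45, 0.60], [0.55, 0.70], [0.71, 0.72], [0.85, 0.90], [0.95, 1.30]]
    )
    weights = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
    return NpPrior(points=points, weights=weights)


class TestNpPosterior:
    def test_no_observations_returns_prior(self, np_spec, median_child,
                                           full_course):
        prior = five_point_prior()
        post = np_posterior(np_spec, median_child, full_course, [], prior=prior)
        np.testing.assert_allclose(post.weights, prior.weights)
        assert not post.degenerate

    def test_single_support_point_gets_all_mass(self, np_spec, median_child,
                                                full_course):
        prior = NpPrior(points=np.array([[0.71, 0.72]]), weights=np.array([1.0]))
        post = np_posterior(
            np_spec, median_child, full_course,
            [Observation(2.5, 3.0)], prior=prior,
        )
        assert post.weights.tolist() == [1.0]

    def test_matches_hand_rolled_enumeration(self, np_spec, median_child,
                                             full_course):
        """Posterior equals direct prior*likelihood/sum arithmetic to 1e-12."""
        prior = five_point_prior()
        obs = [Observation(2.5, 1.1), Observation(4.0, 0.75)]
        post = np_posterior(np_spec, median_child, full_course, obs, prior=prior)

        expected = []
        for (kes, vs), w in zip(prior.points, prior.weights):
            params = neely_params(kes, vs, median_child, np_spec)
            like = 1.0
            for o in obs:
                pred = float(
                    predict_concentration(params, full_course, [o.time])[0]
                )
                sd = 0.02 + 0.1 * o.concentration
                like *= math.exp(
                    -0.5 * ((o.concentration - pred) / sd) ** 2
                ) / (sd * math.sqrt(2 * math.pi))
            expected.append(w * like)
        expected = np.array(expected) / sum(expected)
        np.testing.assert_allclose(post.weights, expected, atol=1e-12)

    def test_weights_always_normalized(self, np_spec, median_child, full_course):
        post = np_posterior(
            np_spec, median_child, full_course,
            [Observation(2.5, 1.3), Observation(4.0, 0.8)],
            prior=five_point_prior(),
        )
        assert post.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(post.weights >= 0)

    def test_underflow_falls_back_to_uniform_with_flag(self, median_child,
                                                       full_course):
        # an absurd observation makes every support point's likelihood zero
        sharp = NonparametricModelSpec(
            residual_intercept=1e-12, residual_slope=1e-12
        )
        with pytest.warns(UserWarning, match="underflow"):
            post = np_posterior(
                sharp, median_child, full_course,
                [Observation(2.5, 500.0)], prior=five_point_prior(),
            )
        assert post.degenerate
        np.testing.assert_allclose(post.weights, 0.2)

    def test_posterior_mean_in_support_hull(self, np_spec, median_child,
                                            full_course):
        post = np_posterior(
            np_spec, median_child, full_course,
            [Observation(2.5, 1.0)], prior=five_point_prior(),
        )
        mean = post.mean_point
        pts = post.prior.points
        assert pts[:, 0].min() <= mean[0] <= pts[:, 0].max()
        assert pts[:, 1].min() <= mean[1] <= pts[:, 1].max()


class TestExposureSummaries:
    def test_map_cumulative_auc_identity(self, par_spec, full_course):
        cov = PatientCovariates(body_weight=9.0)  # typical CL exactly 2.18
        fit = map_fit(par_spec, cov, full_course, [])
        summary = individual_auc_and_dose(fit, full_course)
        assert summary.auc_cum == pytest.approx(16 * 10.9 / 2.18)
        assert summary.auc_cum == pytest.approx(80.0)

    def test_single_support_posterior_reduces_to_point_evaluation(
        self, np_spec, median_child, full_course
    ):
        prior = NpPrior(points=np.array([[0.71, 0.72]]), weights=np.array([1.0]))
        post = np_posterior(
            np_spec, median_child, full_course,
            [Observation(2.5, 1.0)], prior=prior,
        )
        summary = individual_auc_and_dose(post, full_course)
        params = neely_params(0.71, 0.72, median_child, np_spec)
        assert summary.auc_cum == pytest.approx(
            full_course.total_dose / params.clearance
        )
        assert summary.clearance == pytest.approx(params.clearance)

    def test_posterior_mean_auc_is_convex_combination(self, np_spec, median_child,
                                                      full_course):
        post = np_posterior(
            np_spec, median_child, full_course,
            [Observation(2.5, 1.2), Observation(4.0, 0.8)],
            prior=five_point_prior(),
        )
        summary = individual_auc_and_dose(post, full_course)
        per_support = [
            full_course.total_dose / p.clearance for p in post.support_params
        ]
        assert min(per_support) <= summary.auc_cum <= max(per_support)
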