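"""Cohort generator: marginals, copula associations, smoking chain,
variance-component calibration and the mixed-model outcome draw."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from attrisim.cohort_generator import (
    CalibrationError,
    calibrate_copula,
    calibrate_generative_params,
    default_generative_params,
    draw_baseline_covariates,
    draw_smoking_trajectories,
    fixed_effect_moments,
    generate_cohort,
    lmm_covariance,
    ordinal_code_corr,
    _skeleton_params,
)
from attrisim.params import (
    ANALYSIS_PHASES,
    CODE_CORR_TARGETS,
    GLOBAL_TARGETS,
    MEMORY_TARGETS,
    PHASES,
    PHASE_TIME,
)


def binom_3se(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


class TestBaselineCovariates:
    def test_marginals_match_census(self, global_cohort):
        base = global_cohort[global_cohort["phase"] == 5]
        n = len(base)
        checks = [
            ((base["age_cat"] == 1).mean(), 0.2420),
            ((base["grade"] == 1).mean(), 0.5812),
            ((base["education"] == 3).mean(), 0.4770),
        ]
        for observed, expected in checks:
            assert abs(observed - expected) < binom_3se(expected, n)

    def test_degenerate_marginal_is_constant(self, global_params):
        p = replace(
            global_params,
            covariate_marginals={
                **global_params.covariate_marginals,
                "grade": np.array([1.0, 0.0, 0.0]),
            },
        )
        cov = draw_baseline_covariates(2_000, p, 3)
        assert (cov["grade"] == 1).all()

    def test_identity_copula_independence(self, global_params):
        """Cramer's V between grade and education under an identity copula
        matches an independent-draw oracle (both ~0)."""
        n = 50_000
        p = replace(global_params, copula_corr=np.eye(4))
        cov = draw_baseline_covariates(n, p, 11)

        def cramers_v(a, b):
            tab = pd.crosstab(a, b).to_numpy()
            exp = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
            chi2 = ((tab - exp) ** 2 / exp).sum()
            return np.sqrt(chi2 / (tab.sum() * (min(tab.shape) - 1)))

        rng = np.random.default_rng(12)
        oracle_g = rng.choice([1, 2, 3], size=n, p=p.covariate_marginals["grade"])
        oracle_e = rng.choice([1, 2, 3], size=n, p=p.covariate_marginals["education"])
        v_model = cramers_v(cov["grade"], cov["education"])
        v_oracle = cramers_v(oracle_g, oracle_e)
        assert v_model < 0.02 and v_oracle < 0.02
        assert abs(v_model - v_oracle) < 0.015

    def test_copula_reproduces_code_correlations(self, global_cohort):
        base = global_cohort[global_cohort["phase"] == 5]
        for (a, b), target in CODE_CORR_TARGETS.items():
            if "smoking" in (a, b):
                continue  # checked at phase 5 via the trajectory draw below
            r = np.corrcoef(base[a], base[b])[0, 1]
            assert abs(r - target) < 0.02, (a, b)

    def test_non_psd_copula_raises(self, global_params):
        bad = np.array(
            [[1, 0.9, -0.9, 0], [0.9, 1, 0.9, 0], [-0.9, 0.9, 1, 0], [0, 0, 0, 1.0]]
        )
        p = replace(global_params, copula_corr=bad)
        with pytest.raises(ValueError, match="positive"):
            draw_baseline_covariates(100, p, 0)

    def test_latent_calibration_roundtrip(self):
        latent = calibrate_copula()
        from attrisim.params import DEFAULT_MARGINALS, GenerativeParams

        order = GenerativeParams.COPULA_ORDER
        for (a, b), target in CODE_CORR_TARGETS.items():
            rho = latent[order.index(a), order.index(b)]
            implied = ordinal_code_corr(rho, DEFAULT_MARGINALS[a], DEFAULT_MARGINALS[b])
            assert abs(implied - target) < 1e-4


class TestSmokingTrajectories:
    def test_current_smoker_decline_matches_census(self, global_cohort):
        n = global_cohort["participant_id"].nunique()
        frac = global_cohort.groupby("phase")["smoking"].apply(lambda s: (s == 3).mean())
        for phase, expected in ((5, 0.072), (7, 0.062), (9, 0.050)):
            assert abs(frac[phase] - expected) < binom_3se(expected, n)

    def test_never_smokers_fixed(self, global_cohort):
        wide = global_cohort.pivot(index="participant_id", columns="phase", values="smoking")
        never_any = (wide == 1).any(axis=1)
        never_all = (wide == 1).all(axis=1)
        assert (never_any == never_all).all()

    def test_quit_probability_zero_is_constant(self, global_params):
        p = replace(global_params, smoking_transition=np.zeros(4))
        cov = draw_baseline_covariates(1_000, p, 5)
        smk = draw_smoking_trajectories(cov, p, 6)
        arr = smk[[f"smoking_{t}" for t in PHASES]].to_numpy()
        assert (arr == arr[:, [0]]).all()

    def test_quit_probability_one_exhausts_current(self, global_params):
        """With quit probability 1 no current smokers remain after one
        interval; verified against exhaustive transition enumeration."""
        p = replace(global_params, smoking_transition=np.ones(4))
        cov = draw_baseline_covariates(1_000, p, 7)
        smk = draw_smoking_trajectories(cov, p, 8)
        arr = smk[[f"smoking_{t}" for t in PHASES]].to_numpy()
        assert not (arr[:, 1:] == 3).any()
        # enumeration: the only legal transitions are s->s and 3->2
        for j in range(arr.shape[1] - 1):
            pairs = set(map(tuple, np.unique(arr[:, j : j + 2], axis=0)))
            assert pairs <= {(1, 1), (2, 2), (3, 3), (3, 2)}

    def test_invalid_quit_probability_raises(self, global_params):
        cov = draw_baseline_covariates(10, global_params, 0)
        p = replace(global_params, smoking_transition=np.array([0.1, 1.2, 0.1, 0.1]))
        with pytest.raises(ValueError, match="quit"):
            draw_smoking_trajectories(cov, p, 0)


class TestVarianceCalibration:
    def test_global_calibration_reproduces_targets(self, global_params):
        times = np.array([PHASE_TIME[p] for p in ANALYSIS_PHASES])
        cov = lmm_covariance(global_params, times)
        sd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(sd, sd)
        assert abs(sd[0] - GLOBAL_TARGETS.phase5_sd) < 1e-4
        for got, want in zip(
            (corr[0, 1], corr[0, 2], corr[1, 2]), GLOBAL_TARGETS.lag_corrs
        ):
            assert abs(got - want) < 1e-4

    def test_memory_calibration_near_targets(self, memory_params):
        times = np.array([PHASE_TIME[p] for p in ANALYSIS_PHASES])
        cov = lmm_covariance(memory_params, times)
        sd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(sd, sd)
        assert abs(sd[0] - MEMORY_TARGETS.phase5_sd) < 1e-3
        for got, want in zip(
            (corr[0, 1], corr[0, 2], corr[1, 2]), MEMORY_TARGETS.lag_corrs
        ):
            assert abs(got - want) < 2e-3

    def test_pure_random_intercept_gives_unit_correlation(self):
        p = replace(_skeleton_params("global"), sigma_b0=0.5)
        times = np.array([PHASE_TIME[q] for q in ANALYSIS_PHASES])
        cov = lmm_covariance(p, times)
        sd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(sd, sd)
        assert np.allclose(corr, 1.0, atol=1e-12)

    def test_memory_calibration_beats_grid_oracle(self, memory_params):
        """The calibrated components attain a squared-residual objective no
        worse than a brute 2-D grid over (sigma_b0, sigma_eps)."""
        times = np.array([PHASE_TIME[p] for p in ANALYSIS_PHASES])
        moments = fixed_effect_moments(memory_params)

        def objective(sb0, se):
            p = replace(memory_params, sigma_b0=sb0, sigma_eps=se)
            cov = lmm_covariance(p, times, moments)
            sd = np.sqrt(np.diag(cov))
            corr = cov / np.outer(sd, sd)
            res = np.array(
                [
                    sd[0] - MEMORY_TARGETS.phase5_sd,
                    corr[0, 1] - MEMORY_TARGETS.lag_corrs[0],
                    corr[0, 2] - MEMORY_TARGETS.lag_corrs[1],
                    corr[1, 2] - MEMORY_TARGETS.lag_corrs[2],
                ]
            )
            return float(res @ res)

        grid = [
            objective(sb0, se)
            for sb0 in np.linspace(0.2, 0.6, 41)
            for se in np.linspace(0.3, 0.8, 41)
        ]
        calibrated = objective(memory_params.sigma_b0, memory_params.sigma_eps)
        assert calibrated <= min(grid) + 1e-8

    def test_infeasible_targets_raise(self, global_params):
        with pytest.raises(CalibrationError):
            calibrate_generative_params(
                {"phase5_sd": -1.0, "lag_corrs": (0.9, 0.9, 0.9)}, global_params
            )


class TestOutcomes:
    def test_phase_means_match_closed_form(self, global_cohort, global_params):
        wide = global_cohort.pivot(index="participant_id", columns="phase", values="outcome")
        n = wide.shape[0]
        m = fixed_effect_moments(global_params)
        for phase in ANALYSIS_PHASES:
            t = PHASE_TIME[phase]
            expected = global_params.beta0 + m["mean_f0"] + m["mean_slope"] * t
            se = wide[phase].std() / np.sqrt(n)
            assert abs(wide[phase].mean() - expected) < 3 * se

    def test_phase5_standardization(self, global_cohort):
        base = global_cohort[global_cohort["phase"] == 5]["outcome"]
        assert abs(base.mean()) < 3 * base.std() / np.sqrt(len(base))

    def test_zero_effects_give_zero_outcome(self):
        panel = generate_cohort(_skeleton_params("global"), 200, 9)
        assert np.allclose(panel["outcome"], 0.0)

    def test_empirical_covariance_matches_closed_form(self, global_cohort, global_params):
        """Entrywise agreement of the empirical outcome covariance with the
        closed-form LMM covariance within 3 Monte-Carlo SEs."""
        wide = global_cohort.pivot(index="participant_id", columns="phase", values="outcome")
        arr = wide[list(PHASES)].to_numpy()
        n = arr.shape[0]
        emp = np.cov(arr, rowvar=False)
        times = np.array([PHASE_TIME[p] for p in PHASES])
        theo = lmm_covariance(global_params, times)
        for i in range(5):
            for j in range(5):
                se = np.sqrt((theo[i, i] * theo[j, j] + theo[i, j] ** 2) / n)
                assert abs(emp[i, j] - theo[i, j]) < 3 * se, (i, j)


class TestGenerateCohort:
    def test_shape_and_determinism(self, global_params):
        a = generate_cohort(global_params, 500, 77)
        b = generate_cohort(global_params, 500, 77)
        assert len(a) == 500 * 5
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cohort(self, global_params):
        panel = generate_cohort(global_params, 0, 0)
        assert len(panel) == 0

    def test_never_smoker_fraction(self, global_cohort):
        wide = global_cohort.pivot(index="participant_id", columns="phase", values="smoking")
        frac = (wide == 1).all(axis=1).mean()
        assert abs(frac - 0.494) < binom_3se(0.494, wide.shape[0])
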