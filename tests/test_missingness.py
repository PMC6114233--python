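"""Missingness engine: status-model calibration, absorbing states,
informative-attrition calibration and value blanking."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import statsmodels.api as sm

from attrisim.cohort_generator import generate_cohort
from attrisim.missingness_engine import (
    apply_missingness,
    assign_participation,
    calibrate_informative_attrition,
    default_missingness_params,
    _base_covariates,
    _ignorable_attrition_structure,
)
from attrisim.params import MissingnessParams


def binom_3se(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


@pytest.fixture(scope="module")
def assigned_ignorable(global_params):
    """Two n=10,000 cohorts with ignorable statuses (averaged in the
    proportion checks to reduce Monte-Carlo noise)."""
    out = []
    for seed in (201, 202):
        panel = generate_cohort(global_params, 10_000, seed)
        params = MissingnessParams()
        out.append((panel, assign_participation(panel, params, seed + 50)))
    return out


def _status_wide(assigned):
    return assigned.pivot(index="participant_id", columns="phase", values="status")


class TestStatusAssignment:
    def test_phase7_proportions(self, assigned_ignorable):
        fracs = []
        for _, assigned in assigned_ignorable:
            sw = _status_wide(assigned)
            fracs.append(
                [
                    (sw[7] == "response").mean(),
                    (sw[7] == "death").mean(),
                    (sw[7] == "non_response").mean(),
                    (sw[7] == "attrition").mean(),
                ]
            )
        mean = np.mean(fracs, axis=0)
        n = 20_000
        for got, want in zip(mean, (0.785, 0.024, 0.149, 0.043)):
            assert abs(got - want) < binom_3se(want, n), (got, want)

    def test_phase5_response_and_phase9_attrition(self, assigned_ignorable):
        resp5, att9 = [], []
        for _, assigned in assigned_ignorable:
            sw = _status_wide(assigned)
            resp5.append((sw[5] == "response").mean())
            att9.append((sw[9] == "attrition").mean())
        assert abs(np.mean(resp5) - 0.871) < binom_3se(0.871, 20_000)
        assert abs(np.mean(att9) - 0.060) < binom_3se(0.060, 20_000)

    def test_death_and_attrition_absorbing(self, assigned_ignorable):
        _, assigned = assigned_ignorable[0]
        sw = _status_wide(assigned)
        for a, b in ((5, 7), (7, 9), (9, 11)):
            absorbed = sw[a].isin(["death", "attrition"])
            assert (sw.loc[absorbed, b] == sw.loc[absorbed, a]).all()

    def test_nonmonotone_nonresponse_exists(self, assigned_ignorable):
        _, assigned = assigned_ignorable[0]
        sw = _status_wide(assigned)
        alternators = ((sw[7] == "non_response") & (sw[9] == "response")).sum()
        assert alternators > 0

    def test_forced_response_everywhere(self, global_params):
        panel = generate_cohort(global_params, 500, 7)
        targets = {
            3: {"non_response": 0.0},
            5: {"response": {"non_response": 0.0}, "non_response": {"non_response": 0.0}},
        }
        for ph in (7, 9, 11):
            targets[ph] = {
                "response": {"non_response": 0.0, "death": 0.0, "attrition": 0.0},
                "non_response": {"non_response": 0.0, "death": 0.0, "attrition": 0.0},
            }
        params = MissingnessParams(status_targets=targets)
        assigned = assign_participation(panel, params, 8)
        assert (assigned["status"] == "response").all()

    def test_attrition_mar_given_covariates_when_ignorable(self, global_params):
        """Under the ignorable mechanism, new attrition at phase 7 carries no
        outcome signal beyond the covariates."""
        panel = generate_cohort(global_params, 20_000, 300)
        assigned = assign_participation(panel, MissingnessParams(), 301)
        sw = _status_wide(assigned)
        base = panel[panel["phase"] == 7].set_index("participant_id")
        at_risk = sw[5].isin(["response", "non_response"])
        y = base.loc[at_risk.index[at_risk], "outcome"]
        d = (sw.loc[at_risk, 7] == "attrition").astype(float)
        cov = base.loc[y.index, ["age_cat", "grade", "education"]].astype(float)
        X = sm.add_constant(pd.concat([cov, y.rename("outcome")], axis=1))
        fit = sm.Logit(d.to_numpy(), X).fit(disp=0)
        assert abs(fit.params["outcome"]) < 3 * fit.bse["outcome"]


@pytest.fixture(scope="module")
def calibrated(global_params):
    panel = generate_cohort(global_params, 10_000, 400)
    params = MissingnessParams()
    lam0, lam1, report = calibrate_informative_attrition(panel, params, -0.5, seed=401)
    return panel, params, lam0, lam1, report


class TestInformativeAttrition:
    def test_shift_and_rate_achieved(self, calibrated):
        _, _, _, lam1, report = calibrated
        assert lam1 < 0
        assert abs(report["achieved_shift"] - (-0.5)) < 0.02
        for phase, rate in report["expected_new_attrition_rate"].items():
            assert abs(rate - report["ignorable_new_attrition_rate"][phase]) < 1e-3

    def test_realized_attrition_outcomes_shifted(self, calibrated):
        panel, params, lam0, lam1, report = calibrated
        informative = replace(params, lambda0=lam0, lambda1=lam1)
        assigned = assign_participation(panel, informative, 402)
        sw = _status_wide(assigned)
        ywide = panel.pivot(index="participant_id", columns="phase", values="outcome")
        vals = []
        seen = pd.Series(False, index=sw.index)
        for ph in (7, 9, 11):
            new = (sw[ph] == "attrition") & ~seen
            vals.append(ywide.loc[new[new].index, ph])
            seen |= new
        y_onset = pd.concat(vals)
        target = report["ignorable_attrition_mean"] - 0.5
        se = y_onset.std() / np.sqrt(len(y_onset))
        assert abs(y_onset.mean() - target) < 3 * se

    def test_zero_target_shift_reduces_to_ignorable(self, global_params):
        panel = generate_cohort(global_params, 4_000, 405)
        lam0, lam1, report = calibrate_informative_attrition(
            panel, MissingnessParams(), 0.0, seed=406
        )
        assert lam1 == 0.0
        assert abs(report["achieved_shift"]) < 1e-10

    def test_agrees_with_grid_search_oracle(self, calibrated, global_params):
        """Brute 2-D lattice over (lambda1, lambda0_7) reproduces the
        calibrated pair to grid resolution (single-phase sub-problem)."""
        panel, params, lam0, lam1, _ = calibrated
        _, structure = _ignorable_attrition_structure(panel, params, 401)
        s = structure[7]
        target_mass = s["p_ign"].sum()
        m0 = (s["p_ign"] * s["y"]).sum() / target_mass
        # oracle: for each lambda1 on a lattice, pick the lambda0 minimising
        # the rate error, then pick the pair minimising the shift error
        l1_grid = np.linspace(lam1 - 0.5, lam1 + 0.5, 81)
        l0_grid = np.linspace(lam0[7] - 1.0, lam0[7] + 1.0, 161)
        best = None
        for l1 in l1_grid:
            mass = expit(l0_grid[:, None] + l1 * s["y"][None, :]).sum(axis=1)
            l0 = l0_grid[np.argmin(np.abs(mass - target_mass))]
            p = expit(l0 + l1 * s["y"])
            shift = (p * s["y"]).sum() / p.sum() - m0
            err = abs(shift - (-0.5))
            if best is None or err < best[0]:
                best = (err, l1, l0)
        # single-phase oracle should land near the jointly calibrated values
        assert abs(best[1] - lam1) < 0.1
        assert abs(best[2] - lam0[7]) < 0.1

    def test_infeasible_shift_raises(self, global_params):
        from attrisim.cohort_generator import CalibrationError

        panel = generate_cohort(global_params, 2_000, 407)
        with pytest.raises(CalibrationError, match="achiev"):
            calibrate_informative_attrition(panel, MissingnessParams(), -50.0, seed=408)


class TestBlanking:
    def test_observed_values_preserved(self, memory_mi_run):
        panel, blanked = memory_mi_run["panel"], memory_mi_run["blanked"]
        obs = blanked["outcome"].notna()
        assert np.allclose(blanked.loc[obs, "outcome"], panel.loc[obs, "outcome"])
        obs_s = blanked["smoking"].notna()
        assert (blanked.loc[obs_s, "smoking"].to_numpy() == panel.loc[obs_s, "smoking"].to_numpy()).all()

    def test_statuses_blank_their_phases(self, memory_mi_run):
        blanked = memory_mi_run["blanked"]
        nonresp = blanked["status"] != "response"
        assert blanked.loc[nonresp, "outcome"].isna().all()
        assert blanked.loc[nonresp, "smoking"].isna().all()

    def test_flag_marks_attrition_only_by_default(self, memory_mi_run):
        blanked = memory_mi_run["blanked"]
        assert (blanked["attrition_flag"] == (blanked["status"] == "attrition").astype(int)).all()

    def test_all_response_and_zero_item_rate_identity(self, global_params):
        panel = generate_cohort(global_params, 300, 17)
        params = MissingnessParams(item_nonresponse_rate=0.0)
        forced = panel.copy()
        forced["status"] = "response"
        blanked = apply_missingness(forced, params, 18)
        assert np.allclose(blanked["outcome"], panel["outcome"])
        assert (blanked["smoking"].to_numpy() == panel["smoking"].to_numpy()).all()
        assert (blanked["attrition_flag"] == 0).all()

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError, match="mechanism"):
            MissingnessParams(mechanism="bogus").validate()

    def test_sensitivity_variant_flags_more(self, global_params):
        panel = generate_cohort(global_params, 10_000, 500)
        params, _ = default_missingness_params(panel, seed=501)
        assigned = assign_participation(panel, params, 502)
        only = apply_missingness(assigned, params, 503)
        plus = apply_missingness(
            assigned, replace(params, noninformative_group="attrition_plus_nonresponse"), 503
        )
        late = lambda df: df[df["phase"].isin([7, 9, 11])]
        f_only = late(only).groupby("participant_id")["attrition_flag"].max().mean()
        f_plus = late(plus).groupby("participant_id")["attrition_flag"].max().mean()
        assert 0.04 < f_only < 0.11
        assert 0.17 < f_plus < 0.30
        assert f_plus > 2.5 * f_only

    def test_education_mechanism(self, global_params):
        panel = generate_cohort(global_params, 5_000, 600)
        params = MissingnessParams(mechanism="education_missing")
        assert "education" not in params.status_covariates()
        assert "smoking" in params.status_covariates()
        assigned = assign_participation(panel, params, 601)
        blanked = apply_missingness(assigned, params, 602)
        assert blanked["smoking"].notna().all()
        miss_edu = blanked.groupby("participant_id")["education"].apply(lambda s: s.isna().all())
        some_edu = blanked.groupby("participant_id")["education"].apply(lambda s: s.isna().any())
        assert (miss_edu == some_edu).all()  # time-independent: all-or-none
        assert abs(some_edu.mean() - params.education_missing_rate) < 0.03
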