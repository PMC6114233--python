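"""Participation statuses and value blanking.

Statuses follow the emulated cohort's follow-up design: phases 3 and 5 admit
only response / non-response (a covariate-conditional logistic, phase 5
stratified by the phase-3 status); phases 7, 9 and 11 admit all four
statuses (response, non-response, death, attrition) from covariate-
conditional multinomial models stratified by the previous response /
non-response status.  Death and attrition are absorbing.  Intercepts are
calibrated by root-finding so the realized status proportions match the
configured targets; the covariate coefficients themselves are modest
ordinal log-odds, making the mechanism ignorable given covariates.

Informative attrition replaces the covariate-based attrition probability
with a logistic in the same-phase outcome value,

    logit(p_ij) = lambda0_j + lambda1 * Y_ij,

with (lambda0_j, lambda1) calibrated so the expected attrition rate is
preserved while the mean outcome among attriters drops by a configured
amount (default 0.5 SD) relative to the ignorable mechanism.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .params import (
    PHASES,
    STATUS_ATTRITION,
    STATUS_DEATH,
    STATUS_NONRESPONSE,
    STATUS_RESPONSE,
    MissingnessParams,
)
from .cohort_generator import CalibrationError

_MULTI_PHASES = (7, 9, 11)
_NONREF_STATUSES = (STATUS_NONRESPONSE, STATUS_DEATH, STATUS_ATTRITION)


def _base_covariates(panel: pd.DataFrame, params: MissingnessParams) -> pd.DataFrame:
    """Per-participant covariate codes entering the status models."""
    base = panel[panel["phase"] == 5].set_index("participant_id")
    cols = {}
    for v in params.status_covariates():
        cols[v] = base[v].astype(float)
    return pd.DataFrame(cols)


def _linear_predictor(cov: pd.DataFrame, coeffs: Mapping[str, float]) -> np.ndarray:
    lin = np.zeros(len(cov))
    for v, series in cov.items():
        key = v if v in coeffs else "education"  # smoking substitutes for education
        lin = lin + coeffs[key] * (series.to_numpy() - series.to_numpy().mean())
    return lin


def _calibrate_binary_intercept(lin: np.ndarray, target: float) -> float:
    if target <= 1e-12:
        return -50.0  # probability numerically zero
    if target >= 1 - 1e-12:
        return 50.0
    f = lambda a: float(np.mean(expit(a + lin))) - target
    return optimize.brentq(f, -60.0, 60.0, xtol=1e-10)


def _calibrate_multinomial_intercepts(
    lins: dict[str, np.ndarray], targets: Mapping[str, float]
) -> dict[str, float]:
    """Intercepts of a multinomial logit (reference = response) such that the
    mean predicted probability of each non-reference status equals its
    target."""
    statuses = [s for s in _NONREF_STATUSES if s in targets]
    tvec = np.array([targets[s] for s in statuses])
    if tvec.sum() >= 1.0:
        raise CalibrationError(f"status targets sum to {tvec.sum():.3f} >= 1")
    if np.any(tvec <= 1e-12):
        # degenerate targets: those statuses get probability zero
        kept = {s: targets[s] for s, t in zip(statuses, tvec) if t > 1e-12}
        alphas = _calibrate_multinomial_intercepts(lins, kept) if kept else {}
        for s, t in zip(statuses, tvec):
            if t <= 1e-12:
                alphas[s] = -50.0
        return alphas

    def mean_probs(alpha: np.ndarray) -> np.ndarray:
        eta = np.stack([alpha[i] + lins[s] for i, s in enumerate(statuses)])
        denom = 1.0 + np.exp(eta).sum(axis=0)
        return (np.exp(eta) / denom).mean(axis=1)

    sol = optimize.root(lambda a: mean_probs(a) - tvec, x0=np.log(tvec / (1 - tvec.sum())), tol=1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
        raise CalibrationError(f"status intercept calibration failed: residuals {sol.fun}")
    return dict(zip(statuses, sol.x))


def _status_probabilities(
    cov: pd.DataFrame,
    params: MissingnessParams,
    targets: Mapping[str, float],
    idx: np.ndarray,
) -> dict[str, np.ndarray]:
    """Calibrated per-participant probabilities within a stratum (rows
    ``idx`` of the covariate frame).

    Attrition is a separate Bernoulli overlay, flat in covariates (so the
    informative outcome-dependent logistic nests it exactly at lambda1=0);
    the remaining statuses come from a covariate multinomial among
    non-attriters, renormalized so the stratum marginals hit the targets."""
    sub = cov.iloc[idx]
    p_att = float(targets.get(STATUS_ATTRITION, 0.0))
    rest = {
        s: targets[s] / (1.0 - p_att)
        for s in (STATUS_NONRESPONSE, STATUS_DEATH)
        if s in targets
    }
    lins = {s: _linear_predictor(sub, params.status_coeffs[s]) for s in rest}
    alphas = _calibrate_multinomial_intercepts(lins, rest)
    eta = np.stack([alphas[s] + lins[s] for s in alphas])
    denom = 1.0 + np.exp(eta).sum(axis=0)
    cond = {s: np.exp(eta[i]) / denom for i, s in enumerate(alphas)}
    probs = {s: (1.0 - p_att) * p for s, p in cond.items()}
    probs[STATUS_ATTRITION] = np.full(len(sub), p_att)
    probs[STATUS_RESPONSE] = (1.0 - p_att) / denom
    return probs


def assign_participation(
    panel: pd.DataFrame,
    params: MissingnessParams,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Fill the ``status`` column at every phase.

    If ``params.lambda1 != 0`` (with calibrated ``params.lambda0``), the
    attrition component at phases 7/9/11 is generated from the informative
    logistic on the same-phase outcome instead of the covariate multinomial;
    the remaining statuses are rescaled to keep a proper distribution.
    """
    params.validate()
    if params.informative and params.lambda0 is None:
        raise ValueError("informative attrition requires calibrated lambda0 per phase")
    rng = np.random.default_rng(seed)
    cov = _base_covariates(panel, params)
    n = len(cov)
    outcome = panel.pivot(index="participant_id", columns="phase", values="outcome")
    outcome = outcome.loc[cov.index]
    status = {}

    # phase 3: response / non-response
    lin = _linear_predictor(cov, params.status_coeffs[STATUS_NONRESPONSE])
    a3 = _calibrate_binary_intercept(lin, params.status_targets[3][STATUS_NONRESPONSE])
    nr3 = rng.random(n) < expit(a3 + lin)
    status[3] = np.where(nr3, STATUS_NONRESPONSE, STATUS_RESPONSE)

    # phase 5: stratified by phase-3 status
    status[5] = np.empty(n, dtype=object)
    for stratum, tdict in params.status_targets[5].items():
        mask = status[3] == stratum
        if not mask.any():
            continue
        sub_lin = lin[mask]
        a5 = _calibrate_binary_intercept(sub_lin, tdict[STATUS_NONRESPONSE])
        nr5 = rng.random(mask.sum()) < expit(a5 + sub_lin)
        status[5][mask] = np.where(nr5, STATUS_NONRESPONSE, STATUS_RESPONSE)

    # phases 7, 9, 11: four statuses, absorbing death/attrition
    for phase in _MULTI_PHASES:
        prev = status[phase - 2]
        cur = np.array(prev, dtype=object)  # carry forward absorbing states
        for stratum in (STATUS_RESPONSE, STATUS_NONRESPONSE):
            mask = prev == stratum
            if not mask.any():
                continue
            idx = np.flatnonzero(mask)
            probs = _status_probabilities(cov, params, params.status_targets[phase][stratum], idx)
            if params.informative:
                y = outcome[phase].to_numpy()[idx]
                p_att = expit(params.lambda0[phase] + params.lambda1 * y)
                scale = (1.0 - p_att) / np.clip(1.0 - probs[STATUS_ATTRITION], 1e-12, None)
                probs = {
                    s: (p_att if s == STATUS_ATTRITION else p * scale)
                    for s, p in probs.items()
                }
            mat = np.column_stack([probs[s] for s in (STATUS_RESPONSE, STATUS_NONRESPONSE, STATUS_DEATH, STATUS_ATTRITION)])
            u = rng.random(len(idx))
            choice = (u[:, None] >= np.cumsum(mat, axis=1)).sum(axis=1)
            labels = np.array((STATUS_RESPONSE, STATUS_NONRESPONSE, STATUS_DEATH, STATUS_ATTRITION), dtype=object)
            cur[idx] = labels[np.clip(choice, 0, 3)]
        status[phase] = cur

    out = panel.copy()
    smap = pd.DataFrame(status, index=cov.index)  # columns = phases
    long = smap.stack()
    long.index.names = ["participant_id", "phase"]
    out = out.set_index(["participant_id", "phase"])
    out["status"] = long.astype("string")
    return out.reset_index()


# ---------------------------------------------------------------------------
# Informative-attrition calibration
# ---------------------------------------------------------------------------


def _ignorable_attrition_structure(
    panel: pd.DataFrame, params: MissingnessParams, seed: int | np.random.Generator
):
    """One ignorable assignment plus, per phase, the frozen at-risk index
    sets, per-participant ignorable attrition probabilities and outcomes."""
    ign = replace(params, lambda0=None, lambda1=0.0)
    assigned = assign_participation(panel, ign, seed)
    cov = _base_covariates(panel, params)
    outcome = panel.pivot(index="participant_id", columns="phase", values="outcome").loc[cov.index]
    swide = assigned.pivot(index="participant_id", columns="phase", values="status").loc[cov.index]
    structure = {}
    for phase in _MULTI_PHASES:
        prev = swide[phase - 2].to_numpy()
        at_risk = np.flatnonzero((prev == STATUS_RESPONSE) | (prev == STATUS_NONRESPONSE))
        p_att = np.empty(len(at_risk))
        for stratum in (STATUS_RESPONSE, STATUS_NONRESPONSE):
            mask = prev[at_risk] == stratum
            if not mask.any():
                continue
            probs = _status_probabilities(
                cov, params, params.status_targets[phase][stratum], at_risk[mask]
            )
            p_att[mask] = probs[STATUS_ATTRITION]
        structure[phase] = {
            "y": outcome[phase].to_numpy()[at_risk],
            "p_ign": p_att,
        }
    return assigned, structure


def calibrate_informative_attrition(
    panel: pd.DataFrame,
    params: MissingnessParams,
    target_shift: float = -0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[int, float], float, dict]:
    """Calibrate (lambda0 per phase, lambda1) of the informative logistic.

    Nested root-finding: for a candidate lambda1 the inner loop solves each
    phase's lambda0 so the expected attrition mass among the (frozen,
    ignorably assigned) at-risk set matches the ignorable mechanism's; the
    outer loop solves lambda1 so the probability-weighted mean outcome of
    attriters sits ``target_shift`` away from the ignorable mechanism's.

    Returns ``(lambda0, lambda1, report)``; the report carries achieved
    expected rates and shift.
    """
    _, structure = _ignorable_attrition_structure(panel, params, seed)
    masses = {j: s["p_ign"].sum() for j, s in structure.items()}
    m0 = sum((s["p_ign"] * s["y"]).sum() for s in structure.values()) / sum(masses.values())

    def solve_lambda0(lam1: float) -> dict[int, float]:
        lam0 = {}
        for j, s in structure.items():
            f = lambda a: expit(a + lam1 * s["y"]).sum() - masses[j]
            lam0[j] = optimize.brentq(f, -30.0, 10.0, xtol=1e-12)
        return lam0

    def shift(lam1: float) -> float:
        lam0 = solve_lambda0(lam1)
        num = den = 0.0
        for j, s in structure.items():
            p = expit(lam0[j] + lam1 * s["y"])
            num += (p * s["y"]).sum()
            den += p.sum()
        return num / den - m0

    if target_shift == 0.0:
        lam1 = 0.0
    else:
        lo, hi = (-12.0, 0.0) if target_shift < 0 else (0.0, 12.0)
        f = lambda l: shift(l) - target_shift
        if f(lo) * f(hi) > 0:
            raise CalibrationError(
                f"no lambda1 in [{lo}, {hi}] achieves shift {target_shift}; "
                f"achievable range edge {shift(lo if target_shift < 0 else hi):.3f}"
            )
        lam1 = optimize.brentq(f, lo, hi, xtol=1e-10)
    lam0 = solve_lambda0(lam1)
    achieved_rates = {}
    for j, s in structure.items():
        achieved_rates[j] = float(expit(lam0[j] + lam1 * s["y"]).mean())
    report = {
        "lambda0": {int(k): float(v) for k, v in lam0.items()},
        "lambda1": float(lam1),
        "ignorable_attrition_mean": float(m0),
        "achieved_shift": float(shift(lam1)),
        "target_shift": float(target_shift),
        "expected_new_attrition_rate": achieved_rates,
        "ignorable_new_attrition_rate": {
            int(j): float(s["p_ign"].mean()) for j, s in structure.items()
        },
    }
    return {int(k): float(v) for k, v in lam0.items()}, float(lam1), report


# ---------------------------------------------------------------------------
# Blanking
# ---------------------------------------------------------------------------


def apply_missingness(
    panel: pd.DataFrame,
    params: MissingnessParams,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Blank values according to assigned statuses and the chosen mechanism,
    set the non-ignorable flag R, and record observedness indicators.

    smoking_missing: outcome and smoking blank at non-response / death /
    attrition phases, plus age-dependent item non-response among responders.
    education_missing: outcome blanks per status; baseline education blanks
    for a random (age-dependent) subset of participants; smoking stays
    observed.
    """
    params.validate()
    if panel["status"].isna().any():
        raise ValueError("statuses must be assigned before blanking")
    rng = np.random.default_rng(seed)
    out = panel.copy()
    status = out["status"].to_numpy()
    responder = status == STATUS_RESPONSE
    nonobs = ~responder  # non-response, death or attrition phase

    # item non-response among responders, mildly increasing in age
    lin = params.item_nonresponse_age_coeff * (out["age_cat"].to_numpy() - 3.0)
    base = np.log(params.item_nonresponse_rate / (1 - params.item_nonresponse_rate)) if params.item_nonresponse_rate > 0 else -np.inf
    p_item = expit(base + lin) if params.item_nonresponse_rate > 0 else np.zeros(len(out))

    miss_outcome = nonobs | (responder & (rng.random(len(out)) < p_item))
    if params.mechanism == "smoking_missing":
        miss_smoking = nonobs | (responder & (rng.random(len(out)) < p_item))
        miss_education_participant = np.zeros(0, dtype=bool)
    else:
        miss_smoking = np.zeros(len(out), dtype=bool)
        base_rows = out["phase"] == 5
        age5 = out.loc[base_rows, "age_cat"].to_numpy()
        p_edu = expit(
            np.log(params.education_missing_rate / (1 - params.education_missing_rate))
            + params.item_nonresponse_age_coeff * (age5 - 3.0)
        )
        miss_education_participant = rng.random(base_rows.sum()) < p_edu

    out.loc[miss_outcome, "outcome"] = np.nan
    out["observed_outcome"] = (~miss_outcome).astype(int)
    if params.mechanism == "smoking_missing":
        out["smoking"] = out["smoking"].astype(float)
        out.loc[miss_smoking, "smoking"] = np.nan
        out["observed_exposure"] = (~miss_smoking).astype(int)
    else:
        pid_missing_edu = out.loc[out["phase"] == 5, "participant_id"].to_numpy()[
            miss_education_participant
        ]
        edu_mask = out["participant_id"].isin(pid_missing_edu).to_numpy()
        out["education"] = out["education"].astype(float)
        out.loc[edu_mask, "education"] = np.nan
        out["observed_exposure"] = (~edu_mask).astype(int)

    flagged = status == STATUS_ATTRITION
    if params.noninformative_group == "attrition_plus_nonresponse":
        flagged = flagged | (status == STATUS_NONRESPONSE)
    out["attrition_flag"] = flagged.astype(int)
    return out


def default_missingness_params(
    panel: pd.DataFrame,
    mechanism: str = "smoking_missing",
    noninformative_group: str = "attrition_only",
    k: float = -0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[MissingnessParams, dict]:
    """Missingness parameters with the informative-attrition logistic
    calibrated on the supplied (fully observed) panel."""
    params = MissingnessParams(
        mechanism=mechanism, noninformative_group=noninformative_group, k=k
    )
    lam0, lam1, report = calibrate_informative_attrition(panel, params, target_shift=k, seed=seed)
    return replace(params, lambda0=lam0, lambda1=lam1), report
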