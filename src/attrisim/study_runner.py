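"""Replicate orchestration: generate -> fit full -> ampute -> fit AC ->
impute (two-fold FCS) + pool -> delta-adjust + pool -> evaluate.

Replicates are embarrassingly parallel; every stage of every replicate
draws from a counter-based RNG stream derived from (master_seed, replicate,
stage), so a single replicate can be recomputed in isolation and results
are invariant to the worker count.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import evaluation as ev
from .cohort_generator import default_generative_params, generate_cohort
from .imputation import apply_pmm, impute_twofold_fcs
from .inference import FitResult, fit_substantive_model, pool_rubin
from .missingness_engine import (
    apply_missingness,
    assign_participation,
    default_missingness_params,
)
from .params import CATEGORY_LABELS, GenerativeParams, StudyConfig, derive_seed

_STAGE = {"generate": 0, "calibrate": 1, "assign": 2, "blank": 3, "impute": 4}

METHODS = ("full", "available_case", "mi", "pmm")


def truth_map(params: GenerativeParams) -> dict[str, float]:
    """True fixed-effect value for every substantive-model term."""
    out = {"Intercept": params.beta0, "time": params.slope_reference}
    for var, labels in CATEGORY_LABELS.items():
        key = var if var != "smoking" else "smoking"
        for level in range(2, len(labels) + 1):
            out[f"{var}[{level}]"] = float(params.main_effects[key][level - 1])
            out[f"time:{var}[{level}]"] = float(params.slope_effects[key][level - 1])
    return out


def _impute_seed(config: StudyConfig, replicate: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [int(config.master_seed), int(replicate), _STAGE["impute"]]
    )


def run_replicate(config: StudyConfig, replicate: int) -> dict:
    """All four analyses on one simulated cohort; returns fits and panels."""
    gen = default_generative_params(config.outcome_regime)
    panel = generate_cohort(
        gen, config.n_participants, derive_seed(config.master_seed, replicate, _STAGE["generate"])
    )
    fit_full = fit_substantive_model(panel, "full")

    mparams, calib_report = default_missingness_params(
        panel,
        mechanism=config.mechanism,
        noninformative_group=config.noninformative_group,
        k=config.k,
        seed=derive_seed(config.master_seed, replicate, _STAGE["calibrate"]),
    )
    assigned = assign_participation(
        panel, mparams, derive_seed(config.master_seed, replicate, _STAGE["assign"])
    )
    blanked = apply_missingness(
        assigned, mparams, derive_seed(config.master_seed, replicate, _STAGE["blank"])
    )
    fit_ac = fit_substantive_model(blanked, "available_case")

    completed = impute_twofold_fcs(blanked, config.imputation, _impute_seed(config, replicate))
    fits_mi = [fit_substantive_model(p, "mi") for p in completed]
    pooled_mi = pool_rubin(fits_mi, "mi")

    adjusted = apply_pmm(completed, config.k, blanked)
    fits_pmm = [fit_substantive_model(p, "pmm") for p in adjusted]
    pooled_pmm = pool_rubin(fits_pmm, "pmm")

    return {
        "replicate": replicate,
        "fits": {
            "full": fit_full,
            "available_case": fit_ac,
            "mi": pooled_mi,
            "pmm": pooled_pmm,
        },
        "panels": {
            "full": panel,
            "available_case": blanked,
            "mi": completed,
            "pmm": adjusted,
        },
        "calibration": calib_report,
    }


def _estimate_rows(replicate: int, fits: Mapping[str, FitResult]) -> pd.DataFrame:
    frames = []
    for method, fr in fits.items():
        f = fr.to_frame().rename(columns={"method_tag": "method"})
        f["replicate"] = replicate
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def _slope_table(results: list[dict]) -> pd.DataFrame:
    """Mean adjusted per-category slopes and SEs per method across
    replicates (coefficient-table layout)."""
    rows = []
    for res in results:
        for method, fr in res["fits"].items():
            sl = fr.adjusted_slopes()
            sl["method"] = method
            sl["replicate"] = res["replicate"]
            rows.append(sl)
    allsl = pd.concat(rows, ignore_index=True)
    return (
        allsl.groupby(["variable", "level", "method"], sort=False)[["slope", "se"]]
        .mean()
        .reset_index()
    )


def run_study(config: StudyConfig) -> dict:
    """Run the full replicate study described by ``config``.

    Returns a results bundle with raw per-replicate estimates, the
    Monte-Carlo evaluation summary, coefficient tables, correlation
    diagnostics (computed on the first successful replicate) and the
    calibration reports.  Replicates whose model fits fail are excluded and
    logged; the run aborts if more than ``max_failure_fraction`` fail.
    """
    config.validate()
    indices = list(range(config.n_replicates))

    def _safe(replicate: int):
        try:
            return run_replicate(config, replicate)
        except Exception as exc:  # noqa: BLE001 - per-replicate quarantine
            return {"replicate": replicate, "error": repr(exc)}

    if config.n_jobs != 1:
        raw = Parallel(n_jobs=config.n_jobs)(delayed(_safe)(r) for r in indices)
    else:
        raw = [_safe(r) for r in indices]
    failures = [r for r in raw if "error" in r]
    results = [r for r in raw if "error" not in r]
    if len(failures) > config.max_failure_fraction * config.n_replicates:
        raise RuntimeError(
            f"{len(failures)}/{config.n_replicates} replicates failed: "
            + "; ".join(f"{f['replicate']}: {f['error']}" for f in failures[:5])
        )

    estimates = pd.concat(
        [_estimate_rows(r["replicate"], r["fits"]) for r in results], ignore_index=True
    )
    gen = default_generative_params(config.outcome_regime)
    truth = truth_map(gen)
    summary = (
        ev.evaluate_estimates(estimates, truth) if len(results) >= 2 else None
    )
    corr = ev.correlation_diagnostics(
        {
            "full": results[0]["panels"]["full"],
            "available_case": results[0]["panels"]["available_case"],
            "mi": results[0]["panels"]["mi"],
            "pmm": results[0]["panels"]["pmm"],
        }
    )
    return {
        "config": dataclasses.asdict(config),
        "estimates": estimates,
        "evaluation": summary,
        "slope_table": _slope_table(results),
        "correlations": corr,
        "calibration": results[0]["calibration"],
        "failures": failures,
        "n_completed": len(results),
    }
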