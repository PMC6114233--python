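"""Monte-Carlo evaluation statistics and correlation diagnostics.

For each coefficient and estimation method across simulation replicates:
bias (mean estimate minus truth), empirical variance (denominator M-1),
MSE = variance + bias^2, the MSE ratio against the available-case analysis,
and confidence-interval coverage (t quantiles where a pooled-MI df is
available, normal quantiles otherwise).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .params import ANALYSIS_PHASES


def evaluate_estimates(
    estimates: pd.DataFrame,
    truth: Mapping[str, float],
    level: float = 0.95,
    reference_method: str = "available_case",
) -> pd.DataFrame:
    """Summarise replicate estimates per (term, method).

    ``estimates`` needs columns: replicate, method, term, estimate, se, df
    (df = inf for normal-quantile intervals).  ``truth`` maps term -> true
    value; terms absent from it raise.
    """
    required = {"replicate", "method", "term", "estimate", "se", "df"}
    if missing := required - set(estimates.columns):
        raise ValueError(f"estimates frame lacks columns {sorted(missing)}")
    alpha = 1 - level
    rows = []
    for (term, method), g in estimates.groupby(["term", "method"], sort=False):
        if term not in truth:
            raise KeyError(f"no true value supplied for term {term!r}")
        theta = float(truth[term])
        est = g["estimate"].to_numpy(dtype=float)
        se = g["se"].to_numpy(dtype=float)
        df = g["df"].to_numpy(dtype=float)
        n = len(est)
        if n < 2:
            raise ValueError(f"need at least 2 replicates for ({term}, {method})")
        bias = float(np.mean(est) - theta)
        var = float(np.var(est, ddof=1))
        mse = var + bias**2
        q = np.where(np.isfinite(df), stats.t.ppf(1 - alpha / 2, np.clip(df, 1e-3, None)),
                     stats.norm.ppf(1 - alpha / 2))
        covered = np.abs(est - theta) <= q * se
        rows.append(
            {
                "term": term,
                "method": method,
                "truth": theta,
                "bias": bias,
                "pct_bias": 100.0 * bias / abs(theta) if theta != 0 else np.nan,
                "emp_variance": var,
                "mse": mse,
                "coverage": float(np.mean(covered)),
                "n_replicates": n,
            }
        )
    out = pd.DataFrame(rows)
    ref = out[out["method"] == reference_method].set_index("term")["mse"]
    if len(ref):
        out["mse_ratio_vs_ac"] = out.apply(
            lambda r: r["mse"] / ref[r["term"]] if r["term"] in ref.index and ref[r["term"]] > 0 else np.nan,
            axis=1,
        )
    else:
        out["mse_ratio_vs_ac"] = np.nan
    return out


_DIAG_PHASES = tuple(ANALYSIS_PHASES)


def _diagnostic_matrix(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-participant frame over the diagnostic variables: outcome and
    smoking at the analysis phases plus the coded baseline covariates."""
    Y = panel.pivot(index="participant_id", columns="phase", values="outcome")
    S = panel.pivot(index="participant_id", columns="phase", values="smoking")
    base = panel[panel["phase"] == 5].set_index("participant_id")
    out = {}
    for p in _DIAG_PHASES:
        out[f"outcome_{p}"] = Y[p]
    for p in _DIAG_PHASES:
        out[f"smoking_{p}"] = S[p].astype(float)
    for v in ("age_cat", "grade", "education"):
        out[v] = base[v].astype(float)
    return pd.DataFrame(out)


def correlation_diagnostics(
    panels: Mapping[str, pd.DataFrame | list[pd.DataFrame]]
) -> dict[str, pd.DataFrame]:
    """Pearson correlation matrix per data state plus differences vs 'full'.

    Keys are data states ('full', 'available_case', 'mi', 'pmm', ...); a
    list value (multiply-imputed panels) is averaged element-wise over the
    imputations.  Available-case correlations use pairwise completers;
    an empty pairwise cell yields NaN.
    """
    mats = {}
    for state, value in panels.items():
        if isinstance(value, (list, tuple)):
            stack = [
                _diagnostic_matrix(p).corr(method="pearson", min_periods=2) for p in value
            ]
            mats[state] = sum(stack) / len(stack)
        else:
            mats[state] = _diagnostic_matrix(value).corr(method="pearson", min_periods=2)
    out = dict(mats)
    if "full" in mats:
        for state, m in mats.items():
            if state != "full":
                out[f"diff_{state}"] = m - mats["full"]
    return out


def plot_evaluation(summary: pd.DataFrame, path=None):
    """Panel plot of % bias, MSE ratio vs AC and coverage per slope term
    and method (requires matplotlib; returns the figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    slopes = summary[summary["term"].str.startswith("time")]
    metrics = [("pct_bias", "% bias", 0.0), ("mse_ratio_vs_ac", "MSE ratio vs AC", 1.0),
               ("coverage", "coverage", 0.95)]
    fig, axes = plt.subplots(1, 3, figsize=(14, 4), sharey=True)
    terms = list(dict.fromkeys(slopes["term"]))
    ypos = np.arange(len(terms))
    for ax, (col, label, refline) in zip(axes, metrics):
        for method, g in slopes.groupby("method"):
            vals = g.set_index("term").reindex(terms)[col]
            ax.plot(vals.to_numpy(), ypos, "o", label=method, alpha=0.75)
        ax.axvline(refline, color="grey", lw=0.8, ls="--")
        ax.set_xlabel(label)
    axes[0].set_yticks(ypos, terms)
    axes[0].invert_yaxis()
    axes[-1].legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
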