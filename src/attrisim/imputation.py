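"""Two-fold fully-conditional-specification multiple imputation and the
pattern-mixture delta adjustment.

The two-fold FCS algorithm imputes the panel phase by phase: within a phase
it cycles univariate imputation models for each incomplete variable
conditional on the other variables at that phase and the outcome at the
adjacent phases (a within-time iteration, repeated ``b_W`` times); sweeping
all phases in time order completes one among-time iteration, repeated
``b_A`` times.  The restricted conditioning window keeps the longitudinal
correlation structure while avoiding the collinearity of conditioning on
every phase at once.

Smoking status is conditioned on at baseline only (its repeated measures
correlate ~0.95 and destabilise the categorical models), i.e. adjacent-
phase smoking terms are replaced by baseline smoking in every model.

Continuous targets use proper imputation (posterior parameter draw plus
Gaussian noise); categorical targets use a multinomial logit fitted on
completers with a category draw from the predicted probabilities.

The pattern-mixture adjustment afterwards shifts imputed outcome values
flagged as non-ignorably missing (attrition, optionally plus non-response)
by a fixed offset k, encoding the assumed departure from ignorability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .params import PHASES, CATEGORY_LABELS, ImputationConfig


class ImputationError(RuntimeError):
    pass


@dataclass
class ImputationLog:
    """Per-run record of fallbacks and seeds (one entry per event)."""

    events: list = field(default_factory=list)

    def add(self, imputation: int, phase: int, variable: str, message: str) -> None:
        self.events.append(
            {"imputation": imputation, "phase": phase, "variable": variable, "message": message}
        )


# ---------------------------------------------------------------------------
# Univariate draws
# ---------------------------------------------------------------------------


def draw_univariate_imputation(
    kind: str,
    X_fit: np.ndarray,
    y_fit: np.ndarray,
    X_target: np.ndarray,
    rng: np.random.Generator,
    *,
    parameter_draw: bool = True,
    noise: bool = True,
) -> np.ndarray:
    """Random draws from one univariate imputation model.

    continuous: OLS on completers, regression parameters drawn from their
    large-sample posterior (sigma^2 from the scaled inverse chi-square, beta
    from its Gaussian given sigma^2), then value = linear predictor +
    Gaussian noise.  ``parameter_draw=False`` / ``noise=False`` disable the
    respective draws (used for degenerate checks).

    categorical: multinomial logit on completers; each target row's category
    is drawn from its predicted probabilities.
    """
    if kind == "continuous":
        n, p = X_fit.shape
        beta_hat, _, rank, _ = np.linalg.lstsq(X_fit, y_fit, rcond=None)
        resid = y_fit - X_fit @ beta_hat
        dof = max(n - rank, 1)
        ss = float(resid @ resid)
        if parameter_draw and ss > 0:
            sigma2 = ss / stats.chi2.rvs(dof, random_state=rng)
            XtX = X_fit.T @ X_fit
            cov = np.linalg.pinv(XtX) * sigma2
            w, V = np.linalg.eigh(cov)
            beta = beta_hat + (V * np.sqrt(np.clip(w, 0, None))) @ V.T @ rng.standard_normal(p)
        else:
            sigma2 = ss / dof
            beta = beta_hat
        values = X_target @ beta
        if noise:
            values = values + rng.standard_normal(len(X_target)) * np.sqrt(sigma2)
        return values
    if kind == "categorical":
        classes = np.unique(y_fit)
        if len(classes) == 1:
            return np.full(len(X_target), classes[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            # near-unpenalized: the tiny ridge only stabilises separation
            clf = LogisticRegression(C=1e4, max_iter=60, tol=1e-3, solver="newton-cg")
            clf.fit(X_fit[:, 1:], y_fit)  # sklearn adds its own intercept
            probs = clf.predict_proba(X_target[:, 1:])
        u = rng.random(len(X_target))
        idx = (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)
        return clf.classes_[np.clip(idx, 0, len(clf.classes_) - 1)]
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# Wide-format helpers
# ---------------------------------------------------------------------------


def _to_wide(panel: pd.DataFrame) -> dict[str, pd.DataFrame]:
    Y = panel.pivot(index="participant_id", columns="phase", values="outcome")
    S = panel.pivot(index="participant_id", columns="phase", values="smoking").astype(float)
    base = panel[panel["phase"] == 5].set_index("participant_id")
    cov = base[["age_cat", "grade", "education"]].astype(float)
    return {"Y": Y, "S": S, "cov": cov}


def _dummies(codes: np.ndarray, levels: int, drop_first: bool = True) -> np.ndarray:
    start = 2 if drop_first else 1
    return np.column_stack([(codes == lv).astype(float) for lv in range(start, levels + 1)])


def _sparse_trim(X: np.ndarray, names: list[str], min_count: int = 3):
    """Drop indicator columns with too few positives among completers
    (equivalent to merging the sparse category into the reference)."""
    keep = [0]
    dropped = []
    for j in range(1, X.shape[1]):
        col = X[:, j]
        uniq = np.unique(col)
        if set(np.round(uniq, 6)).issubset({0.0, 1.0}) and col.sum() < min_count:
            dropped.append(names[j])
        else:
            keep.append(j)
    return X[:, keep], [names[i] for i in keep], dropped


class _TwofoldState:
    """Mutable working copy of the panel plus the original missingness
    masks."""

    def __init__(self, panel: pd.DataFrame):
        wide = _to_wide(panel)
        self.Y = wide["Y"].copy()
        self.S = wide["S"].copy()
        self.cov = wide["cov"].copy()
        self.miss_Y = {t: wide["Y"][t].isna().to_numpy() for t in PHASES}
        self.miss_S = {t: wide["S"][t].isna().to_numpy() for t in PHASES}
        self.miss_edu = wide["cov"]["education"].isna().to_numpy()
        for t in PHASES:
            if self.miss_Y[t].all():
                raise ImputationError(f"outcome entirely missing at phase {t}")
            if self.miss_S[t].all():
                raise ImputationError(f"smoking entirely missing at phase {t}")
        if self.miss_edu.all():
            raise ImputationError("education entirely missing")

    def initialize(self, rng: np.random.Generator) -> None:
        """Fill missing cells with draws from the per-phase observed
        marginals."""
        for t in PHASES:
            for frame, miss in ((self.Y, self.miss_Y[t]), (self.S, self.miss_S[t])):
                if miss.any():
                    obs = frame[t].to_numpy()[~miss]
                    frame.loc[miss, t] = rng.choice(obs, size=miss.sum(), replace=True)
        if self.miss_edu.any():
            obs = self.cov["education"].to_numpy()[~self.miss_edu]
            self.cov.loc[self.miss_edu, "education"] = rng.choice(
                obs, size=self.miss_edu.sum(), replace=True
            )

    # ---- predictor blocks -------------------------------------------------

    def _covariate_block(self, exclude: str | None = None):
        cols, names = [np.ones((len(self.cov), 1))], ["Intercept"]
        spec = [
            ("age_cat", self.cov["age_cat"].to_numpy(), 5),
            ("grade", self.cov["grade"].to_numpy(), 3),
            ("education", self.cov["education"].to_numpy(), 3),
        ]
        for name, codes, k in spec:
            if name == exclude:
                continue
            cols.append(_dummies(codes, k))
            names.extend(f"{name}[{lv}]" for lv in range(2, k + 1))
        return np.column_stack(cols), names

    def _smoking_block(self, t: int, config: ImputationConfig, target: str):
        """Smoking predictor columns for a model at phase ``t``; baseline
        smoking only under the flag, otherwise same phase (for outcome
        models) — never the target variable itself."""
        use_phase = 5 if config.baseline_smoking_only else t
        if target == "smoking" and use_phase == t:
            return None, []
        codes = self.S[use_phase].to_numpy()
        return _dummies(codes, 3), [f"smoking{use_phase}[{lv}]" for lv in (2, 3)]

    def _adjacent_outcomes(self, t: int, config: ImputationConfig, include_self: bool):
        idx = PHASES.index(t)
        phases = []
        if include_self:
            phases.append(t)
        for d in range(1, config.window + 1):
            if idx - d >= 0:
                phases.append(PHASES[idx - d])
            if idx + d < len(PHASES):
                phases.append(PHASES[idx + d])
        block = np.column_stack([self.Y[p].to_numpy() for p in phases])
        return block, [f"Y{p}" for p in phases]

    def design(self, t: int, target: str, config: ImputationConfig):
        """(X, names) for the univariate model of ``target`` at phase t."""
        blocks, names = [], []
        exclude_cov = "education" if target == "education" else None
        Xc, nc = self._covariate_block(exclude=exclude_cov)
        blocks.append(Xc)
        names.extend(nc)
        sb, sn = self._smoking_block(t, config, target)
        if sb is not None:
            blocks.append(sb)
            names.extend(sn)
        yb, yn = self._adjacent_outcomes(t, config, include_self=target != "outcome")
        blocks.append(yb)
        names.extend(yn)
        return np.column_stack(blocks), names


def _impute_one(
    state: _TwofoldState,
    t: int,
    target: str,
    config: ImputationConfig,
    rng: np.random.Generator,
    log: ImputationLog,
    m: int,
) -> None:
    if target == "outcome":
        miss = state.miss_Y[t]
        frame, col, kind = state.Y, t, "continuous"
    elif target == "smoking":
        miss = state.miss_S[t]
        frame, col, kind = state.S, t, "categorical"
    else:  # education
        miss = state.miss_edu
        frame, col, kind = state.cov, "education", "categorical"
    if not miss.any():
        return
    X, names = state.design(t, target, config)
    y_all = frame[col].to_numpy()
    fit_rows, tgt_rows = ~miss, miss
    X_fit, names_kept, dropped = _sparse_trim(X[fit_rows], names)
    if dropped:
        log.add(m, t, target, f"merged sparse predictor levels: {dropped}")
        keep_idx = [names.index(nm) for nm in names_kept]
        X_tgt = X[tgt_rows][:, keep_idx]
    else:
        X_tgt = X[tgt_rows]
    try:
        if kind == "categorical" and X_fit.shape[0] <= X_fit.shape[1] + 2:
            raise ImputationError("too few completers")
        values = draw_univariate_imputation(kind, X_fit, y_all[fit_rows], X_tgt, rng)
    except (np.linalg.LinAlgError, ImputationError, ValueError):
        # ladder step: drop adjacent-phase outcome predictors
        narrow = [i for i, nm in enumerate(names_kept) if not nm.startswith("Y")]
        try:
            values = draw_univariate_imputation(
                kind, X_fit[:, narrow], y_all[fit_rows], X_tgt[:, narrow], rng
            )
            log.add(m, t, target, "dropped adjacent-phase predictors")
        except (np.linalg.LinAlgError, ValueError):
            obs = y_all[fit_rows]
            values = rng.choice(obs, size=int(miss.sum()), replace=True)
            log.add(m, t, target, "marginal draw fallback")
    frame.loc[miss, col] = values


def _reassemble(panel: pd.DataFrame, state: _TwofoldState) -> pd.DataFrame:
    out = panel.copy()
    ylong = state.Y.stack()
    slong = state.S.stack()
    key = pd.MultiIndex.from_frame(out[["participant_id", "phase"]])
    out["outcome"] = ylong.reindex(key).to_numpy()
    out["smoking"] = slong.reindex(key).to_numpy()
    edu = state.cov["education"]
    out["education"] = out["participant_id"].map(edu).to_numpy()
    return out


def impute_twofold_fcs(
    panel: pd.DataFrame,
    config: ImputationConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    return_log: bool = False,
):
    """Run the two-fold FCS algorithm; returns M completed panels.

    Observed values are never modified.  Each imputation runs on its own
    deterministic RNG stream derived from ``seed`` and the imputation
    index, so any single completed panel can be reproduced in isolation.
    """
    config = config or ImputationConfig()
    config.validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(config.M)
    log = ImputationLog()
    completed = []
    any_missing = (
        panel["outcome"].isna().any()
        or panel["smoking"].isna().any()
        or panel["education"].isna().any()
    )
    for m in range(config.M):
        if not any_missing:
            completed.append(panel.copy())
            continue
        rng = np.random.default_rng(children[m])
        state = _TwofoldState(panel)
        state.initialize(rng)
        targets_by_phase = {}
        for t in PHASES:
            targets = []
            if state.miss_Y[t].any():
                targets.append("outcome")
            if state.miss_S[t].any():
                targets.append("smoking")
            if t == 5 and state.miss_edu.any():
                targets.append("education")
            targets_by_phase[t] = targets
        for _ in range(config.b_A):
            for t in PHASES:
                for _ in range(config.b_W):
                    for target in targets_by_phase[t]:
                        _impute_one(state, t, target, config, rng, log, m)
        completed.append(_reassemble(panel, state))
    if return_log:
        return completed, log
    return completed


def apply_pmm(
    completed_panels: list[pd.DataFrame],
    k: float,
    reference_panel: pd.DataFrame,
) -> list[pd.DataFrame]:
    """Pattern-mixture delta adjustment: add exactly ``k`` to every outcome
    value that was imputed (unobserved in ``reference_panel``) and flagged
    non-ignorable (``attrition_flag == 1``); all other cells are untouched.
    """
    flags = reference_panel["attrition_flag"].to_numpy()
    observed = reference_panel["observed_outcome"].to_numpy()
    shift_mask = (flags == 1) & (observed == 0)
    adjusted = []
    for p in completed_panels:
        if len(p) != len(reference_panel) or not (
            p["participant_id"].to_numpy() == reference_panel["participant_id"].to_numpy()
        ).all() or not (p["phase"].to_numpy() == reference_panel["phase"].to_numpy()).all():
            raise ValueError("completed panel rows misaligned with the reference panel")
        q = p.copy()
        q.loc[shift_mask, "outcome"] = q.loc[shift_mask, "outcome"] + k
        adjusted.append(q)
    return adjusted
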