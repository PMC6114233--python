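"""Substantive-model fitting and Rubin's-rules pooling.

The substantive model regresses the standardized cognitive outcome at the
analysis phases (5, 7, 9) on the baseline (phase-5) values of smoking
status, age band, occupational grade and education — each as a main effect
and in interaction with time — with a correlated random intercept and
random time slope per participant (REML).

Available-case behaviour is implicit: records lacking an observed outcome
are dropped row-wise, and participants lacking observed baseline exposure
or covariates are dropped entirely; the mixed model then uses whichever
partial follow-up remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams

from .params import ANALYSIS_PHASES, BASELINE_PHASE, CATEGORY_LABELS

MODEL_VARIABLES = ("smoking", "age_cat", "grade", "education")


class FitFailureError(RuntimeError):
    pass


@dataclass
class FitResult:
    """Fixed-effect estimates from one substantive-model fit (or a pooled
    set of fits)."""

    coefficients: pd.Series
    std_errors: pd.Series
    df: pd.Series  # per-term degrees of freedom; inf => normal quantiles
    vcov: pd.DataFrame
    method_tag: str
    n_used: int
    converged: bool = True
    notes: tuple[str, ...] = ()

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients.index)

    def confint(self, level: float = 0.95) -> pd.DataFrame:
        """Per-term intervals: t quantiles where df is finite (pooled MI
        fits), normal quantiles otherwise."""
        alpha = 1.0 - level
        q = np.where(
            np.isfinite(self.df.to_numpy()),
            stats.t.ppf(1 - alpha / 2, np.clip(self.df.to_numpy(), 1e-3, None)),
            stats.norm.ppf(1 - alpha / 2),
        )
        lo = self.coefficients - q * self.std_errors
        hi = self.coefficients + q * self.std_errors
        return pd.DataFrame({"lower": lo, "upper": hi})

    def adjusted_slopes(self) -> pd.DataFrame:
        """Per-category adjusted 10-year decline: reference slope plus the
        category's time-interaction contrast, with delta-method SEs from the
        coefficient covariance."""
        rows = []
        terms = self.terms
        for var in MODEL_VARIABLES:
            labels = CATEGORY_LABELS[var]
            for level in range(2, len(labels) + 1):
                tname = f"time:{var}[{level}]"
                if tname not in terms:
                    continue
                contrast = pd.Series(0.0, index=terms)
                contrast["time"] = 1.0
                contrast[tname] = 1.0
                est = float(self.coefficients @ contrast)
                se = float(np.sqrt(contrast @ self.vcov @ contrast))
                rows.append(
                    {
                        "variable": var,
                        "level": labels[level - 1],
                        "slope": est,
                        "se": se,
                        "df": float(min(self.df.get("time", np.inf), self.df.get(tname, np.inf))),
                    }
                )
        ref = {
            "variable": "reference",
            "level": "reference",
            "slope": float(self.coefficients["time"]),
            "se": float(self.std_errors["time"]),
            "df": float(self.df.get("time", np.inf)),
        }
        return pd.DataFrame([ref] + rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.coefficients.to_numpy(),
                "se": self.std_errors.to_numpy(),
                "df": self.df.to_numpy(),
                "method_tag": self.method_tag,
            }
        )


def build_analysis_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Analysis-phase records with the baseline exposure attached.

    Keeps rows with an observed outcome from participants whose baseline
    smoking and covariates are all observed (available-case rule)."""
    sub = panel[panel["phase"].isin(ANALYSIS_PHASES)].copy()
    base = panel[panel["phase"] == BASELINE_PHASE].set_index("participant_id")
    sub["baseline_smoking"] = sub["participant_id"].map(base["smoking"])
    row_ok = sub[["baseline_smoking", "age_cat", "grade", "education"]].notna().all(axis=1)
    keep = row_ok.groupby(sub["participant_id"]).transform("all")
    return sub[keep & sub["outcome"].notna()]


def _design(sub: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=sub.index)
    X["Intercept"] = 1.0
    codes = {
        "smoking": sub["baseline_smoking"].astype(int),
        "age_cat": sub["age_cat"].astype(int),
        "grade": sub["grade"].astype(int),
        "education": sub["education"].astype(int),
    }
    for var in MODEL_VARIABLES:
        for level in range(2, len(CATEGORY_LABELS[var]) + 1):
            X[f"{var}[{level}]"] = (codes[var] == level).astype(float)
    X["time"] = sub["time"].to_numpy()
    for var in MODEL_VARIABLES:
        for level in range(2, len(CATEGORY_LABELS[var]) + 1):
            X[f"time:{var}[{level}]"] = X[f"{var}[{level}]"] * X["time"]
    return X


class _ProfiledREML:
    """Exact REML for the random-intercept/random-slope model, profiled over
    fixed effects.

    Because every participant's random-effect design is ``[1, t]`` over a
    handful of shared time points, groups fall into a few observation
    patterns with identical marginal covariance V_p.  Per-pattern sufficient
    statistics (sum of X'X, X'y, y'y blocks) are accumulated once, after
    which each REML objective evaluation costs microseconds regardless of
    the number of participants."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray, times: np.ndarray):
        self.q = X.shape[1]
        order = np.argsort(groups, kind="mergesort")
        X, y, groups, times = X[order], y[order], groups[order], times[order]
        _, start = np.unique(groups, return_index=True)
        bounds = np.append(start, len(y))
        pat: dict[tuple, list[list[int]]] = {}
        for i in range(len(start)):
            rows = np.arange(bounds[i], bounds[i + 1])
            key = tuple(np.round(times[rows], 6))
            pat.setdefault(key, []).append(rows)
        self.patterns = []
        self.n_groups = len(start)
        self.n_obs = len(y)
        for key, rowsets in pat.items():
            k = len(key)
            idx = np.stack(rowsets)  # (n_p, k)
            Xs = X[idx]  # (n_p, k, q)
            ys = y[idx]  # (n_p, k)
            T = np.einsum("nkq,nlr->klqr", Xs, Xs)
            U = np.einsum("nkq,nl->klq", Xs, ys)
            S = np.einsum("nk,nl->kl", ys, ys)
            Z = np.column_stack([np.ones(k), np.asarray(key)])
            self.patterns.append({"n": idx.shape[0], "Z": Z, "T": T, "U": U, "S": S})

    @staticmethod
    def _unpack(theta: np.ndarray) -> tuple[np.ndarray, float]:
        l11, l21, l22, lse = theta
        L = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
        return L @ L.T, np.exp(lse) ** 2

    def _assemble(self, theta: np.ndarray):
        G, s2 = self._unpack(theta)
        q = self.q
        A = np.zeros((q, q))
        Xty = np.zeros(q)
        yty = 0.0
        logdet = 0.0
        for p in self.patterns:
            k = p["Z"].shape[0]
            V = p["Z"] @ G @ p["Z"].T + s2 * np.eye(k)
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                return None
            Vinv = np.linalg.inv(V)
            logdet += p["n"] * ld
            A += np.einsum("kl,klqr->qr", Vinv, p["T"])
            Xty += np.einsum("kl,klq->q", Vinv, p["U"])
            yty += float(np.sum(Vinv * p["S"]))
        return A, Xty, yty, logdet

    def neg2_reml(self, theta: np.ndarray) -> float:
        parts = self._assemble(theta)
        if parts is None:
            return 1e12
        A, Xty, yty, logdet = parts
        sign, ldA = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e12
        try:
            beta = np.linalg.solve(A, Xty)
        except np.linalg.LinAlgError:
            return 1e12
        ypy = yty - Xty @ beta
        if ypy <= 0:
            return 1e12
        return logdet + ldA + ypy

    def solve(self, theta: np.ndarray):
        A, Xty, yty, logdet = self._assemble(theta)
        beta = np.linalg.solve(A, Xty)
        return beta, np.linalg.inv(A)


def _fit_profiled(sub: pd.DataFrame, X: pd.DataFrame):
    from scipy import optimize

    y = sub["outcome"].to_numpy()
    prof = _ProfiledREML(
        X.to_numpy(), y, sub["participant_id"].to_numpy(), sub["time"].to_numpy()
    )
    sd = max(float(np.std(y)), 1e-6)
    starts = [
        np.array([np.log(0.8 * sd), 0.0, np.log(0.1 * sd), np.log(0.5 * sd)]),
        np.array([np.log(0.5 * sd), 0.0, np.log(0.3 * sd), np.log(0.8 * sd)]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(prof.neg2_reml, x0, method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-6, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e11:
            break
    if best.fun >= 1e11:
        raise FitFailureError("profiled REML failed to find an interior optimum")
    beta, cov_beta = prof.solve(best.x)
    G, s2 = _ProfiledREML._unpack(best.x)
    return beta, cov_beta, G, s2, bool(best.success)


def _fit_statsmodels(sub: pd.DataFrame, X: pd.DataFrame):
    y = sub["outcome"].to_numpy()
    groups = sub["participant_id"].to_numpy()
    exog_re = np.column_stack([np.ones(len(sub)), sub["time"].to_numpy()])
    notes: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
        fit = None
        for attempt, method in enumerate(("lbfgs", "powell"), start=1):
            try:
                cand = model.fit(reml=True, method=method)
                if np.all(np.isfinite(cand.bse_fe)):
                    fit = cand
                    if attempt > 1:
                        notes.append(f"optimizer fallback ({method})")
                    break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if fit is None:
            free = MixedLMParams.from_components(
                fe_params=np.ones(X.shape[1]), cov_re=np.eye(2)
            )
            try:
                fit = model.fit(reml=True, free=free, method="lbfgs")
                notes.append("independent random effects fallback")
            except (np.linalg.LinAlgError, ValueError) as exc:
                raise FitFailureError(f"mixed-model fit failed: {exc}") from exc
    q = X.shape[1]
    beta = np.asarray(fit.fe_params)
    cov_beta = np.asarray(fit.cov_params())[:q, :q]
    G = np.asarray(fit.cov_re) * fit.scale
    return beta, cov_beta, G, float(fit.scale), bool(getattr(fit, "converged", True)), notes


def fit_substantive_model(
    panel: pd.DataFrame, method_tag: str = "full", engine: str = "profiled"
) -> FitResult:
    """REML linear mixed model with random intercept and random time slope.

    ``engine='profiled'`` (default) uses the exact pattern-pooled profiled
    REML; ``engine='statsmodels'`` delegates to ``statsmodels.MixedLM``.
    The profiled engine falls back to statsmodels on failure and records the
    fallback in ``notes``."""
    sub = build_analysis_table(panel)
    n_participants = sub["participant_id"].nunique()
    multi = sub.groupby("participant_id").size()
    if (multi >= 2).sum() < 2:
        raise FitFailureError(
            "need at least two participants with two or more observed outcomes"
        )
    X = _design(sub)
    notes: list[str] = []
    # degenerate exact fit (e.g. constant outcome): REML is unbounded, the
    # least-squares solution is already exact
    ols, _, _, _ = np.linalg.lstsq(X.to_numpy(), sub["outcome"].to_numpy(), rcond=None)
    if float(np.var(sub["outcome"].to_numpy() - X.to_numpy() @ ols)) < 1e-14:
        terms = list(X.columns)
        eps = 1e-12
        return FitResult(
            coefficients=pd.Series(ols, index=terms),
            std_errors=pd.Series(np.sqrt(eps), index=terms),
            df=pd.Series(np.inf, index=terms),
            vcov=pd.DataFrame(np.eye(len(terms)) * eps, index=terms, columns=terms),
            method_tag=method_tag,
            n_used=int(n_participants),
            converged=True,
            notes=("degenerate zero-residual fit",),
        )
    if engine == "profiled":
        try:
            beta, cov_beta, G, s2, converged = _fit_profiled(sub, X)
        except (FitFailureError, np.linalg.LinAlgError):
            beta, cov_beta, G, s2, converged, fb_notes = _fit_statsmodels(sub, X)
            notes = ["statsmodels fallback", *fb_notes]
    elif engine == "statsmodels":
        beta, cov_beta, G, s2, converged, notes = _fit_statsmodels(sub, X)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    terms = list(X.columns)
    coeffs = pd.Series(beta, index=terms)
    vcov = pd.DataFrame(cov_beta, index=terms, columns=terms)
    ses = pd.Series(np.sqrt(np.diag(vcov)), index=terms)
    return FitResult(
        coefficients=coeffs,
        std_errors=ses,
        df=pd.Series(np.inf, index=terms),
        vcov=vcov,
        method_tag=method_tag,
        n_used=int(n_participants),
        converged=bool(converged),
        notes=tuple(notes),
    )


def pool_rubin(fits: list[FitResult], method_tag: str = "mi") -> FitResult:
    """Combine M completed-data fits.

    Pooled estimate = mean; total variance T = W + (1 + 1/M) B with W the
    mean squared SE and B the between-fit variance of the estimates;
    degrees of freedom nu = (M-1) (1 + W / ((1+1/M) B))^2 (B = 0 gives
    infinite df, i.e. normal quantiles)."""
    if len(fits) < 2:
        raise ValueError("Rubin pooling needs at least M=2 fits")
    terms = fits[0].terms
    for f in fits[1:]:
        if f.terms != terms:
            raise ValueError("fits have mismatched term sets")
    M = len(fits)
    est = np.stack([f.coefficients.to_numpy() for f in fits])
    ses = np.stack([f.std_errors.to_numpy() for f in fits])
    qbar = est.mean(axis=0)
    W = (ses**2).mean(axis=0)
    B = est.var(axis=0, ddof=1)
    T = W + (1 + 1 / M) * B
    with np.errstate(divide="ignore"):
        nu = np.where(B > 0, (M - 1) * (1 + W / ((1 + 1 / M) * B)) ** 2, np.inf)
    vcov_stack = np.stack([f.vcov.to_numpy() for f in fits]).mean(axis=0)
    Bmat = np.cov(est, rowvar=False, ddof=1).reshape(len(terms), len(terms))
    vcov = pd.DataFrame(
        vcov_stack + (1 + 1 / M) * Bmat, index=terms, columns=terms
    )
    return FitResult(
        coefficients=pd.Series(qbar, index=terms),
        std_errors=pd.Series(np.sqrt(T), index=terms),
        df=pd.Series(nu, index=terms),
        vcov=vcov,
        method_tag=method_tag,
        n_used=fits[0].n_used,
        converged=all(f.converged for f in fits),
        notes=tuple(n for f in fits for n in f.notes),
    )
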