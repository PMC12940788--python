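"""Survival analysis: Kaplan-Meier, log-rank, Cox and LASSO-Cox selection.

Overall survival (months from diagnosis to death or last follow-up) is
modelled with the proportional-hazards family: Kaplan-Meier curves and
log-rank tests for stratified description, univariate Cox screening of
gene mutations with Benjamini-Hochberg correction, and an L1-penalized
Cox model over all clinical, immunophenotype and molecular covariates
with 10-fold cross-validation.  The reported model refits the covariates
selected at the one-standard-error lambda without penalty, which yields
hazard ratios with Wald confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning as LifelinesConvergenceWarning
from lifelines.statistics import multivariate_logrank_test
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "KMResult",
    "CoxFit",
    "LassoCoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_partial_loglik",
    "cox_score",
    "univariate_screen",
    "lasso_cox",
    "build_design",
]

REFERENCE_LEVELS = {"subtype": "G1", "site": "axial", "imp": "IMP1",
                    "sex": "F", "margins": "R0"}


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    times: np.ndarray
    survival: np.ndarray
    median: float        # NaN when S never reaches 0.5
    n: int

    def at(self, t: float) -> float:
        """S(t); carries the last value forward beyond follow-up."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMResult:
    """Product-limit estimator of the survival function.

    The median is the earliest time with S <= 0.5 and is NaN (flagged)
    when the curve never crosses it.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) < 1:
        raise ValueError("at least one subject required")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_.iloc[:, 0]
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    below = surv <= 0.5
    median = float(grid[below][0]) if below.any() else float("nan")
    return KMResult(times=grid, survival=surv, median=median, n=len(times))


def logrank_test(times, events, groups) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square statistic, p).

    Observed-minus-expected event counts over the pooled event times with
    hypergeometric variance, k-1 degrees of freedom.  When no events are
    observed in any group the statistic is 0 and p = 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if events.sum() == 0:
        return 0.0, 1.0
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox partial likelihood (used for diagnostics and cross-validation loss)
# ---------------------------------------------------------------------------

def cox_partial_loglik(X, time, event, beta, ties: str = "efron") -> float:
    """Cox log partial likelihood at ``beta`` (Efron or Breslow ties)."""
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        s_risk = w[at_risk].sum()
        ll += eta[dead].sum()
        if ties == "breslow":
            ll -= d * np.log(s_risk)
        else:
            s_dead = w[dead].sum()
            for l in range(d):
                ll -= np.log(s_risk - (l / d) * s_dead)
    return float(ll)


def cox_score(X, time, event, beta) -> np.ndarray:
    """Gradient of the Efron-tie-corrected log partial likelihood."""
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    beta = np.asarray(beta, dtype=float)
    w = np.exp(X @ beta)
    grad = np.zeros_like(beta)
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        s_risk = w[at_risk].sum()
        sx_risk = (w[at_risk, None] * X[at_risk]).sum(axis=0)
        s_dead = w[dead].sum()
        sx_dead = (w[dead, None] * X[dead]).sum(axis=0)
        grad += X[dead].sum(axis=0)
        for l in range(d):
            frac = l / d
            grad -= (sx_risk - frac * sx_dead) / (s_risk - frac * s_dead)
    return grad


# ---------------------------------------------------------------------------
# Cox fits
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    summary: pd.DataFrame          # coef, hr, se, ci_lower, ci_upper, p per covariate
    loglik: float
    flagged: list = field(default_factory=list)

    @property
    def coefs(self) -> pd.Series:
        return self.summary["coef"]

    @property
    def hr(self) -> pd.Series:
        return self.summary["hr"]


def cox_fit(X: pd.DataFrame, time, event) -> CoxFit:
    """Maximum-partial-likelihood Cox regression (Efron tie handling).

    Wald confidence intervals exp(beta +- 1.96 se).  Perfect separation
    (monotone likelihood) is flagged and the fit retried with a small
    ridge penalty so a capped coefficient is still reported.
    """
    X = pd.DataFrame(X)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    if int(np.asarray(event).sum()) < 1:
        raise ValueError("at least one event required")
    df = X.copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=int)
    flagged = []
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=LifelinesConvergenceWarning)
            cph.fit(df, duration_col="_time", event_col="_event")
    except Exception:
        flagged.append("monotone_likelihood_or_nonconvergence")
        log.warning("Cox fit unstable; refitting with small ridge penalty")
        cph = CoxPHFitter(penalizer=1e-2)
        cph.fit(df, duration_col="_time", event_col="_event")
    # polish to a tighter stationary point than lifelines' default stopping
    # rule (score components below 1e-6)
    beta = cph.params_.to_numpy()
    Xn = X.to_numpy(dtype=float)
    tn = np.asarray(time, dtype=float)
    en = np.asarray(event, dtype=int)
    if not flagged:
        from scipy.optimize import minimize

        res = minimize(
            lambda b: -cox_partial_loglik(Xn, tn, en, b),
            beta,
            jac=lambda b: -cox_score(Xn, tn, en, b),
            method="BFGS",
            options={"gtol": 1e-8, "maxiter": 100},
        )
        if res.success or np.abs(res.jac).max() < 1e-6:
            beta = res.x
    s = cph.summary
    se = s["se(coef)"].to_numpy()
    out = pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "se": se,
            "ci_lower": np.exp(beta - 1.96 * se),
            "ci_upper": np.exp(beta + 1.96 * se),
            "p": s["p"].to_numpy(),
        },
        index=s.index,
    )
    out.index = [i if not isinstance(i, tuple) else i[0] for i in out.index]
    return CoxFit(summary=out, loglik=float(cph.log_likelihood_), flagged=flagged)


def univariate_screen(
    gene_flags: pd.DataFrame, time, event, min_mutated: int = 3
) -> pd.DataFrame:
    """Univariate Cox per gene-mutation flag with BH-adjusted FDR.

    Genes mutated in fewer than ``min_mutated`` patients (or constant)
    are excluded.  Returns one row per tested gene.
    """
    rows = []
    for g in gene_flags.columns:
        flag = gene_flags[g].astype(int)
        if flag.nunique() < 2 or flag.sum() < min_mutated:
            continue
        fit = cox_fit(flag.to_frame(g), time, event)
        r = fit.summary.loc[g]
        rows.append({"gene": g, "hr": r["hr"], "coef": r["coef"],
                     "ci_lower": r["ci_lower"], "ci_upper": r["ci_upper"],
                     "p": r["p"]})
    out = pd.DataFrame(rows)
    if not len(out):
        log.info("no gene passed the prevalence floor for univariate screening")
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("q").reset_index(drop=True)


# ---------------------------------------------------------------------------
# LASSO-Cox with cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LassoCoxResult:
    alphas: np.ndarray             # lambda path, decreasing
    coef_path: pd.DataFrame        # covariate x lambda (original scale)
    cv_mean: np.ndarray            # CV partial-likelihood deviance per lambda
    cv_se: np.ndarray
    alpha_min: float
    alpha_1se: float
    selected: list
    refit: CoxFit | None           # unpenalized refit on the selected set


def _fold_assignment(event, folds, rng):
    """Fold labels stratified by event status."""
    event = np.asarray(event, dtype=int)
    labels = np.empty(len(event), dtype=int)
    for val in (0, 1):
        idx = np.flatnonzero(event == val)
        rng.shuffle(idx)
        labels[idx] = np.arange(len(idx)) % folds
    return labels


def lasso_cox(
    X: pd.DataFrame,
    time,
    event,
    folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.01,
) -> LassoCoxResult:
    """L1-penalized Cox over a 100-step lambda path with K-fold CV.

    Covariates are standardized internally for the penalty; reported
    coefficients are on the original scale.  The CV loss is the
    Verweij-van Houwelingen cross-validated partial-likelihood deviance
    -2 (pl_all(beta_{-k}) - pl_{-k}(beta_{-k})).  lambda_1se is the
    largest lambda whose CV loss is within one standard error of the
    minimum; the final model refits the covariates with nonzero
    coefficients at lambda_1se by unpenalized Cox regression.
    """
    X = pd.DataFrame(X).astype(float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n_events = int(event.sum())
    if n_events < folds:
        log.warning("only %d events; reducing folds from %d", n_events, folds)
        folds = max(n_events, 2)
    mean, sd = X.mean(), X.std(ddof=0).replace(0.0, 1.0)
    Xs = ((X - mean) / sd).to_numpy()
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio,
        fit_baseline_model=False,
    )
    path.fit(Xs, y)
    alphas = np.asarray(path.alphas_)
    coef_std = np.asarray(path.coef_)  # p x n_alphas

    rng = np.random.default_rng(seed)
    fold_of = _fold_assignment(event, folds, rng)
    dev = np.zeros((folds, len(alphas)))
    for k in range(folds):
        train = fold_of != k
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(Xs[train], Surv.from_arrays(event=event[train].astype(bool),
                                              time=time[train]))
        fold_alphas = list(np.asarray(m.alphas_))
        cf = np.asarray(m.coef_)
        for j, a in enumerate(alphas):
            jj = fold_alphas.index(a) if a in fold_alphas else min(
                range(len(fold_alphas)), key=lambda q: abs(fold_alphas[q] - a)
            )
            b = cf[:, jj]
            pl_all = cox_partial_loglik(Xs, time, event, b, ties="breslow")
            pl_train = cox_partial_loglik(Xs[train], time[train], event[train], b,
                                          ties="breslow")
            dev[k, j] = -2.0 * (pl_all - pl_train)
    cv_mean = dev.sum(axis=0)
    cv_se = dev.std(axis=0, ddof=1) * np.sqrt(folds)
    i_min = int(np.argmin(cv_mean))
    thresh = cv_mean[i_min] + cv_se[i_min]
    i_1se = next(i for i in range(len(alphas)) if cv_mean[i] <= thresh)
    alpha_1se = float(alphas[i_1se])
    selected = [c for c, b in zip(X.columns, coef_std[:, i_1se]) if b != 0.0]

    coef_path = pd.DataFrame(
        coef_std / sd.to_numpy()[:, None], index=X.columns,
        columns=[f"{a:.6g}" for a in alphas],
    )
    refit = None
    if selected:
        refit = cox_fit(X[selected], time, event)
    else:
        log.info("lambda_1se selected the empty model; no refit")
    return LassoCoxResult(
        alphas=alphas, coef_path=coef_path, cv_mean=cv_mean, cv_se=cv_se,
        alpha_min=float(alphas[i_min]), alpha_1se=alpha_1se,
        selected=selected, refit=refit,
    )


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design(
    clinical: pd.DataFrame,
    imp: pd.Series | None = None,
    gene_columns: list | None = None,
    include: tuple = ("age", "size_cm", "subtype", "site", "margins", "imp"),
) -> pd.DataFrame:
    """Reference-coded covariate matrix for survival modelling.

    Categorical covariates are expanded to indicators against the
    reference levels G1 (subtype), axial (site), R0 (margins) and IMP1.
    ``imp`` overrides/provides the immunophenotype assignment; gene flag
    columns (0/1) are appended as-is.
    """
    df = clinical.set_index("sample") if "sample" in clinical.columns else clinical.copy()
    out = pd.DataFrame(index=df.index)
    work = df.copy()
    if imp is not None:
        work["imp"] = pd.Series(imp).reindex(work.index)
    elif "imp" not in work.columns and "imp_true" in work.columns:
        work["imp"] = work["imp_true"]
    for col in include:
        if col not in work.columns:
            continue
        if work[col].dtype.kind in "ifb":
            out[col] = work[col].astype(float)
        else:
            ref = REFERENCE_LEVELS.get(col)
            for level in sorted(work[col].dropna().unique()):
                if level == ref:
                    continue
                out[f"{col}_{level}"] = (work[col] == level).astype(float)
    for g in gene_columns or []:
        out[g] = df[g].astype(float)
    return out
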