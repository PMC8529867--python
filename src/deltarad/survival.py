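"""Survival modelling: LASSO-Cox feature selection, multivariate Cox fits
with dichotomized clinical covariates, and Kaplan-Meier cutoff stratification.

The selection step fits an L1-penalised Cox partial likelihood over a
log-spaced penalty grid and picks the penalty minimising the mean 10-fold
cross-validated partial-likelihood deviance (lambda-min); among the
surviving features the one with the largest absolute standardized
coefficient is the "best" univariate marker.  Multivariate Cox models use
Breslow tie handling and Wald confidence intervals.  Kaplan-Meier analysis
splits patients at a cutoff ("above" is strictly greater; boundary values
fall in the low group) and compares the groups with a two-sided log-rank
test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import aggregate

OS = "OS"
PFS = "PFS"

#: Clinical dichotomization cutoffs: LDH above 1.5x the upper limit of
#: normal, LDH percentage change above 20%, three or more metastatic sites.
LDH_ULN_FACTOR = 1.5
PERC_LDH_CUTOFF = 20.0
SITES_CUTOFF = 3


class SurvivalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------


def dichotomize(
    ldh_pre: float,
    ldh_post: float,
    n_sites: int,
    uln: float,
    convention: str = aggregate.AS_PRINTED,
) -> dict:
    """Dichotomize the clinical covariates at the published cutoffs.

    ``ldh_high`` is LDH strictly above 1.5x ULN; ``perc_ldh_high`` is the
    LDH percentage change strictly above 20; ``sites_high`` is three or
    more metastatic sites.  Values exactly at a continuous cutoff fall in
    the low group.
    """
    if uln is None or not np.isfinite(uln) or uln <= 0:
        raise SurvivalError("a positive LDH upper limit of normal (ULN) is required")
    perc_ldh = aggregate.percentage_change(ldh_pre, ldh_post, convention=convention)
    return {
        "perc_ldh": perc_ldh,
        "ldh_high": bool(ldh_pre > LDH_ULN_FACTOR * uln),
        "perc_ldh_high": bool(perc_ldh > PERC_LDH_CUTOFF),
        "sites_high": bool(n_sites >= SITES_CUTOFF),
    }


def add_clinical_flags(
    table: pd.DataFrame, uln: float, convention: str = aggregate.AS_PRINTED
) -> pd.DataFrame:
    """Vectorised :func:`dichotomize` over a patient table (returns a copy)."""
    out = table.copy()
    flags = [
        dichotomize(r.ldh_pre, r.ldh_post, r.n_sites, uln, convention)
        for r in table.itertuples()
    ]
    for key in ("perc_ldh", "ldh_high", "perc_ldh_high", "sites_high"):
        out[key] = [f[key] for f in flags]
    for key in ("ldh_high", "perc_ldh_high", "sites_high"):
        out[key] = out[key].astype(int)
    return out


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow) -- used for CV deviance and as an oracle
# ---------------------------------------------------------------------------


def cox_partial_loglik(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow partial log-likelihood of coefficients ``beta``."""
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    lp = X @ beta
    order = np.argsort(time, kind="stable")
    t, lp_s, ev = time[order], lp[order], event[order]
    shift = lp_s.max()
    # log sum_{j: t_j >= t_i} exp(lp_j), shared across tied times
    rev = np.logaddexp.accumulate((lp_s - shift)[::-1])[::-1] + shift
    denom = rev[np.searchsorted(t, t, side="left")]
    return float(np.sum(lp_s[ev] - denom[ev]))


def _stratified_folds(
    event: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold labels stratified by event status, dealt round-robin after a shuffle."""
    folds = np.empty(len(event), dtype=int)
    for value in (True, False):
        idx = np.flatnonzero(event == value)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


# ---------------------------------------------------------------------------
# LASSO-Cox selection
# ---------------------------------------------------------------------------


@dataclass
class LassoSelection:
    """Outcome of the penalised selection step.

    Coefficients are on the standardized-feature scale; ``selected`` are
    the features with nonzero coefficients at the chosen penalty and
    ``best_feature`` the one largest in absolute value (None if the model
    is empty).
    """

    lambda_grid: np.ndarray
    chosen_lambda: float
    coefficients: pd.Series
    selected: tuple[str, ...]
    best_feature: str | None
    cv_deviance: np.ndarray
    coef_path: pd.DataFrame
    n_used: int
    n_events: int
    n_dropped_rows: int
    dropped_features: tuple[str, ...]
    k_folds: int
    seed: int


def lasso_cox_select(
    features: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[bool],
    k_folds: int = 10,
    seed: int = 0,
    alphas: Sequence[float] | None = None,
    n_alphas: int = 50,
) -> LassoSelection:
    """L1-penalised Cox selection with seeded, event-stratified k-fold CV.

    Rows with missing feature values are dropped (and counted); features
    with zero variance are dropped with a warning.  Features are
    standardized internally, the penalty grid is taken from the full-data
    path unless ``alphas`` is supplied, and the chosen penalty minimises
    the mean out-of-fold partial-likelihood deviance.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    X = features.astype(float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)

    dropped_features = tuple(c for c in X.columns if X[c].isna().all())
    X = X.drop(columns=list(dropped_features))
    keep_rows = ~X.isna().any(axis=1)
    n_dropped_rows = int((~keep_rows).sum())
    X, time, event = X.loc[keep_rows], time[keep_rows.to_numpy()], event[keep_rows.to_numpy()]

    if event.sum() < 2:
        raise SurvivalError("need at least 2 events for LASSO-Cox selection")
    constant = tuple(c for c in X.columns if X[c].std(ddof=0) == 0)
    if constant:
        warnings.warn(f"dropping zero-variance features: {constant}", stacklevel=2)
        dropped_features = dropped_features + constant
        X = X.drop(columns=list(constant))
    if X.shape[1] == 0:
        raise SurvivalError("no usable features remain after dropping")

    Xs = (X - X.mean()) / X.std(ddof=0)
    Xa = Xs.to_numpy()
    y = Surv.from_arrays(event=event, time=time)

    def fit_path(rows: np.ndarray, grid: Sequence[float] | None):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            alphas=None if grid is None else list(grid),
            n_alphas=n_alphas,
            alpha_min_ratio=0.01,
            max_iter=100000,
            normalize=False,
            fit_baseline_model=False,
        )
        with warnings.catch_warnings():
            # a fold can zero out every coefficient at the top of the grid;
            # that is a legitimate path point, not a user error
            warnings.filterwarnings("ignore", message="all coefficients are zero")
            model.fit(Xa[rows], y[rows])
        return model

    full = fit_path(np.arange(len(Xs)), alphas)
    grid = np.asarray(full.alphas_)

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(event, k_folds, rng)
    deviance = np.zeros((k_folds, len(grid)))
    for k in range(k_folds):
        train, test = folds != k, folds == k
        if event[train].sum() < 2 or not test.any():
            deviance[k] = np.nan
            continue
        fold_model = fit_path(np.flatnonzero(train), grid)
        coefs = fold_model.coef_  # (p, n_converged_alphas)
        # the solver may drop alphas it could not converge for; align to grid
        fold_alphas = {float(a): i for i, a in enumerate(fold_model.alphas_)}
        deviance[k] = np.nan
        for a, alpha in enumerate(grid):
            i = fold_alphas.get(float(alpha))
            if i is None:
                continue
            deviance[k, a] = -2.0 * cox_partial_loglik(
                coefs[:, i], Xa[test], time[test], event[test]
            )
    mean_dev = np.nanmean(deviance, axis=0)
    best_idx = int(np.nanargmin(mean_dev))
    chosen = float(grid[best_idx])

    coef = pd.Series(full.coef_[:, best_idx], index=Xs.columns)
    selected = tuple(coef.index[coef != 0])
    best = coef.abs().idxmax() if selected else None
    return LassoSelection(
        lambda_grid=grid,
        chosen_lambda=chosen,
        coefficients=coef,
        selected=selected,
        best_feature=best,
        cv_deviance=mean_dev,
        coef_path=pd.DataFrame(full.coef_, index=Xs.columns, columns=grid),
        n_used=len(Xs),
        n_events=int(event.sum()),
        n_dropped_rows=n_dropped_rows,
        dropped_features=dropped_features,
        k_folds=k_folds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Multivariate Cox
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``summary`` has one row per covariate with columns
    ``coef, se, hr, ci_low, ci_high, p`` (hazard ratios per unit of the
    covariate; Wald 95% intervals).
    """

    summary: pd.DataFrame
    n: int
    n_events: int
    model_id: str = ""
    converged: bool = True
    notes: tuple[str, ...] = field(default_factory=tuple)

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(
    design: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[bool],
    model_id: str = "",
    drop_constant: bool = False,
) -> CoxFit:
    """Maximum partial-likelihood Cox fit with Breslow tie handling.

    Perfect separation / non-convergence is flagged on the result instead
    of raising; constant covariates raise unless ``drop_constant``.
    """
    from statsmodels.duration.hazard_regression import PHReg

    X = design.astype(float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 2:
        raise SurvivalError("need at least 2 events for a Cox fit")
    if X.isna().any().any():
        raise SurvivalError("Cox design matrix contains missing values")

    notes: list[str] = []
    constant = [c for c in X.columns if X[c].std(ddof=0) == 0]
    if constant:
        if not drop_constant:
            raise SurvivalError(f"constant covariates in design: {constant}")
        notes.append(f"dropped constant covariates: {constant}")
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise SurvivalError("empty design matrix")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = PHReg(time, X.to_numpy(), status=event, ties="breslow")
            result = model.fit(disp=False)
        coef = np.asarray(result.params, dtype=float)
        se = np.asarray(result.bse, dtype=float)
    except (np.linalg.LinAlgError, ValueError) as exc:
        # singular information matrix / optimizer failure: flag, don't crash
        notes.append(f"Cox fit failed numerically: {exc}")
        coef = np.full(X.shape[1], np.nan)
        se = np.full(X.shape[1], np.nan)
    converged = bool(np.all(np.isfinite(coef)) and np.all(np.isfinite(se)))
    if converged and (np.any(np.abs(coef) > 25) or np.any(se > 100)):
        converged = False
        notes.append("possible monotone likelihood / separation: huge coefficient or SE")
    z = np.divide(coef, se, out=np.full_like(coef, np.nan), where=se > 0)
    from scipy import stats as sps

    p = 2.0 * sps.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):
        summary = pd.DataFrame(
            {
                "coef": coef,
                "se": se,
                "hr": np.exp(coef),
                "ci_low": np.exp(coef - 1.96 * se),
                "ci_high": np.exp(coef + 1.96 * se),
                "p": p,
            },
            index=X.columns,
        )
    return CoxFit(
        summary=summary,
        n=len(X),
        n_events=int(event.sum()),
        model_id=model_id,
        converged=converged,
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMResult:
    """Two-group Kaplan-Meier comparison at a cutoff.

    Medians are the first times the product-limit estimate drops to <= 0.5;
    NaN means the curve never crosses 0.5 (median not reached).
    """

    cutoff: float
    cutoff_mode: str
    n_above: int
    n_below: int
    median_above: float
    median_below: float
    logrank_statistic: float
    p_value: float
    above: np.ndarray  # boolean group assignment, True = strictly above cutoff


def km_median(time: Sequence[float], event: Sequence[bool]) -> float:
    """KM median survival of one group (NaN if not reached)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    med = kmf.median_survival_time_
    return float(med) if np.isfinite(med) else math.nan


def km_split(
    values: Sequence[float],
    time: Sequence[float],
    event: Sequence[bool],
    cutoff: float | str = "median",
) -> KMResult:
    """Split patients at a cutoff and compare survival with a log-rank test.

    ``cutoff`` is either the string ``"median"`` (median of ``values``) or a
    fixed number.  The high group is strictly above the cutoff.
    """
    from lifelines.statistics import logrank_test

    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.isnan(values).any():
        raise SurvivalError("cutoff variable contains missing values")
    if isinstance(cutoff, str):
        if cutoff != "median":
            raise SurvivalError(f"unknown cutoff mode {cutoff!r}")
        cut, mode = float(np.median(values)), "median"
    else:
        cut, mode = float(cutoff), "fixed"
    above = values > cut
    if above.all() or not above.any():
        raise SurvivalError(
            f"one-sided split at cutoff {cut:g} (all patients on one side); "
            "consider a fixed cutoff"
        )
    lr = logrank_test(
        time[above], time[~above], event_observed_A=event[above], event_observed_B=event[~above]
    )
    return KMResult(
        cutoff=cut,
        cutoff_mode=mode,
        n_above=int(above.sum()),
        n_below=int((~above).sum()),
        median_above=km_median(time[above], event[above]),
        median_below=km_median(time[~above], event[~above]),
        logrank_statistic=float(lr.test_statistic),
        p_value=float(lr.p_value),
        above=above,
    )


def plot_km(
    values: Sequence[float],
    time: Sequence[float],
    event: Sequence[bool],
    cutoff: float | str = "median",
    label: str = "feature",
    ax=None,
):
    """Plot the two KM curves of a cutoff split (optional reporting helper)."""
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    result = km_split(values, time, event, cutoff)
    if ax is None:
        _, ax = plt.subplots()
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    for name, sel in (("above", result.above), ("below/equal", ~result.above)):
        KaplanMeierFitter().fit(
            time[sel], event[sel], label=f"{label} {name} {result.cutoff:.3g}"
        ).plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_title(f"log-rank p = {result.p_value:.3g}")
    return ax


# ---------------------------------------------------------------------------
# Per-endpoint orchestration
# ---------------------------------------------------------------------------


@dataclass
class EndpointReport:
    """Everything the analysis produces for one endpoint (OS or PFS)."""

    endpoint: str
    lasso_baseline: LassoSelection
    lasso_delta: LassoSelection
    cox_fits: dict[str, CoxFit]
    km_results: dict[str, KMResult]
    n_patients: int
    n_events: int
    notes: tuple[str, ...] = field(default_factory=tuple)


def _endpoint_columns(endpoint: str) -> tuple[str, str]:
    if endpoint == OS:
        return "os_months", "os_event"
    if endpoint == PFS:
        return "pfs_months", "pfs_event"
    raise SurvivalError(f"unknown endpoint {endpoint!r}; expected OS or PFS")


def run_endpoint_analysis(
    patient_table: pd.DataFrame,
    endpoint: str,
    uln: float = 450.0,
    k_folds: int = 10,
    seed: int = 0,
    sign_convention: str = aggregate.AS_PRINTED,
    fixed_cutoffs: Mapping[str, float] | None = None,
    report_markers_baseline: Sequence[str] = ("kurtosis_ssf2", "kurtosis_ssf3"),
    report_markers_delta: Sequence[str] = ("perc_entropy_ssf4", "perc_entropy_ssf6"),
    min_events: int = 5,
) -> EndpointReport:
    """Full single-endpoint analysis.

    Steps: (1) LASSO-Cox over baseline texture features, (2) LASSO-Cox over
    delta features, (3) a multivariate Cox model per marker with its
    clinical template — ``{marker, ldh_high, sites_high}`` for baseline
    markers, ``{marker, sites_high, perc_ldh_high}`` for delta markers —
    and (4) KM analysis at the median cutoff plus any configured fixed
    cutoff.  Markers are the LASSO best features plus the explicitly
    requested report markers.
    """
    time_col, event_col = _endpoint_columns(endpoint)
    for col in (time_col, event_col):
        if col not in patient_table.columns:
            raise SurvivalError(f"patient table lacks required column {col!r}")
    table = add_clinical_flags(patient_table, uln=uln, convention=sign_convention)
    time = table[time_col].to_numpy(dtype=float)
    event = table[event_col].to_numpy(dtype=bool)
    if event.sum() < min_events:
        raise SurvivalError(
            f"insufficient events for {endpoint}: {int(event.sum())} < {min_events}"
        )

    from .texture import BASELINE_FEATURES, DELTA_FEATURES

    baseline_cols = [c for c in BASELINE_FEATURES if c in table.columns]
    delta_cols = [c for c in DELTA_FEATURES if c in table.columns]
    if not baseline_cols or not delta_cols:
        raise SurvivalError("patient table lacks baseline and/or delta feature columns")

    lasso_baseline = lasso_cox_select(
        table[baseline_cols], time, event, k_folds=k_folds, seed=seed
    )
    lasso_delta = lasso_cox_select(
        table[delta_cols], time, event, k_folds=k_folds, seed=seed + 1
    )

    notes: list[str] = []
    cox_fits: dict[str, CoxFit] = {}
    km_results: dict[str, KMResult] = {}
    fixed_cutoffs = dict(fixed_cutoffs or {})

    def analyse_marker(marker: str, family: str) -> None:
        if marker in cox_fits or marker not in table.columns:
            return
        values = table[marker]
        if values.isna().any():
            notes.append(f"{marker}: missing values, marker skipped")
            return
        clinical = (
            ["ldh_high", "sites_high"] if family == "baseline" else ["sites_high", "perc_ldh_high"]
        )
        design = table[[marker] + clinical]
        try:
            cox_fits[marker] = cox_fit(
                design, time, event, model_id=f"{endpoint}:{marker}", drop_constant=True
            )
        except SurvivalError as exc:
            notes.append(f"{marker}: Cox fit failed ({exc})")
            return
        for mode_name, cut in (("median", "median"), ("fixed", fixed_cutoffs.get(marker))):
            if cut is None:
                continue
            try:
                km_results[f"{marker}@{mode_name}"] = km_split(values, time, event, cut)
            except SurvivalError as exc:
                notes.append(f"{marker} KM {mode_name}: {exc}")

    baseline_markers = [m for m in [lasso_baseline.best_feature] if m] + list(
        report_markers_baseline
    )
    delta_markers = [m for m in [lasso_delta.best_feature] if m] + list(report_markers_delta)
    for marker in baseline_markers:
        analyse_marker(marker, "baseline")
    for marker in delta_markers:
        analyse_marker(marker, "delta")

    return EndpointReport(
        endpoint=endpoint,
        lasso_baseline=lasso_baseline,
        lasso_delta=lasso_delta,
        cox_fits=cox_fits,
        km_results=km_results,
        n_patients=len(table),
        n_events=int(event.sum()),
        notes=tuple(notes),
    )


def cox_table(report: EndpointReport) -> pd.DataFrame:
    """Long-format multivariate Cox table (one row per model x covariate)."""
    rows = []
    for marker, fit in report.cox_fits.items():
        for covariate, r in fit.summary.iterrows():
            rows.append(
                {
                    "endpoint": report.endpoint,
                    "model": marker,
                    "covariate": covariate,
                    "hr": r["hr"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "p": r["p"],
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def km_table(report: EndpointReport) -> pd.DataFrame:
    """KM stratification table (one row per marker x cutoff mode)."""
    rows = []
    for key, km in report.km_results.items():
        marker, mode = key.split("@")
        rows.append(
            {
                "endpoint": report.endpoint,
                "feature": marker,
                "cutoff_mode": mode,
                "cutoff": km.cutoff,
                "n_above": km.n_above,
                "n_below": km.n_below,
                "median_above": km.median_above,
                "median_below": km.median_below,
                "logrank_p": km.p_value,
            }
        )
    return pd.DataFrame(rows)
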