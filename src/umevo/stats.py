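"""Cohort statistics: association scans, survival analysis, matching, power.

The test-selection rule, endpoints and conventions follow the analysis plan
this package models: chi-square for categorical contrasts unless at least
25% of cells have expected counts below 5 (then Fisher exact), two-tailed
rank-sum for continuous contrasts, Kaplan-Meier/log-rank for survival
differences, uni-/multivariable Cox regression (Efron ties), 3:1 propensity
matching on tumor thickness and diameter, survival probabilities at
specified time points for continuous covariates, and a Monte-Carlo
log-rank power simulation cross-checked against the Schoenfeld closed form.
All p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from sklearn.linear_model import LogisticRegression


class CoxConvergenceError(RuntimeError):
    """Cox partial-likelihood fit failed (separation or singular design)."""


# ---------------------------------------------------------------------------
# contingency tests
# ---------------------------------------------------------------------------

def expected_counts(table: np.ndarray) -> np.ndarray:
    """Expected cell counts under independence of the margins."""
    t = np.asarray(table, dtype=float)
    total = t.sum()
    if total == 0:
        raise ValueError("contingency table has zero grand total")
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / total


def select_test(table: np.ndarray, small_cell: float = 5.0,
                fraction: float = 0.25) -> str:
    """'fisher' when >= ``fraction`` of cells expect < ``small_cell`` counts
    under the independence margins, else 'chi_square'."""
    exp = expected_counts(table)
    return "fisher" if np.mean(exp < small_cell) >= fraction else "chi_square"


def categorical_test(table: np.ndarray, seed: int | None = None,
                     n_mc: int = 20000) -> tuple[str, float, float]:
    """Apply the switching rule and run the selected test.

    Returns (test_used, statistic, two-sided p).  Fisher on r x c tables
    larger than 2 x 2 uses a seeded Monte-Carlo conditional test (Patefield
    sampling of tables with fixed margins, chi-square ordering statistic).
    """
    t = np.asarray(table, dtype=int)
    test = select_test(t)
    if test == "chi_square":
        stat, p, _, _ = sps.chi2_contingency(t, correction=False)
        return test, float(stat), float(p)
    if t.shape == (2, 2):
        stat, p = sps.fisher_exact(t, alternative="two-sided")
        return test, float(stat), float(p)
    # r x c exact test approximated by conditional Monte Carlo
    rng = np.random.default_rng(seed)
    obs_stat = _chi2_stat(t)
    sampler = sps.random_table(t.sum(axis=1), t.sum(axis=0))
    draws = sampler.rvs(n_mc, random_state=rng)
    sim = np.array([_chi2_stat(d) for d in draws])
    p = (1.0 + np.sum(sim >= obs_stat - 1e-12)) / (n_mc + 1.0)
    return test, float(obs_stat), float(p)


def _chi2_stat(t: np.ndarray) -> float:
    exp = expected_counts(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(exp > 0, (t - exp) ** 2 / exp, 0.0)
    return float(contrib.sum())


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    variable: str
    mutation: str
    test_used: str | None
    statistic: float | None
    p_value: float | None
    untestable: bool = False
    reason: str | None = None


def association_scan(df: pd.DataFrame, mutation_col: str,
                     variables: dict[str, str],
                     seed: int | None = None) -> list[AssociationResult]:
    """Compare carriers vs non-carriers of one mutation across variables.

    ``variables`` maps column name -> 'categorical' | 'continuous'.
    Categorical variables go through the chi-square/Fisher switching rule;
    continuous ones through the two-tailed rank-sum test.  Constant inputs
    (including a mutation present in all or no samples) are flagged
    untestable rather than raising.
    """
    flags = df[mutation_col].astype(bool)
    results: list[AssociationResult] = []
    if flags.nunique() < 2:
        return [AssociationResult(v, mutation_col, None, None, None, True,
                                  "mutation status constant")
                for v in variables]
    for var, kind in variables.items():
        col = df[var]
        if col.dropna().nunique() < 2:
            results.append(AssociationResult(var, mutation_col, None, None,
                                             None, True, "variable constant"))
            continue
        ok = col.notna()
        if kind == "categorical":
            table = pd.crosstab(flags[ok], col[ok]).to_numpy()
            test, stat, p = categorical_test(table, seed=seed)
        elif kind == "continuous":
            a = col[ok & flags].to_numpy(dtype=float)
            b = col[ok & ~flags].to_numpy(dtype=float)
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            test = "wilcoxon"
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
        results.append(AssociationResult(var, mutation_col, test,
                                         float(stat), float(p)))
    return results


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

def km_logrank(df: pd.DataFrame, time_col: str, event_col: str,
               group_col: str) -> dict:
    """Product-limit curves per group plus the two-sided log-rank test.

    With a single group or zero events the curves are still returned and the
    test is flagged undefined.
    """
    curves: dict[str, pd.DataFrame] = {}
    for g, sub in df.groupby(group_col):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], event_observed=sub[event_col].astype(bool),
                label=str(g))
        curves[str(g)] = kmf.survival_function_
    n_groups = df[group_col].nunique()
    total_events = int(df[event_col].astype(bool).sum())
    if n_groups < 2 or total_events == 0:
        return {"curves": curves, "logrank_p": None, "test_defined": False}
    res = multivariate_logrank_test(df[time_col], df[group_col],
                                    df[event_col].astype(bool))
    return {"curves": curves, "logrank_p": float(res.p_value),
            "statistic": float(res.test_statistic), "test_defined": True}


def logrank_two_group(time: np.ndarray, event: np.ndarray,
                      group: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank chi-square and p, vectorised in numpy.

    Used by the power simulation (thousands of replicates); agreement with
    lifelines' logrank_test is asserted in the test suite.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=int)
    et = np.unique(time[event])
    if len(et) == 0:
        return np.nan, np.nan
    t_all = np.sort(time)
    t_g1 = np.sort(time[group == 1])
    n_at_risk = len(time) - np.searchsorted(t_all, et, side="left")
    n1_at_risk = len(t_g1) - np.searchsorted(t_g1, et, side="left")
    # events per unique time, overall and in group 1
    ev_times = time[event]
    ev_g = group[event]
    idx = np.searchsorted(et, ev_times)
    d = np.bincount(idx, minlength=len(et)).astype(float)
    d1 = np.bincount(idx, weights=(ev_g == 1), minlength=len(et))
    frac = n1_at_risk / n_at_risk
    o_minus_e = d1.sum() - (d * frac).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = np.where(
            n_at_risk > 1,
            d * frac * (1.0 - frac) * (n_at_risk - d) / (n_at_risk - 1.0),
            0.0)
    v = var_terms.sum()
    if v <= 0:
        return np.nan, np.nan
    chi2 = o_minus_e ** 2 / v
    return float(chi2), float(sps.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxResult:
    endpoint: str
    covariates: tuple[str, ...]
    hazard_ratios: dict[str, float]
    p_values: dict[str, float]
    confidence_intervals: dict[str, tuple[float, float]]
    model_type: str
    n: int
    n_events: int


def cox_fit(df: pd.DataFrame, covariates: list[str], time_col: str,
            event_col: str, endpoint: str = "MFS") -> CoxResult:
    """Cox proportional-hazards fit (Efron tie handling, Wald two-sided p).

    Raises :class:`CoxConvergenceError` on separation or a singular design
    (e.g. duplicated covariate columns) rather than returning silently
    wrong estimates.  Warns when events < 5 per covariate.
    """
    data = df[covariates + [time_col, event_col]].dropna().copy()
    for c in covariates:
        if data[c].nunique() < 2:
            raise CoxConvergenceError(f"covariate {c!r} is constant")
    corr = data[covariates].astype(float).corr().to_numpy()
    off_diag = corr[~np.eye(len(covariates), dtype=bool)]
    if len(off_diag) and np.any(np.abs(off_diag) > 1.0 - 1e-10):
        raise CoxConvergenceError("singular design: collinear covariates")
    n_events = int(data[event_col].astype(bool).sum())
    if n_events < 5 * len(covariates):
        warnings.warn(
            f"only {n_events} events for {len(covariates)} covariates; "
            "hazard ratios may be unstable", UserWarning, stacklevel=2)
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(data, duration_col=time_col, event_col=event_col)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        raise CoxConvergenceError(f"Cox fit failed: {exc}") from exc
    summary = fitter.summary
    return CoxResult(
        endpoint=endpoint, covariates=tuple(covariates),
        hazard_ratios={c: float(summary.loc[c, "exp(coef)"])
                       for c in covariates},
        p_values={c: float(summary.loc[c, "p"]) for c in covariates},
        confidence_intervals={
            c: (float(summary.loc[c, "exp(coef) lower 95%"]),
                float(summary.loc[c, "exp(coef) upper 95%"]))
            for c in covariates},
        model_type="univariate" if len(covariates) == 1 else "multivariate",
        n=len(data), n_events=n_events)


# ---------------------------------------------------------------------------
# propensity matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    matched_controls: pd.DataFrame
    case_ids: list
    control_ids_per_case: dict
    smd_before: dict[str, float]
    smd_after: dict[str, float]
    partial: bool
    ratio: int


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled)


def propensity_match(cases: pd.DataFrame, controls: pd.DataFrame,
                     match_vars: list[str] | None = None, ratio: int = 3,
                     caliper_sd: float = 0.2,
                     id_col: str = "sample_id") -> MatchResult:
    """Greedy nearest-neighbour propensity matching without replacement.

    The propensity is the fitted probability of case status given
    ``match_vars`` (default: tumor thickness and diameter).  Controls are
    taken within a caliper of ``caliper_sd`` x SD of the logit propensity;
    a case that cannot fill its quota marks the match partial.
    """
    match_vars = match_vars or ["thickness_mm", "diameter_mm"]
    if len(controls) < ratio * len(cases):
        raise ValueError("need at least ratio x n_cases eligible controls")
    pool = pd.concat([cases.assign(_case=1), controls.assign(_case=0)],
                     ignore_index=True)
    X = pool[match_vars].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    model = LogisticRegression(max_iter=1000)
    model.fit(X, pool["_case"])
    p = model.predict_proba(X)[:, 1].clip(1e-12, 1 - 1e-12)
    logit = np.log(p / (1 - p))
    pool = pool.assign(_logit=logit)
    case_rows = pool[pool["_case"] == 1]
    ctrl_rows = pool[pool["_case"] == 0].copy()
    caliper = caliper_sd * float(np.std(logit, ddof=1))

    used: set = set()
    assignment: dict = {}
    partial = False
    # match best-resolved cases first (highest propensity = hardest to match)
    for _, crow in case_rows.sort_values("_logit", ascending=False).iterrows():
        dist = (ctrl_rows["_logit"] - crow["_logit"]).abs()
        order = dist.sort_values().index
        picked = []
        for j in order:
            if j in used:
                continue
            if dist.loc[j] > caliper:
                break
            picked.append(j)
            used.add(j)
            if len(picked) == ratio:
                break
        if len(picked) < ratio:
            partial = True
        assignment[crow[id_col]] = [ctrl_rows.loc[j, id_col] for j in picked]
    matched_idx = [j for ids in assignment.values() for j in ids]
    matched = controls[controls[id_col].isin(matched_idx)]

    smd_before, smd_after = {}, {}
    for v in match_vars:
        smd_before[v] = _smd(cases[v].to_numpy(dtype=float),
                             controls[v].to_numpy(dtype=float))
        if len(matched):
            smd_after[v] = _smd(cases[v].to_numpy(dtype=float),
                                matched[v].to_numpy(dtype=float))
        else:
            smd_after[v] = np.nan
    return MatchResult(matched_controls=matched,
                       case_ids=list(case_rows[id_col]),
                       control_ids_per_case=assignment,
                       smd_before=smd_before, smd_after=smd_after,
                       partial=partial, ratio=ratio)


# ---------------------------------------------------------------------------
# survival probabilities for a continuous covariate
# ---------------------------------------------------------------------------

def survival_at_times(df: pd.DataFrame, covariate: str, time_col: str,
                      event_col: str,
                      times: list[float] = (12, 24, 36, 48, 60),
                      values: np.ndarray | None = None) -> dict:
    """Survival probabilities S(t | x) from a Cox model with a continuous
    covariate, evaluated on a grid of covariate values and time points.

    Returns {'surface': DataFrame(times x values), 'cox': CoxResult,
    'extrapolated': list of flagged times beyond observed follow-up}.
    """
    res = cox_fit(df, [covariate], time_col, event_col)
    fitter = CoxPHFitter()
    data = df[[covariate, time_col, event_col]].dropna()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitter.fit(data, duration_col=time_col, event_col=event_col)
    if values is None:
        values = np.quantile(data[covariate], [0.1, 0.25, 0.5, 0.75, 0.9])
    times = list(times)
    max_follow = float(data[time_col].max())
    extrapolated = [t for t in times if t > max_follow]
    X = pd.DataFrame({covariate: np.asarray(values, dtype=float)})
    sf = fitter.predict_survival_function(X, times=times)
    sf.columns = [float(v) for v in np.asarray(values, dtype=float)]
    return {"surface": sf, "cox": res, "extrapolated": extrapolated}


# ---------------------------------------------------------------------------
# log-rank power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerResult:
    n_per_group: tuple[int, int]
    survival_at_horizon: tuple[float, float]
    horizon_months: float
    alpha: float
    n_reps: int
    estimated_power: float
    mc_se: float
    schoenfeld_power: float
    hazard_ratio: float
    expected_events: float


def schoenfeld_power(n1: int, n2: int, s1: float, s2: float,
                     horizon: float, alpha: float = 0.05) -> dict:
    """Schoenfeld events-based closed-form power for the log-rank test.

    Exponential margins anchored at the horizon survivals, administrative
    censoring at the horizon (so expected events are n_i x (1 - S_i)), and
    allocation fractions n_i/(n1+n2):
    power = Phi( sqrt(d p1 p2) |log HR| - z_{1-alpha/2} ).
    """
    if not (0.0 < s1 < 1.0 and 0.0 < s2 < 1.0):
        raise ValueError("horizon survivals must lie in (0, 1)")
    lam1 = -np.log(s1) / horizon
    lam2 = -np.log(s2) / horizon
    hr = lam2 / lam1
    d = n1 * (1.0 - s1) + n2 * (1.0 - s2)
    p1, p2 = n1 / (n1 + n2), n2 / (n1 + n2)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    power = float(sps.norm.cdf(np.sqrt(d * p1 * p2) * abs(np.log(hr)) - z))
    return {"power": power, "hazard_ratio": float(hr),
            "expected_events": float(d)}


def logrank_power(n_per_group: tuple[int, int],
                  survival_at_horizon: tuple[float, float],
                  horizon_months: float = 60.0, alpha: float = 0.05,
                  n_reps: int = 10000, seed: int = 0) -> PowerResult:
    """Monte-Carlo power of the two-sided log-rank test.

    Each replicate draws exponential event times matched to the stated
    horizon survivals, censors administratively at the horizon, and applies
    the two-sided log-rank test at ``alpha``.  Power is the rejection
    fraction, with its Monte-Carlo standard error; the Schoenfeld closed
    form is computed alongside as an analytic cross-check.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n1, n2 = n_per_group
    s1, s2 = survival_at_horizon
    closed = schoenfeld_power(n1, n2, s1, s2, horizon_months, alpha)
    lam1 = -np.log(s1) / horizon_months
    lam2 = -np.log(s2) / horizon_months
    rng = np.random.default_rng(seed)
    group = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])
    rejections = 0
    for _ in range(n_reps):
        t = np.concatenate([rng.exponential(1.0 / lam1, n1),
                            rng.exponential(1.0 / lam2, n2)])
        event = t <= horizon_months
        tc = np.minimum(t, horizon_months)
        _, p = logrank_two_group(tc, event, group)
        if np.isfinite(p) and p < alpha:
            rejections += 1
    power = rejections / n_reps
    mc_se = float(np.sqrt(power * (1.0 - power) / n_reps))
    if s1 == s2 and power > alpha + 3.0 * max(mc_se, 1e-6):
        warnings.warn("null design rejected above alpha; check inputs",
                      UserWarning, stacklevel=2)
    return PowerResult(
        n_per_group=(n1, n2), survival_at_horizon=(s1, s2),
        horizon_months=horizon_months, alpha=alpha, n_reps=n_reps,
        estimated_power=float(power), mc_se=mc_se,
        schoenfeld_power=closed["power"],
        hazard_ratio=closed["hazard_ratio"],
        expected_events=closed["expected_events"])
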