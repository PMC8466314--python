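"""Survival-analysis battery for the cohort table.

Kaplan-Meier curves with log-rank comparison, univariate and
multivariate Cox proportional-hazards models (Efron tie handling, Wald
intervals on the log-hazard scale), Aalen-Johansen cumulative incidence
for competing risks with Gray's test, chi-square / Student-t group
comparisons, and rank-based ROC-AUC variable screening with the 0.7
retention threshold.

Model fitting is delegated to :mod:`lifelines`; Gray's test for the
equality of cumulative incidence functions is implemented here (see
:func:`gray_test`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvFit",
    "CIFResult",
    "EffectEstimate",
    "ComparisonResult",
    "km_logrank",
    "cox_fit",
    "cumulative_incidence",
    "gray_test",
    "compare_groups",
    "auc_screen",
]

_ENDPOINTS = {"os": ("os_time_months", "os_event"),
              "pfs": ("pfs_time_months", "pfs_event")}


def _endpoint_cols(endpoint: str) -> tuple[str, str]:
    try:
        return _ENDPOINTS[endpoint]
    except KeyError:
        raise ValueError(f"endpoint must be one of {sorted(_ENDPOINTS)}") from None


def _step_at(times: np.ndarray, values: np.ndarray, t: float,
             start: float = 1.0) -> float:
    """Right-continuous step-function evaluation with value ``start`` before
    the first jump."""
    i = np.searchsorted(times, t, side="right") - 1
    return float(values[i]) if i >= 0 else start


@dataclass
class EffectEstimate:
    hr: float
    ci95: tuple[float, float]
    p: float


@dataclass
class SurvFit:
    """Fitted survival comparison: effect estimates and/or curves."""

    model_type: str                      # univariate | multivariate | km
    endpoint: str
    effects: dict[str, EffectEstimate] = field(default_factory=dict)
    curves: dict = field(default_factory=dict)   # level -> DataFrame
    logrank_p: float | None = None

    def survival_at(self, level, t: float) -> float:
        df = self.curves[level]
        return _step_at(df["time"].to_numpy(), df["survival"].to_numpy(), t)


def km_logrank(table: pd.DataFrame, group: str, endpoint: str = "os") -> SurvFit:
    """Kaplan-Meier curves per group level plus the log-rank test.

    Requires at least two group levels; all-censored levels are fine
    (their curve stays at 1).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    tcol, ecol = _endpoint_cols(endpoint)
    if (table[tcol] <= 0).any():
        raise ValueError("survival times must be positive")
    levels = sorted(table[group].unique())
    if len(levels) < 2:
        raise ValueError(f"group {group!r} has a single level; nothing to compare")
    curves = {}
    for lev in levels:
        sub = table[table[group] == lev]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[tcol], event_observed=sub[ecol])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy()
        curves[lev] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(),
            "at_risk": at_risk,
        })
    if int(table[ecol].sum()) == 0:
        p = 1.0  # no events anywhere: the curves are identical at 1
    else:
        res = multivariate_logrank_test(table[tcol], table[group], table[ecol])
        p = float(res.p_value)
    return SurvFit(model_type="km", endpoint=endpoint, curves=curves,
                   logrank_p=p)


def cox_fit(table: pd.DataFrame, covariates: Sequence[str],
            endpoint: str = "os") -> SurvFit:
    """Cox proportional hazards (Efron ties, Wald 95% CI per covariate).

    Non-convergence or complete separation raises instead of returning
    silently clipped estimates.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError
    from lifelines.utils import ConvergenceWarning

    tcol, ecol = _endpoint_cols(endpoint)
    covariates = list(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    if int(table[ecol].sum()) == 0:
        raise ValueError("no events; Cox model undefined")
    df = table[covariates + [tcol, ecol]].astype(float)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            cph.fit(df, duration_col=tcol, event_col=ecol)
        except (ConvergenceError, ConvergenceWarning) as exc:
            raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    summary = cph.summary
    effects = {
        cov: EffectEstimate(
            hr=float(summary.loc[cov, "exp(coef)"]),
            ci95=(float(summary.loc[cov, "exp(coef) lower 95%"]),
                  float(summary.loc[cov, "exp(coef) upper 95%"])),
            p=float(summary.loc[cov, "p"]),
        )
        for cov in covariates
    }
    return SurvFit(
        model_type="univariate" if len(covariates) == 1 else "multivariate",
        endpoint=endpoint, effects=effects)


# ---------------------------------------------------------------------------
# competing risks
# ---------------------------------------------------------------------------

@dataclass
class CIFResult:
    """Aalen-Johansen cumulative incidence per group and cause."""

    curves: dict              # (level, cause) -> DataFrame(time, cif, se)
    gray_p: dict[str, float]  # cause -> Gray-test p value
    causes: tuple[str, ...]

    def cif_at(self, level, cause: str, t: float) -> float:
        df = self.curves[(level, cause)]
        return _step_at(df["time"].to_numpy(), df["cif"].to_numpy(), t,
                        start=0.0)


def cumulative_incidence(table: pd.DataFrame, group: str,
                         causes: Sequence[str] = ("relapse", "nrm"),
                         time_col: str = "pfs_time_months",
                         cause_col: str = "failure_cause",
                         gray: bool = True) -> CIFResult:
    """Cause-specific cumulative incidence with Gray's test per cause.

    ``cause_col`` must contain only the given causes plus ``censored``;
    ``gray=False`` skips the test (useful in simulation loops).
    """
    from lifelines import AalenJohansenFitter

    causes = tuple(causes)
    known = set(causes) | {"censored"}
    bad = set(table[cause_col].unique()) - known
    if bad:
        raise ValueError(f"unknown failure cause(s): {sorted(bad)}")
    code = {"censored": 0, **{c: i + 1 for i, c in enumerate(causes)}}
    ev = table[cause_col].map(code).to_numpy()
    t = table[time_col].to_numpy(dtype=float)
    g = table[group].to_numpy()

    curves = {}
    for lev in sorted(pd.unique(g)):
        sel = g == lev
        for i, cause in enumerate(causes):
            ajf = AalenJohansenFitter(calculate_variance=True, seed=12345)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tie-jitter notice
                ajf.fit(t[sel], ev[sel], event_of_interest=i + 1)
            cif = ajf.cumulative_density_
            var = ajf.variance_.reindex(cif.index).to_numpy(dtype=float)
            curves[(lev, cause)] = pd.DataFrame({
                "time": cif.index.to_numpy(dtype=float),
                "cif": cif.iloc[:, 0].to_numpy(),
                "se": np.sqrt(np.clip(var, 0.0, None)),
            })
    gray_p = {}
    if gray:
        gray_p = {cause: gray_test(t, ev, g, cause_code=i + 1)[1]
                  for i, cause in enumerate(causes)}
    return CIFResult(curves=curves, gray_p=gray_p, causes=causes)


def _km_left(d_any: np.ndarray, at_risk: np.ndarray) -> np.ndarray:
    """KM survival just before each event time (left limit)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(at_risk > 0, 1.0 - d_any / np.maximum(at_risk, 1.0), 1.0)
    s = np.cumprod(frac)
    return np.concatenate([[1.0], s[:-1]])


def gray_test(times: np.ndarray, event_codes: np.ndarray, groups: np.ndarray,
              cause_code: int = 1) -> tuple[float, float]:
    """Gray's K-sample test for equality of one cause's CIF.

    Compares the cause's subdistribution hazards across groups: subjects
    who failed from a competing cause remain in a modified risk set with
    weight (1 - F_cause(t-)) / S(t-) estimated within their group
    (Gray's rho = 0 statistic).  The variance uses the log-rank-type
    hypergeometric form on the modified risk sets; see the methods note
    for the approximation this entails.

    Returns ``(chi2, p)`` with K - 1 degrees of freedom.
    """
    times = np.asarray(times, dtype=float)
    event_codes = np.asarray(event_codes)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two groups")

    # pooled grid of all distinct event times of the cause of interest
    tau = np.unique(times[event_codes == cause_code])
    if tau.size == 0:
        return 0.0, 1.0

    m = tau.size
    d1 = np.zeros((k, m))     # cause events per group at tau
    rstar = np.zeros((k, m))  # modified risk sets
    for gi, lev in enumerate(levels):
        sel = groups == lev
        order = np.argsort(times[sel], kind="stable")
        tg = times[sel][order]
        eg = event_codes[sel][order]
        n_g = tg.size
        ev_t = np.unique(tg[eg != 0])
        at_risk = (n_g - np.searchsorted(tg, ev_t, side="left")).astype(float)
        d_any = np.array([np.sum((tg == t0) & (eg != 0)) for t0 in ev_t],
                         dtype=float)
        d_cause = np.array([np.sum((tg == t0) & (eg == cause_code))
                            for t0 in ev_t], dtype=float)
        s_left = _km_left(d_any, at_risk)
        with np.errstate(divide="ignore", invalid="ignore"):
            dcif = s_left * np.where(at_risk > 0,
                                     d_cause / np.maximum(at_risk, 1.0), 0.0)
        s_after = np.cumprod(
            np.where(at_risk > 0, 1.0 - d_any / np.maximum(at_risk, 1.0), 1.0))
        cif_after = np.cumsum(dcif)

        # left-limit state at the pooled grid: after all event times < tau
        j = np.searchsorted(ev_t, tau, side="left")
        s_at = np.concatenate([[1.0], s_after])[j]
        f_at = np.concatenate([[0.0], cif_after])[j]
        y_at = (n_g - np.searchsorted(tg, tau, side="left")).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rstar[gi] = np.where((y_at > 0) & (s_at > 0),
                                 y_at * (1.0 - f_at) / np.maximum(s_at, 1e-300),
                                 0.0)
        d1[gi] = np.array([np.sum((tg == t0) & (eg == cause_code))
                           for t0 in tau], dtype=float)

    rtot = rstar.sum(axis=0)
    dtot = d1.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(rtot > 0, rstar / np.maximum(rtot, 1e-300), 0.0)
    z = (d1 - dtot * frac).sum(axis=1)[:-1]
    # covariance: sum_t d_tot * (diag(r) - r r^T)
    cov = np.zeros((k - 1, k - 1))
    for j in range(m):
        r = frac[:-1, j]
        cov += dtot[j] * (np.diag(r) - np.outer(r, r))
    try:
        chi2 = float(z @ np.linalg.solve(cov, z))
    except np.linalg.LinAlgError:
        return 0.0, 1.0
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


# ---------------------------------------------------------------------------
# group comparisons and screening
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    test: str                 # chi2 | t
    statistic: float
    p: float
    proportions: dict | None = None   # per-group proportion, binary case
    means: dict | None = None         # per-group mean, continuous case
    warning: str | None = None


def _is_discrete(x: pd.Series) -> bool:
    if x.dtype == bool or x.dtype == object or isinstance(
            x.dtype, pd.CategoricalDtype):
        return True
    if np.issubdtype(x.dtype, np.integer) and x.nunique() <= 6:
        return True
    return False


def compare_groups(table: pd.DataFrame, variable: str,
                   group: str) -> ComparisonResult:
    """Chi-square for discrete variables (Yates correction on 2x2 tables),
    two-sample Student's t for continuous ones."""
    x, g = table[variable], table[group]
    if _is_discrete(x):
        ct = pd.crosstab(g, x)
        correction = ct.shape == (2, 2)
        chi2, p, _, expected = stats.chi2_contingency(ct, correction=correction)
        warning = None
        if (expected < 1).any():
            warning = "expected cell count below 1; chi-square unreliable"
        proportions = None
        if ct.shape[1] == 2:
            pos = ct.columns.max()
            proportions = {
                lev: float(ct.loc[lev, pos] / ct.loc[lev].sum())
                for lev in ct.index
            }
        return ComparisonResult(test="chi2", statistic=float(chi2),
                                p=float(p), proportions=proportions,
                                warning=warning)
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError("t test needs exactly two group levels")
    a = x[g == levels[0]].astype(float)
    b = x[g == levels[1]].astype(float)
    tstat, p = stats.ttest_ind(a, b, equal_var=True)
    return ComparisonResult(test="t", statistic=float(tstat), p=float(p),
                            means={levels[0]: float(a.mean()),
                                   levels[1]: float(b.mean())})


def auc_screen(table: pd.DataFrame, variable: str,
               outcome: str) -> tuple[float, bool]:
    """Rank-based ROC AUC of ``variable`` for a binary ``outcome``;
    retained when AUC >= 0.7."""
    from sklearn.metrics import roc_auc_score

    y = table[outcome].to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"outcome {outcome!r} must have exactly two classes")
    auc = float(roc_auc_score(y, table[variable].to_numpy(dtype=float)))
    return auc, auc >= 0.7
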