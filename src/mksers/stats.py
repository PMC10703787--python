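"""Outcome statistics: exact conditional odds ratio, survival, t-test, interaction.

The centrepiece is median-unbiased estimation of the odds ratio from a 2x2
table under Fisher's noncentral hypergeometric (FNCH) conditional model: with
both margins fixed, the count in the exposed-responder cell follows the FNCH
distribution with noncentrality equal to the odds ratio psi. The point
estimate solves the mid-p tail equation

    0.5 * P(X = a; psi) + P(X > a; psi) = 0.5

and the confidence limits solve the corresponding mid-p tail equations at
alpha/2. Survival machinery (Kaplan-Meier, log-rank, univariate Cox with
Efron tie handling) is delegated to lifelines behind a stable interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import gammaln

import lifelines
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
import statsmodels.api as sm

__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "SurvivalCurve",
    "fnch_support",
    "fnch_pmf",
    "fnch_cdf",
    "midp_median_unbiased_or",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "students_t_test",
    "interaction_test",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 response-by-arm table.

    a = responders in the exposed arm, b = non-responders exposed,
    c = responders unexposed, d = non-responders unexposed.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("empty table")

    @property
    def margins(self) -> tuple[int, int, int]:
        """(exposed total, unexposed total, responder total)."""
        return (self.a + self.b, self.c + self.d, self.a + self.c)

    def transpose_arms(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)

    @property
    def sample_odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return np.inf if self.a * self.d > 0 else np.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class OddsRatioResult:
    psi_hat: float
    ci_low: float
    ci_high: float
    alpha: float
    method: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.psi_hat <= self.ci_high):
            raise ValueError("confidence limits must bracket the estimate")


# ---------------------------------------------------------------------------
# Fisher's noncentral hypergeometric distribution
#
# Margins (m1, m2, n): m1 exposed, m2 unexposed, n total responders. X is the
# exposed-responder count, supported on [max(0, n-m2), min(n, m1)]. Weights
# C(m1,x) C(m2,n-x) psi^x are accumulated in log space and normalised.


def fnch_support(margins: tuple[int, int, int]) -> np.ndarray:
    m1, m2, n = margins
    if min(m1, m2, n) < 0 or n > m1 + m2:
        raise ValueError(f"inconsistent margins {margins}")
    return np.arange(max(0, n - m2), min(n, m1) + 1)


def fnch_pmf(margins: tuple[int, int, int], psi: float) -> tuple[np.ndarray, np.ndarray]:
    """Support and normalised probabilities of the FNCH distribution."""
    if not psi > 0:
        raise ValueError("psi must be > 0")
    m1, m2, n = margins
    xs = fnch_support(margins)
    logw = (
        gammaln(m1 + 1) - gammaln(xs + 1) - gammaln(m1 - xs + 1)
        + gammaln(m2 + 1) - gammaln(n - xs + 1) - gammaln(m2 - (n - xs) + 1)
        + xs * np.log(psi)
    )
    logw -= logw.max()
    w = np.exp(logw)
    return xs, w / w.sum()


def fnch_cdf(x: int, margins: tuple[int, int, int], psi: float) -> float:
    """P(X <= x) under FNCH(margins, psi). At psi=1 this is the central
    hypergeometric CDF."""
    xs, p = fnch_pmf(margins, psi)
    if x < xs[0] - 1 or x > xs[-1]:
        raise ValueError(f"x={x} outside support [{xs[0]}, {xs[-1]}]")
    return float(p[xs <= x].sum())


def _midp_upper(a: int, margins, psi: float) -> float:
    """Mid-p upper tail: P(X > a) + 0.5 P(X = a); increasing in psi."""
    xs, p = fnch_pmf(margins, psi)
    return float(p[xs > a].sum() + 0.5 * p[xs == a].sum())


def _exact_upper(a: int, margins, psi: float) -> float:
    xs, p = fnch_pmf(margins, psi)
    return float(p[xs >= a].sum())


def _exact_lower(a: int, margins, psi: float) -> float:
    xs, p = fnch_pmf(margins, psi)
    return float(p[xs <= a].sum())


def _solve_psi(func, target: float, rtol: float = 1e-8) -> float:
    """Root of func(psi) = target in psi, by geometric bracket expansion and
    bisection on log psi. func must be monotone increasing in psi."""
    lo, hi = 1e-8, 1e8
    flo, fhi = func(lo) - target, func(hi) - target
    # numerical monotonicity check on the bracket before root-finding
    if flo > 1e-9 and fhi > 1e-9:
        return 0.0
    if flo < -1e-9 and fhi < -1e-9:
        return np.inf
    while func(lo) - target > 0 and lo > 1e-300:
        lo /= 10
    while func(hi) - target < 0 and hi < 1e300:
        hi *= 10
    log_root = brentq(
        lambda lp: func(np.exp(lp)) - target, np.log(lo), np.log(hi),
        xtol=1e-12, rtol=8.9e-16, maxiter=500,
    )
    return float(np.exp(log_root))


def midp_median_unbiased_or(
    table: ContingencyTable2x2, alpha: float = 0.05, midp: bool = True
) -> OddsRatioResult:
    """Median-unbiased odds-ratio estimate with (mid-)p confidence limits.

    With ``midp=True`` (default) the point estimate solves the mid-p equation
    at 0.5 and the CI solves the mid-p tail equations at alpha/2. With
    ``midp=False`` the exact conditional tails are used: the estimate is the
    geometric mean of the two tail roots and the CI is the exact (Fisher)
    interval. Structural zeros give one-sided limits: 0.0 and ``inf`` encode
    the degenerate ends explicitly.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    margins = table.margins
    if table.a + table.c == 0 or table.b + table.d == 0:
        raise ValueError("a margin of the table is zero; odds ratio undefined")
    xs = fnch_support(margins)
    a = table.a
    if len(xs) == 1:
        raise ValueError("degenerate table: the conditional distribution is a point mass")

    if midp:
        psi_hat = _solve_psi(lambda s: _midp_upper(a, margins, s), 0.5)
        ci_low = (0.0 if a == xs[0]
                  else _solve_psi(lambda s: _midp_upper(a, margins, s), alpha / 2))
        # upper limit solves the mid-p lower tail = alpha/2, i.e. upper = 1 - alpha/2
        ci_high = (np.inf if a == xs[-1]
                   else _solve_psi(lambda s: _midp_upper(a, margins, s), 1.0 - alpha / 2))
        method = "midp_median_unbiased"
    else:
        if a == xs[0]:
            psi_hat, ci_low = 0.0, 0.0
        else:
            psi1 = _solve_psi(lambda s: _exact_upper(a, margins, s), 0.5)
            ci_low = _solve_psi(lambda s: _exact_upper(a, margins, s), alpha / 2)
            psi_hat = psi1
        if a == xs[-1]:
            ci_high = np.inf
            psi2 = np.inf
        else:
            psi2 = _solve_psi(lambda s: 1.0 - _exact_lower(a, margins, s), 0.5)
            ci_high = _solve_psi(lambda s: 1.0 - _exact_lower(a, margins, s), 1.0 - alpha / 2)
        if np.isfinite(psi_hat) and np.isfinite(psi2) and psi_hat > 0:
            psi_hat = float(np.sqrt(psi_hat * psi2))
        elif a == xs[-1]:
            psi_hat = np.inf
        method = "exact_median_unbiased"
    return OddsRatioResult(psi_hat=psi_hat, ci_low=ci_low, ci_high=ci_high,
                           alpha=alpha, method=method)


# ---------------------------------------------------------------------------
# Survival


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit curve with right-continuous step lookup."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t) -> np.ndarray | float:
        tq = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, tq, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out[0]) if np.isscalar(t) else out


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimate; censoring at tied event times handled events-first."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    return SurvivalCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.to_numpy(dtype=float),
        at_risk=tbl["at_risk"].to_numpy(dtype=float),
        events=tbl["observed"].to_numpy(dtype=float),
    )


def logrank_test(times, events, labels) -> tuple[float, int, float]:
    """Log-rank test across >=2 groups; returns (chi2, df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    df = len(groups) - 1
    if not events.any():
        warnings.warn("no events observed; log-rank p set to 1", RuntimeWarning, stacklevel=2)
        return 0.0, df, 1.0
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), df, float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    coef: float
    se: float
    flagged: bool = False  # monotone likelihood / non-convergence


def cox_univariate(times, events, covariate, alpha: float = 0.05) -> CoxResult:
    """Univariate Cox proportional-hazards fit for a binary covariate.

    Partial likelihood with Efron tie handling (lifelines); Wald CI on the
    log-hazard scale. Monotone likelihood (no events in one covariate level)
    is flagged and the CI reported unbounded.
    """
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=bool).astype(int),
        "x": np.asarray(covariate, dtype=float),
    })
    levels = np.unique(df["x"])
    if len(levels) != 2:
        raise ValueError("covariate must be binary")
    events_per_level = df.groupby("x")["event"].sum()
    monotone = (events_per_level == 0).any()
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except lifelines.exceptions.ConvergenceError:
            return CoxResult(np.nan, 0.0, np.inf, np.nan, np.nan, np.inf, flagged=True)
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    z = sps.norm.ppf(1 - alpha / 2)
    p = float(cph.summary.loc["x", "p"])
    if monotone:
        return CoxResult(float(np.exp(coef)), 0.0, np.inf, p, coef, se, flagged=True)
    return CoxResult(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p_value=p,
        coef=coef,
        se=se,
    )


# ---------------------------------------------------------------------------
# t-test and logistic interaction


def students_t_test(x, y, welch: bool = False) -> tuple[float, int | float, float]:
    """Two-sided Student's t-test (pooled variance; Welch behind a flag).

    Returns (t, df, p). Zero pooled variance raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >=2 values")
    if not welch:
        pooled = ((len(x) - 1) * np.var(x, ddof=1) + (len(y) - 1) * np.var(y, ddof=1))
        if pooled == 0:
            raise ValueError("zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = res.df if welch else len(x) + len(y) - 2
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass(frozen=True)
class InteractionResult:
    coef: float
    se: float
    p_value: float | None
    flagged: bool = False  # separation detected


def interaction_test(response, arm, stratum) -> InteractionResult:
    """Wald test of the arm x stratum coefficient in a logistic model.

    Fits response ~ arm + stratum + arm:stratum by IRLS (binomial GLM).
    Separation (non-finite or exploding estimates) is flagged with p = None.
    """
    response = np.asarray(response, dtype=float)
    arm = np.asarray(arm, dtype=float)
    stratum = np.asarray(stratum, dtype=float)
    cells = {(a, s) for a, s in zip(arm, stratum)}
    if len(cells) < 4:
        raise ValueError("all four arm x stratum cells must be observed")
    X = sm.add_constant(np.column_stack([arm, stratum, arm * stratum]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(response, X, family=sm.families.Binomial()).fit()
        except Exception:
            return InteractionResult(np.nan, np.inf, None, flagged=True)
    coef = float(fit.params[3])
    se = float(fit.bse[3])
    if not np.isfinite(coef) or not np.isfinite(se) or se > 1e3 or abs(coef) > 15:
        return InteractionResult(coef, se, None, flagged=True)
    return InteractionResult(coef, se, float(fit.pvalues[3]))
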