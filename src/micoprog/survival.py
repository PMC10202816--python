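"""Survival machinery: Kaplan-Meier, log-rank, Cox proportional hazards,
Harrell's concordance, and density-matched cohort subsampling.

Time-to-event data are DataFrames with a ``time`` column (positive, years)
and an ``event`` column (1 = event, 0 = censored), indexed by sample id.
Kaplan-Meier, log-rank and Cox fitting delegate to lifelines behind this
surface; Harrell's C and the subsampling experiment are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "KMCurve",
    "CoxFit",
    "SubsamplingResult",
    "km_estimate",
    "logrank_test",
    "fit_coxph",
    "harrell_c",
    "density_matched_subsampling",
    "check_survival",
]

#: pairwise hazard contrasts are only computed when both groups have at
#: least this many patients (override with enforce_min_group=False)
MIN_GROUP_SIZE = 10


def check_survival(records: pd.DataFrame) -> pd.DataFrame:
    if not {"time", "event"} <= set(records.columns):
        raise ValueError("survival table needs 'time' and 'event' columns")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return records


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``survival_at(t)`` reads the step function at ``t`` with the drop at an
    event time included (S(t) = P(T > t))."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


@dataclass
class CoxFit:
    """Hazard contrasts from a proportional-hazards fit.

    ``summary`` is indexed by covariate with columns ``coef``, ``hr``,
    ``ci_lower``, ``ci_upper``, ``p`` (Wald, on the log-hazard scale).
    """

    summary: pd.DataFrame
    concordance: float
    log_likelihood: float
    overall_p: float
    n: int
    n_events: int


def km_estimate(records: pd.DataFrame) -> KMCurve:
    records = check_survival(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy(float)
    ev = kmf.event_table
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(float),
        censor_times=np.sort(records.loc[records["event"] == 0, "time"].to_numpy(float)),
    )


def logrank_test(records: pd.DataFrame, groups) -> tuple[float, float]:
    """Log-rank test across two or more groups; returns (chi2, p), df = g - 1."""
    records = check_survival(records)
    groups = pd.Series(groups, index=records.index) if not isinstance(groups, pd.Series) else groups
    groups = groups.reindex(records.index)
    if groups.nunique() < 2:
        raise ValueError("log-rank test needs at least two groups")
    if records["event"].sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(records["time"], groups, records["event"])
    return float(res.test_statistic), float(res.p_value)


def fit_coxph(
    records: pd.DataFrame,
    covariates: pd.DataFrame | pd.Series,
    ties_method: str = "efron",
    enforce_min_group: bool = True,
) -> CoxFit:
    """Cox proportional-hazards fit (partial likelihood, Efron ties default).

    For a binary covariate the pairwise-contrast guard requires both groups
    to hold at least :data:`MIN_GROUP_SIZE` patients unless
    ``enforce_min_group`` is disabled.
    """
    records = check_survival(records)
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    covariates = covariates.reindex(records.index)
    if covariates.isna().any().any():
        raise ValueError("covariates contain missing values after alignment")
    if records["event"].sum() < covariates.shape[1] + 1:
        raise ValueError(
            f"only {int(records['event'].sum())} events for {covariates.shape[1]} covariate(s)"
        )
    if enforce_min_group:
        for col in covariates.columns:
            vals = covariates[col]
            if vals.nunique() == 2:
                sizes = vals.value_counts()
                if (sizes < MIN_GROUP_SIZE).any():
                    raise ValueError(
                        f"covariate {col!r}: group sizes {sizes.to_dict()} below the "
                        f"minimum of {MIN_GROUP_SIZE}; pass enforce_min_group=False to override"
                    )

    if ties_method not in ("efron", "breslow"):
        raise ValueError("ties_method must be 'efron' or 'breslow'")
    if ties_method == "breslow":
        return _fit_coxph_breslow(records, covariates)

    df = pd.concat([records[["time", "event"]], covariates], axis=1)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(f"Cox fit did not converge: {err}") from err

    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        concordance=float(cph.concordance_index_),
        log_likelihood=float(cph.log_likelihood_),
        overall_p=float(cph.log_likelihood_ratio_test().p_value),
        n=len(df),
        n_events=int(records["event"].sum()),
    )


def _fit_coxph_breslow(records: pd.DataFrame, covariates: pd.DataFrame) -> CoxFit:
    """Breslow-ties Cox fit through the statsmodels proportional-hazards model."""
    from statsmodels.duration.hazard_regression import PHReg

    mod = PHReg(
        records["time"].to_numpy(float),
        covariates.to_numpy(float),
        status=records["event"].to_numpy(int),
        ties="breslow",
    )
    res = mod.fit()
    coef = res.params
    se = res.bse
    z = stats.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": coef,
            "hr": np.exp(coef),
            "ci_lower": np.exp(coef - z * se),
            "ci_upper": np.exp(coef + z * se),
            "p": res.pvalues,
        },
        index=covariates.columns,
    )
    lr_stat = 2 * (res.llf - mod.loglike(np.zeros_like(coef)))
    overall_p = float(stats.chi2.sf(max(lr_stat, 0.0), df=len(coef)))
    risk = covariates.to_numpy(float) @ coef
    return CoxFit(
        summary=summary,
        concordance=harrell_c(risk, records),
        log_likelihood=float(res.llf),
        overall_p=overall_p,
        n=len(records),
        n_events=int(records["event"].sum()),
    )


def harrell_c(scores, records: pd.DataFrame) -> float:
    """Harrell's concordance index of a risk score against survival.

    Usable pairs are those where one member is known to fail first: the
    earlier time is an event and the other subject's time is strictly later,
    or the times are tied with exactly one event (the event counted as
    earlier).  A pair is concordant when the earlier failure carries the
    higher score; tied scores count 0.5.
    """
    records = check_survival(records)
    s = np.asarray(pd.Series(scores).reindex(records.index) if isinstance(scores, pd.Series) else scores, float)
    t = records["time"].to_numpy(float)
    e = records["event"].to_numpy(int)
    if s.shape[0] != t.shape[0]:
        raise ValueError("scores not aligned to records")

    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None], e[None, :]
    si, sj = s[:, None], s[None, :]
    # i fails observably before j
    usable = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (ej == 0))
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no usable pairs (all times tied or no events)")
    concordant = (usable & (si > sj)).sum()
    tied = (usable & (si == sj)).sum()
    return float((concordant + 0.5 * tied) / n_usable)


@dataclass
class SubsamplingResult:
    n_subsets: int
    significant_uniform: int
    significant_matched: int
    chi2: float
    p: float
    subsets_uniform: list = field(default_factory=list)
    subsets_matched: list = field(default_factory=list)


def _interp_density(target_scores: np.ndarray, eval_at: np.ndarray, n_bins: int = 50) -> np.ndarray:
    """Piecewise-linear interpolated histogram density of the target sample."""
    lo = min(target_scores.min(), eval_at.min())
    hi = max(target_scores.max(), eval_at.max())
    if hi == lo:
        raise ValueError("degenerate target density: all mass at one point")
    hist, edges = np.histogram(target_scores, bins=n_bins, range=(lo, hi), density=True)
    centers = (edges[:-1] + edges[1:]) / 2
    return np.interp(eval_at, centers, hist, left=0.0, right=0.0)


def density_matched_subsampling(
    records: pd.DataFrame,
    matching_score,
    target_score_sample,
    covariate,
    n_subsets: int = 100,
    subset_size: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    n_bins: int = 50,
) -> SubsamplingResult:
    """Compare prognostic significance under uniform vs density-matched subsampling.

    Scheme A draws ``n_subsets`` subsets of ``subset_size`` uniformly without
    replacement.  Scheme B draws with per-sample weights proportional to the
    target cohort's score density (piecewise-linear interpolation of a
    histogram density) evaluated at each case's ``matching_score`` — i.e. it
    reshapes the cohort to resemble the target cohort's score distribution.
    In each subset a univariate Cox model of ``covariate`` is fitted and
    counted significant when its Wald p < ``alpha``; the two significant
    counts are compared by a chi-squared test on the 2 x 2 table.
    """
    records = check_survival(records)
    n = len(records)
    if subset_size > n:
        raise ValueError("subset_size exceeds cohort size")
    score = np.asarray(pd.Series(matching_score).reindex(records.index)
                       if isinstance(matching_score, pd.Series) else matching_score, float)
    if not np.isfinite(score).all():
        raise ValueError("matching scores must be finite")
    cov = pd.Series(covariate, index=records.index) if not isinstance(covariate, pd.Series) else covariate
    cov = cov.reindex(records.index)

    weights = _interp_density(np.asarray(target_score_sample, float), score, n_bins=n_bins)
    if weights.sum() <= 0:
        raise ValueError("target density assigns zero weight to every case")
    # keep every case drawable so subsets of the requested size always exist
    weights = weights + 1e-12
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)

    def run_scheme(p):
        sig = 0
        members = []
        for _ in range(n_subsets):
            idx = rng.choice(n, size=subset_size, replace=False, p=p)
            members.append(idx)
            sub = records.iloc[idx]
            fit = fit_coxph(sub, cov.iloc[idx], enforce_min_group=False)
            if fit.summary["p"].iloc[0] < alpha:
                sig += 1
        return sig, members

    sig_a, mem_a = run_scheme(None)
    sig_b, mem_b = run_scheme(weights)

    table = np.array([[sig_a, n_subsets - sig_a], [sig_b, n_subsets - sig_b]])
    if table[:, 0].sum() in (0, 2 * n_subsets):
        chi2, p = 0.0, 1.0  # identical margins: no evidence of a difference
    else:
        chi2, p, *_ = stats.chi2_contingency(table)
    return SubsamplingResult(
        n_subsets=n_subsets,
        significant_uniform=sig_a,
        significant_matched=sig_b,
        chi2=float(chi2),
        p=float(p),
        subsets_uniform=mem_a,
        subsets_matched=mem_b,
    )
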