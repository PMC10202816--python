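"""Cohort-level integration: the master per-sample table, the mICRoScore,
adjusted biomarker comparison and grouped survival reporting.

The mICRoScore is the composite of the transcriptomic and microbiome
biomarkers: *high* only when a sample is both ICR-high and MBR low-risk;
every sample that is MBR high-risk and/or ICR-medium/low is *low*; samples
missing either input stay *unassigned* (they are never silently defaulted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import fit_coxph, km_estimate, logrank_test

__all__ = [
    "assign_micro_score",
    "build_cohort_table",
    "adjusted_biomarker_comparison",
    "survival_by_group_report",
    "GroupSurvivalReport",
]


def assign_micro_score(icr_cluster, mbr_group) -> str:
    """The mICRoScore truth table.

    high  iff ICR cluster is High AND MBR risk group is low;
    low   for every other complete combination;
    unassigned when either input is missing.
    """
    if icr_cluster in (None, "unassigned") or (isinstance(icr_cluster, float) and np.isnan(icr_cluster)):
        return "unassigned"
    if mbr_group is None or (isinstance(mbr_group, float) and np.isnan(mbr_group)):
        return "unassigned"
    if icr_cluster not in ("Low", "Medium", "High"):
        raise ValueError(f"unknown ICR cluster {icr_cluster!r}")
    if mbr_group not in ("low", "high"):
        raise ValueError(f"unknown MBR risk group {mbr_group!r}")
    return "high" if (icr_cluster == "High" and mbr_group == "low") else "low"


def build_cohort_table(
    survival: pd.DataFrame,
    icr: pd.DataFrame | None = None,
    clonality: pd.Series | None = None,
    mutations: pd.DataFrame | None = None,
    gie: pd.DataFrame | None = None,
    ies: pd.Series | None = None,
    mbr: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join per-platform outputs into one row per sample.

    ``survival`` defines the sample universe; platform tables covering only
    a subset leave explicit NaN / 'unassigned' entries rather than dropping
    samples cohort-wide.  Adds the ``micro_score`` column from the ICR
    cluster and MBR risk group.
    """
    table = survival.copy()
    if icr is not None:
        table = table.join(icr[["icr_score", "icr_cluster"]])
    if clonality is not None:
        table = table.join(clonality.rename("tcr_clonality"))
    if mutations is not None:
        table = table.join(mutations)
    if gie is not None:
        table = table.join(gie)
    if ies is not None:
        table = table.join(ies.rename("ies"))
    if mbr is not None:
        table = table.join(mbr.rename(columns={"score": "mbr_score", "risk_group": "mbr_group"}))
    if clinical is not None:
        table = table.join(clinical)

    icr_col = table["icr_cluster"] if "icr_cluster" in table else pd.Series(np.nan, index=table.index)
    mbr_col = table["mbr_group"] if "mbr_group" in table else pd.Series(np.nan, index=table.index)
    table["micro_score"] = [
        assign_micro_score(i if pd.notna(i) else None, m if pd.notna(m) else None)
        for i, m in zip(icr_col, mbr_col)
    ]
    return table


#: encodings of the clinical adjustment set
_STAGE_ORDER = {"I": 1, "II": 2, "III": 3, "IV": 4}


def _encode_adjustment(table: pd.DataFrame) -> pd.DataFrame:
    """Age continuous, stage ordinal I-IV, MSI binary (MSI-H = 1 vs MSS),
    CMS categorical with CMS4 as the reference level."""
    enc = pd.DataFrame(index=table.index)
    enc["age"] = table["age"].astype(float)
    enc["stage"] = table["stage"].map(_STAGE_ORDER).astype(float)
    enc["msi"] = table["msi"].map({"MSS": 0, "MSI-H": 1}).astype(float)
    for level in ("CMS1", "CMS2", "CMS3"):
        enc[level] = (table["cms"] == level).astype(float)
    return enc


def _encode_candidate(table: pd.DataFrame, candidate: str) -> pd.Series:
    col = table[candidate]
    if candidate == "icr_cluster":
        return col.map({"Low": 0, "Medium": 1, "High": 2}).rename("icr_ordinal").astype(float)
    if candidate == "mbr_group":
        return (col == "high").astype(float).rename("mbr_high")
    if candidate == "gie":
        return col.astype(float).rename("gie")
    return col.astype(float).rename(candidate)


def adjusted_biomarker_comparison(table: pd.DataFrame, candidates) -> dict:
    """One adjusted multivariable Cox model per candidate biomarker.

    Each candidate (e.g. the ICR cluster as ordinal, the GIE call as binary,
    the MBR risk group as binary) is fitted together with the adjustment set
    — age (continuous), stage (ordinal), MSI (binary) and CMS (categorical
    vs CMS4).  Complete cases only; the per-candidate n is reported on the
    fit.  Returns candidate -> CoxFit.
    """
    results = {}
    for candidate in candidates:
        cand = _encode_candidate(table, candidate)
        cov = pd.concat([cand, _encode_adjustment(table)], axis=1)
        mask = cov.notna().all(axis=1) & table["time"].notna() & table["event"].notna()
        n_dropped = int((~mask).sum())
        if n_dropped:
            warnings.warn(
                f"{candidate}: {n_dropped} incomplete case(s) excluded", stacklevel=2
            )
        sub = table.loc[mask, ["time", "event"]]
        if sub["event"].sum() < cov.shape[1] + 1:
            raise ValueError(
                f"{candidate}: only {int(sub['event'].sum())} events for {cov.shape[1]} covariates"
            )
        results[candidate] = fit_coxph(sub, cov.loc[mask], enforce_min_group=False)
    return results


@dataclass
class GroupSurvivalReport:
    curves: dict          # group -> KMCurve
    horizon_survival: dict  # group -> S(horizon)
    logrank_chi2: float
    logrank_p: float
    pairwise: pd.DataFrame  # group_a, group_b, hr, ci_lower, ci_upper, p (NaN when guarded)


def survival_by_group_report(
    records: pd.DataFrame,
    grouping,
    horizon: float = 5.0,
    enforce_min_group: bool = True,
) -> GroupSurvivalReport:
    """Per-group Kaplan-Meier curves, survival at a horizon, the overall
    log-rank test, and pairwise Cox hazard ratios honoring the minimum
    group-size guard.  Empty group levels are dropped with a notice."""
    groups = pd.Series(grouping, index=records.index) if not isinstance(grouping, pd.Series) else grouping
    groups = groups.reindex(records.index)
    levels = [g for g in pd.unique(groups.dropna())]
    counts = groups.value_counts()
    levels = [g for g in levels if counts.get(g, 0) > 0]

    curves, horizon_surv = {}, {}
    for g in levels:
        curve = km_estimate(records[groups == g])
        curves[g] = curve
        horizon_surv[g] = curve.survival_at(horizon)

    chi2, p = logrank_test(records[groups.notna()], groups.dropna())

    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            mask = groups.isin([a, b])
            sub = records[mask]
            indicator = (groups[mask] == b).astype(int).rename("group")
            try:
                fit = fit_coxph(sub, indicator, enforce_min_group=enforce_min_group)
                s = fit.summary.iloc[0]
                rows.append((a, b, s["hr"], s["ci_lower"], s["ci_upper"], s["p"]))
            except (ValueError, RuntimeError) as err:
                warnings.warn(f"contrast {a} vs {b} skipped: {err}", stacklevel=2)
                rows.append((a, b, np.nan, np.nan, np.nan, np.nan))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "hr", "ci_lower", "ci_upper", "p"])
    return GroupSurvivalReport(
        curves=curves,
        horizon_survival=horizon_surv,
        logrank_chi2=chi2,
        logrank_p=p,
        pairwise=pairwise,
    )
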