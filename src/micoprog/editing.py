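"""Somatic variant filtering, mutational burden, neoantigens and immunoediting.

The genetic immunoediting (GIE) statistic compares the observed number of
neoantigens O in a tumor with the number expected from its nonsynonymous
mutation count x under a linear model ``E(x) = a + b*x``.  A GIE value
``O / E(x)`` below 1 means the tumor carries fewer neoantigens than its
mutational burden predicts — evidence that the immune system has pruned
neoantigenic clones.  Combining the GIE call with the ICR immune cluster
yields the four-level immunoediting score (IES):

====  ==========  =======
IES   ICR         GIE
====  ==========  =======
IES1  Low         absent
IES2  Low         present
IES3  High        absent
IES4  High        present
====  ==========  =======

ICR-medium tumors and tumors with a non-positive expectation are left
unassigned and analyzed separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "ExpectedNeoantigenModel",
    "GIEResult",
    "MutationSummary",
    "filter_somatic_variants",
    "tmb_and_class",
    "classify_msi",
    "call_neoantigens",
    "gie_evaluate",
    "refit_expected_model",
    "assign_ies",
]

#: nonsynonymous variant classes retained for TMB (MAF nomenclature)
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

#: default exome capture size used to express TMB per megabase
DEFAULT_CAPTURE_MB = 40.0
#: nonsynonymous mutations per Mb above which a tumor is called hypermutated
HYPERMUTATION_TMB = 12.0


@dataclass
class ExpectedNeoantigenModel:
    """Linear expectation for neoantigen count given nonsynonymous count x.

    Defaults are the published fit; :func:`refit_expected_model` re-estimates
    the line from a reference set of (x, O) pairs.
    """

    intercept: float = -2.38770
    slope: float = 0.09171

    def expected(self, x) -> float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    @property
    def zero_crossing(self) -> float:
        """Mutation count below which the expectation is non-positive."""
        if self.slope <= 0:
            raise ValueError("model slope must be positive")
        return -self.intercept / self.slope


@dataclass
class MutationSummary:
    sample_id: str
    nonsynonymous_count: int
    tmb_per_mb: float
    hypermutated: bool
    msi_label: str = "unknown"
    mantis_score: float | None = None


@dataclass
class GIEResult:
    observed: int
    expected: float
    gie_value: float | None
    edited: bool | None
    evaluable: bool


def filter_somatic_variants(
    records: pd.DataFrame,
    min_vaf: float = 0.05,
    min_depth_exclusive: int = 3,
    max_pop_af: float = 0.01,
    class_whitelist=NONSYNONYMOUS_CLASSES,
    drop_tolerated_benign: bool = False,
) -> pd.DataFrame:
    """Apply the somatic-variant retention rules to a MAF-like table.

    A variant is retained iff its class is whitelisted, allele fraction
    >= ``min_vaf``, tumor depth strictly greater than ``min_depth_exclusive``
    reads, and population allele frequency <= ``max_pop_af``.  With
    ``drop_tolerated_benign``, variants flagged both tolerated (SIFT-style)
    and benign (PolyPhen-style) are additionally removed — the filter used
    for gene-frequency analyses, not for TMB.

    Accepts either a ``vaf`` column or ``t_alt_count``/``t_depth`` pairs, a
    ``tumor_depth``/``t_depth`` column, and ``population_af``/``ExAC_AF``.
    Unknown variant classes are dropped with a warning.
    """
    df = records.copy()
    cls_col = "variant_class" if "variant_class" in df else "Variant_Classification"
    if cls_col not in df:
        raise ValueError("no variant class column (variant_class / Variant_Classification)")

    if "vaf" in df:
        vaf = df["vaf"].astype(float)
    elif {"t_alt_count", "t_depth"} <= set(df.columns):
        vaf = df["t_alt_count"].astype(float) / df["t_depth"].astype(float)
    else:
        raise ValueError("no allele-fraction information (vaf or t_alt_count/t_depth)")

    depth_col = "tumor_depth" if "tumor_depth" in df else "t_depth"
    if depth_col not in df:
        raise ValueError("no tumor depth column (tumor_depth / t_depth)")
    depth = df[depth_col].astype(float)

    pop_col = "population_af" if "population_af" in df else "ExAC_AF"
    pop_af = df[pop_col].astype(float).fillna(0.0) if pop_col in df else pd.Series(0.0, index=df.index)

    whitelist = set(class_whitelist)
    known = whitelist | {
        "Silent",
        "Synonymous",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "IGR",
        "RNA",
        "Splice_Region",
    }
    unknown = ~df[cls_col].isin(known)
    if unknown.any():
        warnings.warn(
            f"dropping {int(unknown.sum())} variant(s) with unrecognized class: "
            f"{sorted(df.loc[unknown, cls_col].unique())}",
            stacklevel=2,
        )

    keep = (
        df[cls_col].isin(whitelist)
        & (vaf >= min_vaf)
        & (depth > min_depth_exclusive)
        & (pop_af <= max_pop_af)
    )
    if drop_tolerated_benign and {"tolerated", "benign"} <= set(df.columns):
        keep &= ~(df["tolerated"].astype(bool) & df["benign"].astype(bool))
    return df[keep]


def tmb_and_class(
    x: int,
    capture_mb: float = DEFAULT_CAPTURE_MB,
    hyper_threshold: float = HYPERMUTATION_TMB,
    sample_id: str = "",
) -> MutationSummary:
    """Nonsynonymous TMB per Mb and the hypermutation call (strict > threshold)."""
    if capture_mb <= 0:
        raise ValueError("capture_mb must be positive")
    if x < 0:
        raise ValueError("mutation count must be non-negative")
    tmb = x / capture_mb
    return MutationSummary(
        sample_id=sample_id,
        nonsynonymous_count=int(x),
        tmb_per_mb=float(tmb),
        hypermutated=bool(tmb > hyper_threshold),
    )


def classify_msi(mantis_score: float | None, threshold: float = 0.4) -> str:
    """MSI-H iff the instability score is strictly above the threshold, MSS at or below."""
    if mantis_score is None or (isinstance(mantis_score, float) and np.isnan(mantis_score)):
        return "unknown"
    if not np.isfinite(mantis_score):
        raise ValueError("MANTIS score must be finite")
    return "MSI-H" if mantis_score > threshold else "MSS"


def call_neoantigens(
    candidates: pd.DataFrame,
    mut_max: float = 500.0,
    wt_min: float = 500.0,
) -> tuple[int, pd.Series]:
    """Count neoantigens among epitope candidates.

    A candidate is a neoantigen iff its mutant median IC50 is strictly below
    ``mut_max`` nM while the corresponding wild-type epitope's median IC50 is
    strictly above ``wt_min`` nM (the wild-type does not bind).

    Returns the count and the per-candidate boolean flags.
    """
    mut = candidates["mutant_ic50"].astype(float)
    wt = candidates["wt_ic50"].astype(float)
    if (mut <= 0).any() or (wt <= 0).any():
        raise ValueError("IC50 affinities must be positive")
    flags = (mut < mut_max) & (wt > wt_min)
    return int(flags.sum()), flags


def gie_evaluate(
    observed: int,
    x: int,
    model: ExpectedNeoantigenModel | None = None,
    edited_cutoff: float = 1.0,
) -> GIEResult:
    """GIE value O / E(x) and the binary immunoediting call.

    Tumors whose expected count is non-positive (mutation count below the
    model's zero crossing) are non-evaluable: no ratio is fabricated.
    """
    if observed < 0 or x < 0:
        raise ValueError("observed and x must be non-negative")
    model = model or ExpectedNeoantigenModel()
    e = float(model.expected(x))
    if e <= 0:
        return GIEResult(observed=int(observed), expected=e, gie_value=None, edited=None, evaluable=False)
    value = observed / e
    return GIEResult(
        observed=int(observed),
        expected=e,
        gie_value=float(value),
        edited=bool(value < edited_cutoff),
        evaluable=True,
    )


def refit_expected_model(x, observed) -> ExpectedNeoantigenModel:
    """Ordinary least-squares refit of the neoantigen expectation line.

    Intended for a reference set presumed free of editing; requires at least
    three pairs with non-constant x.
    """
    x = np.asarray(x, dtype=float)
    o = np.asarray(observed, dtype=float)
    if x.shape != o.shape or x.ndim != 1:
        raise ValueError("x and observed must be 1-D and aligned")
    if x.size < 3:
        raise ValueError("need at least 3 (x, O) pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: x is constant")
    slope, intercept = np.polyfit(x, o, 1)
    return ExpectedNeoantigenModel(intercept=float(intercept), slope=float(slope))


def assign_ies(icr_cluster: str | None, gie: GIEResult | None) -> str:
    """Four-level immunoediting score from the ICR cluster and the GIE call."""
    if gie is None or not gie.evaluable or icr_cluster not in ("Low", "High"):
        return "unassigned"
    if icr_cluster == "Low":
        return "IES2" if gie.edited else "IES1"
    return "IES4" if gie.edited else "IES3"
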