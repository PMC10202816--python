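"""Genus-level microbiome tables: compositional transforms, filtering,
alpha diversity, taxa harmonization and paired differential abundance.

Tables are pandas DataFrames with samples as rows and taxa as columns;
values are counts or relative abundances (rows summing to one).  Shannon
diversity here uses the natural log, the ecology convention — distinct from
the base-2 entropy of the TCR module.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity.alpha import chao1 as _skbio_chao1
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AlphaDiversity",
    "to_relative_abundance",
    "prevalence_abundance_filter",
    "alpha_diversity",
    "harmonize_taxa",
    "paired_differential_abundance",
    "RUMINOCOCCUS_MERGE",
]

#: harmonization applied before transferring genus-level scores between
#: amplicon classifiers that split Ruminococcus into numbered sub-taxa
RUMINOCOCCUS_MERGE = {
    "Ruminococcus 1": "Ruminococcus",
    "Ruminococcus 2": "Ruminococcus",
}

from dataclasses import dataclass


@dataclass
class AlphaDiversity:
    observed: int
    chao1: float
    shannon: float
    inv_simpson: float


def to_relative_abundance(table: pd.DataFrame, atol: float = 1e-6) -> pd.DataFrame:
    """Row-normalize counts so each sample's abundances sum to one.

    Tables whose rows already sum to one (within ``atol``) are returned
    unchanged with a notice.
    """
    sums = table.sum(axis=1)
    zero = sums == 0
    if zero.any():
        raise ValueError(f"all-zero sample(s): {list(table.index[zero])}")
    if np.allclose(sums, 1.0, atol=atol):
        warnings.warn("table already relative; returned unchanged", stacklevel=2)
        return table
    return table.div(sums, axis=0)


def prevalence_abundance_filter(
    table: pd.DataFrame,
    min_prevalence: float = 0.10,
    min_max_abundance: float = 0.01,
) -> pd.DataFrame:
    """Keep taxa present in at least ``min_prevalence`` of samples and
    reaching at least ``min_max_abundance`` relative abundance in one sample.

    "Present" means abundance strictly greater than zero; both bounds are
    inclusive (at-least).  Idempotent.
    """
    prevalence = (table > 0).mean(axis=0)
    max_abund = table.max(axis=0)
    keep = (prevalence >= min_prevalence) & (max_abund >= min_max_abundance)
    return table.loc[:, keep]


def alpha_diversity(counts, check_integer: bool = True, bias_corrected: bool = True) -> AlphaDiversity:
    """Observed richness, Chao1, Shannon (natural log) and inverse Simpson.

    Chao1 requires integer counts (it is built from singleton and doubleton
    frequencies); Shannon and inverse Simpson accept proportions as well.
    The bias-corrected Chao1 ``S + F1(F1-1) / (2(F2+1))`` is the default;
    ``bias_corrected=False`` gives the classic ``S + F1^2 / (2 F2)`` form.
    """
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if not (arr > 0).any():
        raise ValueError("need at least one positive count")
    if check_integer and not np.allclose(arr, np.round(arr)):
        raise ValueError("Chao1 requires integer counts; pass check_integer=False to skip it")

    pos = arr[arr > 0]
    observed = int(pos.size)
    if check_integer:
        c1 = float(_skbio_chao1(arr.astype(int), bias_corrected=bias_corrected))
    else:
        c1 = float("nan")
    p = pos / pos.sum()
    shannon = float(-np.sum(p * np.log(p)))
    inv_simpson = float(1.0 / np.sum(p**2))
    return AlphaDiversity(observed=observed, chao1=c1, shannon=shannon, inv_simpson=inv_simpson)


def harmonize_taxa(table: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Rename taxa through a many-to-one mapping, summing merged columns.

    Total abundance per sample is conserved exactly.  A mapping whose targets
    are themselves remapped (chained/cyclic) is rejected.
    """
    for target in mapping.values():
        if target in mapping and mapping[target] != target:
            raise ValueError(f"conflicting mapping: target {target!r} is itself remapped")
    renamed = table.rename(columns=lambda c: mapping.get(c, c))
    return renamed.T.groupby(level=0, sort=False).sum().T


def paired_differential_abundance(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    pairing: pd.DataFrame | None = None,
    pseudo: float = 1e-6,
) -> pd.DataFrame:
    """Per-taxon paired two-sided rank test between tumor and matched normal.

    ``pairing`` maps patients to their tumor/normal sample ids (columns
    ``tumor_sample``, ``normal_sample``); when omitted the two tables must
    share their index.  Taxa are the union of both tables' columns (a taxon
    passing upstream filtering in either tissue is tested in both).  The test
    is the two-sided Wilcoxon signed-rank test on paired differences — the
    paired analogue of the Mann-Whitney U-test — with Benjamini-Hochberg FDR
    across taxa.  Fold change is the ratio of tumor to normal mean abundance
    with ``pseudo`` added to both.

    Returns a DataFrame indexed by taxon with columns ``direction``,
    ``fold_change``, ``p``, ``fdr``.
    """
    if pairing is not None:
        t = tumor.loc[pairing["tumor_sample"]]
        n = normal.loc[pairing["normal_sample"]]
        t.index = n.index = pairing.index
    else:
        common = tumor.index.intersection(normal.index)
        t, n = tumor.loc[common], normal.loc[common]
    if len(t) < 2:
        raise ValueError("need at least 2 tumor/normal pairs")

    taxa = t.columns.union(n.columns)
    t = t.reindex(columns=taxa, fill_value=0.0)
    n = n.reindex(columns=taxa, fill_value=0.0)

    rows = []
    for taxon in taxa:
        diff = t[taxon].to_numpy(float) - n[taxon].to_numpy(float)
        if np.all(diff == 0):
            p = 1.0
        else:
            # zero differences dropped per the classic signed-rank procedure
            p = float(stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided").pvalue)
        fc = (t[taxon].mean() + pseudo) / (n[taxon].mean() + pseudo)
        rows.append((taxon, "up" if fc > 1 else ("down" if fc < 1 else "none"), float(fc), p))
    out = pd.DataFrame(rows, columns=["taxon", "direction", "fold_change", "p"]).set_index("taxon")
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
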