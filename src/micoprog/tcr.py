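"""T cell receptor (TCR) repertoire metrics and tumor/normal clone overlap.

A repertoire is a table of unique rearrangements ("clones"), each with a
template count and a productive (in-frame) flag.  All diversity metrics are
computed over productive clones only:

* Shannon entropy ``H = -sum p_i log2 p_i`` (bits), with ``p_i`` the clone's
  share of productive templates,
* Pielou evenness ``J = H / log2(S)`` for ``S`` unique productive clones,
* clonality ``1 - J``, ranging from 0 (perfectly even repertoire) towards 1
  (a single dominant clone).

The same formulas apply to DNA-targeted (immunoSEQ-style) and RNA-derived
(MiXCR-style) clone tables; the log base cancels in ``J``, so clonality is
base-independent.

Tumor-enriched clones are called from a matched tumor/normal pair: a clone is
enriched when its tumor productive frequency exceeds a floor (default 0.1%,
strict) and is at least ``fold_threshold`` times (default 32, inclusive) its
frequency in the matched normal tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Repertoire",
    "RepertoireSummary",
    "OverlapAnalysis",
    "summarize_repertoire",
    "clonality_from_counts",
    "detect_tumor_enriched",
    "fraction_tumor_enriched",
    "read_clone_table",
    "write_clone_table",
]

#: column aliases accepted when reading immunoSEQ-style exports
_SEQ_ALIASES = ("sequence", "nucleotide", "rearrangement", "cdr3", "clone_id")
_COUNT_ALIASES = ("templates", "template_count", "count (templates/reads)", "count", "reads")
_PRODUCTIVE_ALIASES = ("productive", "frame_type", "frame type", "sequencestatus")


@dataclass
class Repertoire:
    """A per-sample clone table.

    Parameters
    ----------
    sample_id:
        Identifier shared with the other assay tables of the cohort.
    clones:
        DataFrame with columns ``sequence`` (opaque unique string),
        ``templates`` (non-negative int) and ``productive`` (bool).
    assay:
        ``"dna-targeted"`` or ``"rna-derived"``; informational only, the
        metrics are identical.
    """

    sample_id: str
    clones: pd.DataFrame
    assay: str = "dna-targeted"

    def __post_init__(self) -> None:
        missing = {"sequence", "templates", "productive"} - set(self.clones.columns)
        if missing:
            raise ValueError(f"clone table missing columns: {sorted(missing)}")
        if self.clones["sequence"].duplicated().any():
            dups = self.clones.loc[self.clones["sequence"].duplicated(), "sequence"]
            raise ValueError(f"duplicate clone sequences: {list(dups.head())}")
        if (self.clones["templates"] < 0).any():
            raise ValueError("negative template counts")

    @property
    def productive(self) -> pd.DataFrame:
        """Productive clones with at least one template."""
        c = self.clones
        return c[(c["productive"]) & (c["templates"] > 0)]

    def frequencies(self) -> pd.Series:
        """Productive frequency per productive clone (sums to 1)."""
        prod = self.productive
        total = prod["templates"].sum()
        if total == 0:
            raise ValueError(f"sample {self.sample_id}: no productive templates")
        return pd.Series(
            prod["templates"].to_numpy(float) / total,
            index=prod["sequence"].to_numpy(),
        )


@dataclass
class RepertoireSummary:
    sample_id: str
    total_templates: int
    productive_templates: int
    unique_productive: int
    entropy_bits: float
    normalized_entropy: float
    clonality: float
    max_productive_frequency: float


@dataclass
class OverlapAnalysis:
    """Tumor/normal clone overlap and the tumor-enriched call set."""

    tumor_sample_id: str
    normal_sample_id: str
    #: one row per tumor productive clone passing nothing in particular:
    #: columns sequence, tumor_frequency, normal_frequency, fold_ratio (inf
    #: when absent in normal), enriched (bool)
    table: pd.DataFrame
    shared: list = field(default_factory=list)
    tumor_enriched: list = field(default_factory=list)
    fraction_enriched: float = 0.0


def clonality_from_counts(counts) -> float:
    """Clonality ``1 - H / log2(S)`` of a vector of clone template counts.

    Requires at least two clones with positive counts (the normalization is
    undefined for a single clone).  Scale-invariant in the counts.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need at least two clone counts")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    arr = arr[arr > 0]
    s = arr.size
    if s < 2:
        raise ValueError("need at least two clones with positive counts")
    p = arr / arr.sum()
    h = -np.sum(p * np.log2(p))
    return float(1.0 - h / np.log2(s))


def summarize_repertoire(rep: Repertoire) -> RepertoireSummary:
    """Entropy, evenness and clonality of the productive clone distribution."""
    prod = rep.productive
    s = len(prod)
    if s < 2:
        raise ValueError(
            f"sample {rep.sample_id}: {s} unique productive clone(s); "
            "normalized entropy requires at least 2"
        )
    freq = rep.frequencies()
    h = float(-np.sum(freq * np.log2(freq)))
    j = h / np.log2(s)
    return RepertoireSummary(
        sample_id=rep.sample_id,
        total_templates=int(rep.clones["templates"].sum()),
        productive_templates=int(prod["templates"].sum()),
        unique_productive=s,
        entropy_bits=h,
        normalized_entropy=float(j),
        clonality=float(1.0 - j),
        max_productive_frequency=float(freq.max()),
    )


def detect_tumor_enriched(
    tumor: Repertoire,
    normal: Repertoire,
    fold_threshold: float = 32.0,
    frequency_floor: float = 0.001,
    absent_in_normal: str = "enriched",
    pseudo_frequency: float | None = None,
) -> OverlapAnalysis:
    """Call tumor-enriched clones from a matched tumor/normal pair.

    A tumor clone is enriched when its productive frequency is strictly above
    ``frequency_floor`` and its tumor/normal frequency ratio is at least
    ``fold_threshold``.  Clones undetected in the normal repertoire are
    treated per ``absent_in_normal``:

    * ``"enriched"`` (default): the fold criterion is deemed satisfied — an
      undetected clone is maximally enriched (the floor still applies);
    * ``"pseudo"``: the normal frequency is replaced by ``pseudo_frequency``
      (required) and the ratio computed against it.
    """
    if absent_in_normal not in ("enriched", "pseudo"):
        raise ValueError("absent_in_normal must be 'enriched' or 'pseudo'")
    if absent_in_normal == "pseudo" and not (pseudo_frequency and pseudo_frequency > 0):
        raise ValueError("pseudo policy requires a positive pseudo_frequency")

    tf = tumor.frequencies()  # raises on empty tumor repertoire
    nf = normal.frequencies()

    norm_aligned = nf.reindex(tf.index)
    absent = norm_aligned.isna()
    if absent_in_normal == "pseudo":
        norm_for_ratio = norm_aligned.fillna(pseudo_frequency)
    else:
        norm_for_ratio = norm_aligned.fillna(0.0)
    with np.errstate(divide="ignore"):
        ratio = np.where(
            norm_for_ratio.to_numpy() > 0,
            tf.to_numpy() / np.where(norm_for_ratio.to_numpy() > 0, norm_for_ratio.to_numpy(), 1.0),
            np.inf,
        )
    passes_fold = ratio >= fold_threshold
    enriched = (tf.to_numpy() > frequency_floor) & passes_fold

    table = pd.DataFrame(
        {
            "sequence": tf.index,
            "tumor_frequency": tf.to_numpy(),
            "normal_frequency": norm_aligned.fillna(0.0).to_numpy(),
            "fold_ratio": ratio,
            "enriched": enriched,
        }
    ).reset_index(drop=True)

    enriched_ids = list(table.loc[table["enriched"], "sequence"])
    analysis = OverlapAnalysis(
        tumor_sample_id=tumor.sample_id,
        normal_sample_id=normal.sample_id,
        table=table,
        shared=list(tf.index[~absent.to_numpy()]),
        tumor_enriched=enriched_ids,
    )
    analysis.fraction_enriched = fraction_tumor_enriched(analysis, tumor)
    return analysis


def fraction_tumor_enriched(analysis: OverlapAnalysis, tumor: Repertoire) -> float:
    """Template-weighted fraction of the tumor repertoire that is enriched.

    Number of productive templates carried by tumor-enriched clones divided
    by the total number of productive templates in the tumor sample.
    """
    if analysis.tumor_sample_id != tumor.sample_id:
        raise ValueError(
            f"analysis is for sample {analysis.tumor_sample_id!r}, "
            f"repertoire is {tumor.sample_id!r}"
        )
    prod = tumor.productive
    total = prod["templates"].sum()
    enriched = set(analysis.tumor_enriched)
    in_enriched = prod.loc[prod["sequence"].isin(enriched), "templates"].sum()
    return float(in_enriched / total)


def _find_column(columns, aliases, what):
    lowered = {c.lower(): c for c in columns}
    for a in aliases:
        if a in lowered:
            return lowered[a]
    raise ValueError(f"could not find a {what} column among {list(columns)}")


def read_clone_table(path, sample_id: str | None = None, assay: str = "dna-targeted") -> Repertoire:
    """Read a clone TSV, accepting immunoSEQ-export-style headers.

    Productive status is taken from a boolean ``productive`` column or from a
    frame-type column where the value ``"In"`` (case-insensitive) marks
    in-frame rearrangements.
    """
    df = pd.read_csv(path, sep="\t")
    seq = _find_column(df.columns, _SEQ_ALIASES, "sequence")
    cnt = _find_column(df.columns, _COUNT_ALIASES, "template count")
    prd = _find_column(df.columns, _PRODUCTIVE_ALIASES, "productive flag")
    prod_raw = df[prd]
    if prod_raw.dtype == bool:
        productive = prod_raw
    else:
        productive = prod_raw.astype(str).str.strip().str.lower().isin(
            {"true", "in", "in-frame", "inframe", "1", "yes"}
        )
    clones = pd.DataFrame(
        {
            "sequence": df[seq].astype(str),
            "templates": df[cnt].astype(int),
            "productive": productive.astype(bool),
        }
    )
    sid = sample_id if sample_id is not None else str(path)
    return Repertoire(sample_id=sid, clones=clones, assay=assay)


def write_clone_table(rep: Repertoire, path) -> None:
    rep.clones.to_csv(path, sep="\t", index=False)
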