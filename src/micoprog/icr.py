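"""Immunologic Constant of Rejection (ICR) scoring and immune subtyping.

The ICR is a fixed 20-gene Th1/cytotoxic signature.  Its per-sample mean
log2 expression is the *ICR score*; resampling consensus clustering of the
signature genes partitions a cohort into Low / Medium / High immune
subtypes, with the number of clusters chosen by the Calinski-Harabasz
criterion and the labels assigned by ranking clusters on their mean ICR
score.

A generic single-sample gene-set enrichment (ssGSEA-style rank walk) is
provided for arbitrary user-supplied signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import calinski_harabasz_score

__all__ = [
    "ICR_SIGNATURE",
    "GeneSignature",
    "ConsensusClusteringResult",
    "icr_score",
    "consensus_cluster",
    "assign_icr_labels",
    "ssgsea_scores",
    "read_signature",
]


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValueError("empty gene signature")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")


#: the 20 ICR genes: Th1 polarization, cytotoxic effectors, chemoattractants
#: and counter-regulatory immune checkpoints
ICR_SIGNATURE = GeneSignature(
    name="ICR",
    genes=(
        "IFNG", "IRF1", "STAT1", "IL12B", "TBX21",
        "CD8A", "CD8B", "CXCL9", "CXCL10", "CCL5",
        "GZMB", "GNLY", "PRF1", "GZMH", "GZMA",
        "CD274", "PDCD1", "CTLA4", "FOXP3", "IDO1",
    ),
)


@dataclass
class ConsensusClusteringResult:
    sample_ids: list
    consensus: dict           # k -> (n, n) ndarray in [0, 1], symmetric, unit diagonal
    labels: dict              # k -> ndarray of cluster ids (1-based)
    criterion: dict           # k -> Calinski-Harabasz value
    chosen_k: int

    @property
    def final_labels(self) -> pd.Series:
        return pd.Series(self.labels[self.chosen_k], index=self.sample_ids)


def _check_signature_genes(expr: pd.DataFrame, sig: GeneSignature) -> pd.DataFrame:
    missing = [g for g in sig.genes if g not in expr.index]
    if missing:
        raise KeyError(f"signature {sig.name!r}: genes missing from matrix: {missing}")
    return expr.loc[list(sig.genes)]


def icr_score(expr: pd.DataFrame, sig: GeneSignature = ICR_SIGNATURE) -> pd.Series:
    """Per-sample mean log2 expression of the signature genes.

    ``expr`` is genes x samples, log2-normalized.  All signature genes must
    be present; missing genes raise rather than being silently dropped.
    """
    sub = _check_signature_genes(expr, sig)
    if not np.isfinite(sub.to_numpy()).all():
        raise ValueError("non-finite expression values among signature genes")
    return sub.mean(axis=0)


def consensus_cluster(
    expr: pd.DataFrame,
    sig: GeneSignature = ICR_SIGNATURE,
    k_range=(2, 3, 4, 5, 6),
    n_reps: int = 5000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    scale_rows: bool = True,
) -> ConsensusClusteringResult:
    """Resampling consensus clustering of samples on the signature genes.

    For each of ``n_reps`` repetitions a fraction of samples is drawn without
    replacement and clustered by Ward-linkage agglomerative clustering
    (Euclidean distance on row-z-scored signature genes) into k groups; the
    consensus matrix entry (i, j) is the fraction of co-drawn repetitions in
    which i and j co-clustered.  Final labels at each k come from
    complete-linkage hierarchical clustering of 1 - consensus; the reported
    ``chosen_k`` maximizes the Calinski-Harabasz criterion of those labels on
    the signature-gene data.

    The same subsample draws are reused across k, so consensus matrices at
    different k are comparable.
    """
    k_range = sorted(set(int(k) for k in k_range))
    data = _check_signature_genes(expr, sig)
    n = data.shape[1]
    if n < 2 * max(k_range):
        raise ValueError(f"need at least {2 * max(k_range)} samples for k up to {max(k_range)}")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")

    vals = data.to_numpy(float)
    if scale_rows:
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        vals = (vals - vals.mean(axis=1, keepdims=True)) / sd
    points = vals.T  # samples x genes

    m = max(2, int(round(subsample_fraction * n)))
    rng = np.random.default_rng(seed)
    draws = [np.sort(rng.choice(n, size=m, replace=False)) for _ in range(n_reps)]

    both = np.zeros((n, n))
    for idx in draws:
        both[np.ix_(idx, idx)] += 1.0
    if (both == 0).any():
        raise RuntimeError(
            "some sample pairs were never co-drawn; increase n_reps or subsample_fraction"
        )

    consensus, labels, criterion = {}, {}, {}
    for k in k_range:
        together = np.zeros((n, n))
        for idx in draws:
            z = linkage(points[idx], method="ward")
            cl = fcluster(z, t=k, criterion="maxclust")
            for c in np.unique(cl):
                members = idx[cl == c]
                together[np.ix_(members, members)] += 1.0
        cons = together / both
        np.fill_diagonal(cons, 1.0)
        cons = np.clip((cons + cons.T) / 2.0, 0.0, 1.0)
        consensus[k] = cons

        dist = squareform(1.0 - cons, checks=False)
        final = fcluster(linkage(dist, method="complete"), t=k, criterion="maxclust")
        labels[k] = final
        if len(np.unique(final)) < 2:
            criterion[k] = -np.inf
        else:
            criterion[k] = float(calinski_harabasz_score(points, final))

    chosen_k = max(k_range, key=lambda k: (criterion[k], -k))
    return ConsensusClusteringResult(
        sample_ids=list(data.columns),
        consensus=consensus,
        labels=labels,
        criterion=criterion,
        chosen_k=chosen_k,
    )


def assign_icr_labels(
    result: ConsensusClusteringResult,
    expr: pd.DataFrame,
    sig: GeneSignature = ICR_SIGNATURE,
) -> pd.DataFrame:
    """Map consensus clusters to ICR Low / Medium / High by mean ICR score.

    Clusters are ranked by the mean ICR score of their members: highest ->
    High, lowest -> Low, the middle one (at k = 3) -> Medium.  For k != 3
    only the extremes are labeled and the rest left unassigned, with a
    warning.  Ties in cluster means break deterministically by cluster size,
    then by smallest member sample id.
    """
    scores = icr_score(expr, sig).reindex(result.sample_ids)
    labels = result.final_labels
    clusters = sorted(labels.unique())

    keys = []
    for c in clusters:
        members = labels.index[labels == c]
        keys.append((float(scores[members].mean()), len(members), min(str(s) for s in members), c))
    means = [k[0] for k in keys]
    if len(set(means)) != len(means):
        warnings.warn("tied cluster mean ICR scores; breaking ties by size then sample id", stacklevel=2)
    order = [k[3] for k in sorted(keys)]  # ascending mean score

    mapping = {c: "unassigned" for c in clusters}
    mapping[order[0]] = "Low"
    mapping[order[-1]] = "High"
    if len(order) == 3:
        mapping[order[1]] = "Medium"
    elif len(order) != 2:
        warnings.warn(
            f"k = {len(order)} clusters: only extremes labeled High/Low, "
            "intermediate clusters left unassigned",
            stacklevel=2,
        )

    return pd.DataFrame(
        {
            "icr_score": scores,
            "icr_cluster": labels.map(mapping),
        }
    )


def ssgsea_scores(
    expr: pd.DataFrame,
    gene_sets: dict,
    weight_exponent: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment by the weighted rank-walk.

    Per sample, genes are ranked by expression (descending) and replaced by
    their rank values n..1.  The enrichment score is the sum over ranks of
    the difference between the weighted in-set cumulative distribution
    (weights = rank value ** ``weight_exponent``) and the uniform out-of-set
    cumulative distribution.  With ``normalize``, scores are divided by the
    overall score range across all sets and samples.

    Returns gene sets x samples.
    """
    n_genes = expr.shape[0]
    genes = expr.index.to_numpy()
    sets = {}
    for name, members in gene_sets.items():
        overlap = [g for g in members if g in expr.index]
        if len(overlap) < 2:
            raise ValueError(f"gene set {name!r} overlaps the matrix by {len(overlap)} gene(s); need >= 2")
        sets[name] = np.isin(genes, overlap)

    out = pd.DataFrame(index=list(sets), columns=expr.columns, dtype=float)
    for sample in expr.columns:
        x = expr[sample].to_numpy(float)
        order = np.argsort(-x, kind="stable")
        rank_values = np.arange(n_genes, 0, -1, dtype=float)  # n..1 down the ranking
        for name, mask in sets.items():
            in_set = mask[order]
            w = np.where(in_set, rank_values**weight_exponent, 0.0)
            p_in = np.cumsum(w) / w.sum()
            n_out = n_genes - in_set.sum()
            p_out = np.cumsum(~in_set) / n_out
            out.loc[name, sample] = float(np.sum(p_in - p_out))
    if normalize:
        rng_ = out.to_numpy().max() - out.to_numpy().min()
        if rng_ > 0:
            out = out / rng_
    return out


def read_signature(path) -> GeneSignature:
    """Read a one-gene-per-line signature file with an optional ``# name:`` header."""
    name = "signature"
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("name:"):
                    name = body[5:].strip()
                continue
            genes.append(line)
    return GeneSignature(name=name, genes=tuple(genes))
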