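"""Synthetic linked multi-omics cohorts with known ground truth.

Every downstream stage of the pipeline (immune subtyping, TCR metrics,
immunoediting, microbiome risk modeling, survival integration) is exercised
on cohorts generated here, so recovery of the planted structure can be
verified without any external data.  The generator plants:

* three expression groups whose 20 signature genes are shifted by
  ``icr_effect`` log2 units per group level, all other genes pure noise;
* per-group TCR clonality via a geometric (stick-breaking) clone-size law
  whose skew parameter is calibrated to the target clonality by bisection,
  plus a configurable number of tumor-spiked clones that satisfy the
  tumor-enrichment rule by construction;
* an immunoediting effect: observed neoantigens are the linear expectation
  E(x) times ``editing_strength`` for edited samples (1 otherwise) plus
  rounding noise;
* Dirichlet genus compositions with per-sample log-scale perturbations on
  designated risk / protective taxa;
* exponential proportional-hazards survival whose log-hazard is a weighted
  sum of the planted truth variables, with independent uniform censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
import pandas as pd

from .editing import ExpectedNeoantigenModel
from .icr import ICR_SIGNATURE
from .tcr import Repertoire

__all__ = ["CohortConfig", "Cohort", "generate_expression", "generate_repertoire_pair",
           "generate_mutation_neoantigen", "generate_microbiome_survival",
           "generate_cohort", "write_cohort", "geometric_clone_probabilities",
           "calibrate_skew"]

ICR_LEVELS = ("Low", "Medium", "High")


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate a mid-sized colon-cancer profiling cohort: ~250
    patients, three immune groups of comparable size with a clear (3 log2
    units) signature separation over unit Gaussian noise, quarter of tumors
    hypermutated, half of tumors immunoedited at strength 0.5, five
    prognostic genera among 100, and moderate (30%) censoring.
    """

    n_samples: int = 246
    n_genes: int = 500
    icr_group_proportions: tuple = (1 / 3, 1 / 3, 1 / 3)
    icr_effect: float = 3.0       # log2 shift of signature genes per group level
    noise_sd: float = 1.0         # log2 units
    base_expression: float = 5.0  # log2 units

    clone_richness: int = 1000
    n_templates: int = 20000
    clonality_targets: dict = dc_field(
        default_factory=lambda: {"Low": 0.08, "Medium": 0.14, "High": 0.25}
    )
    n_spiked_clones: int = 5
    spiked_tumor_frequency: float = 0.005
    spiked_fold: float = 64.0
    nonproductive_fraction: float = 0.15

    hypermutated_fraction: float = 0.25
    editing_fraction: float = 0.5
    editing_strength: float = 0.5
    neoantigen_noise_sd: float = 1.0
    nonhyper_log_mean: float = np.log(150.0)
    hyper_log_mean: float = np.log(900.0)
    mutation_log_sd: float = 0.35

    n_taxa: int = 100
    n_risk_taxa: int = 3
    n_protective_taxa: int = 2
    dirichlet_concentration: float = 50.0

    hazard_coefficients: dict = dc_field(
        default_factory=lambda: {
            "icr": -0.5,            # per ICR level (0 = Low, 2 = High)
            "edited": -0.5,
            "risk_taxon": 1.0,      # per unit z-scored abundance of the taxon
            "protective_taxon": -1.0,
        }
    )
    baseline_median_years: float = 5.0
    follow_up_years: float = 15.0
    censoring_rate: float = 0.3

    missing_assay_fractions: dict = dc_field(default_factory=dict)  # e.g. {"tcr": 0.5}
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_samples <= 0 or self.n_genes <= 0 or self.n_taxa <= 0:
            raise ValueError("dimensions must be positive")
        props = np.asarray(self.icr_group_proportions, float)
        if props.shape != (3,) or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ValueError("icr_group_proportions must be a 3-vector of non-negatives summing to 1")
        for name in ("hypermutated_fraction", "editing_fraction", "censoring_rate",
                     "nonproductive_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.editing_strength <= 1:
            raise ValueError("editing_strength must be in (0, 1]")
        if self.clone_richness < 2:
            raise ValueError("clone_richness must be at least 2 (normalized entropy undefined below)")
        for lvl, c in self.clonality_targets.items():
            if not 0 <= c < 1:
                raise ValueError(f"clonality target for {lvl} must be in [0, 1)")
        if self.n_risk_taxa + self.n_protective_taxa > self.n_taxa:
            raise ValueError("designated risk + protective taxa exceed n_taxa")
        if self.n_genes < len(ICR_SIGNATURE.genes):
            raise ValueError("n_genes must accommodate the 20 signature genes")
        return self


@dataclass
class Cohort:
    """Linked tables of one synthetic cohort, all keyed by sample id."""

    config: CohortConfig
    expression: pd.DataFrame            # genes x samples, log2
    repertoires: dict                   # sample -> (tumor Repertoire, normal Repertoire); missing-assay samples absent
    mutations: pd.DataFrame             # per sample: nonsynonymous_count, observed_neoantigens
    abundance: pd.DataFrame             # samples x taxa, relative
    survival: pd.DataFrame              # per sample: time, event
    truth_samples: pd.DataFrame         # true_icr_level, true_edited, true_linear_predictor
    truth_taxa: pd.Series               # taxon -> risk sign in {+1, -1, 0}


# ---------------------------------------------------------------------------
# clone-size law

def geometric_clone_probabilities(richness: int, skew: float) -> np.ndarray:
    """Truncated geometric clone-frequency law; ``skew = 0`` is uniform."""
    if richness < 2:
        raise ValueError("richness must be at least 2")
    if skew <= 0:
        return np.full(richness, 1.0 / richness)
    w = np.exp(-skew * np.arange(richness))
    return w / w.sum()


def _clonality_of(p: np.ndarray) -> float:
    p = p[p > 0]
    h = -np.sum(p * np.log2(p))
    return 1.0 - h / np.log2(p.size)


@lru_cache(maxsize=None)
def calibrate_skew(
    richness: int,
    target_clonality: float,
    n_templates: int | None = None,
    tol: float = 1e-6,
) -> float:
    """Bisection on the geometric skew so the law's clonality hits the target.

    Clonality is monotone increasing in the skew, which makes the inversion
    reliable.  With ``n_templates`` the objective is the clonality realized
    by a multinomial draw of that many templates (fixed internal seed):
    finite sampling drops rare clones and would otherwise bias realized
    clonality below the ideal-law target at high skew.
    """
    if not 0 <= target_clonality < 1:
        raise ValueError("target clonality must be in [0, 1)")
    if target_clonality == 0:
        return 0.0

    if n_templates is None:
        def realized(skew: float) -> float:
            return _clonality_of(geometric_clone_probabilities(richness, skew))
    else:
        def realized(skew: float) -> float:
            p = geometric_clone_probabilities(richness, skew)
            counts = np.random.default_rng(12345).multinomial(n_templates, p)
            counts = counts[counts > 0].astype(float)
            return _clonality_of(counts / counts.sum())

    lo, hi = 0.0, 1.0
    while realized(hi) < target_clonality:
        hi *= 2
        if hi > 1e6:
            raise RuntimeError("cannot reach target clonality")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target_clonality:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# per-platform generators

def generate_expression(config: CohortConfig, rng: np.random.Generator | None = None):
    """Expression matrix with planted signature-gene shifts, plus sample truth.

    Signature-gene means are ``base + icr_effect * level`` (level 0/1/2 for
    the Low/Medium/High groups); all other genes are pure noise around the
    base level.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    props = np.asarray(config.icr_group_proportions, float)
    counts = np.floor(props * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(props * n - counts))] += 1
    levels = np.repeat([0, 1, 2], counts)
    rng.shuffle(levels)

    sig = list(ICR_SIGNATURE.genes)
    other = [f"G{i:04d}" for i in range(config.n_genes - len(sig))]
    genes = sig + other

    vals = rng.normal(config.base_expression, config.noise_sd, size=(config.n_genes, n))
    vals[: len(sig), :] += config.icr_effect * levels[None, :]
    expr = pd.DataFrame(vals, index=genes, columns=samples)

    truth = pd.DataFrame(
        {"true_icr_level": [ICR_LEVELS[l] for l in levels]},
        index=samples,
    )
    return expr, truth


def generate_repertoire_pair(
    config: CohortConfig,
    sample_id: str,
    icr_level: str,
    rng: np.random.Generator,
) -> tuple[Repertoire, Repertoire]:
    """Matched tumor / normal repertoires for one sample.

    Both tissues draw from a shared background clone pool whose skew is
    calibrated to the sample group's clonality target.  ``n_spiked_clones``
    tumor-specific clones are planted at ``spiked_tumor_frequency`` in the
    tumor and at ``spiked_fold`` lower frequency in the normal, with
    deterministic template counts so that they — and only they — satisfy the
    tumor-enrichment rule by construction.  A separate nonproductive clone
    pool is appended.
    """
    config.validate()
    target = config.clonality_targets[icr_level]
    skew = calibrate_skew(config.clone_richness, target, n_templates=config.n_templates)
    background_p = geometric_clone_probabilities(config.clone_richness, skew)

    n_spike = config.n_spiked_clones
    spike_mass_t = n_spike * config.spiked_tumor_frequency
    spike_freq_n = config.spiked_tumor_frequency / config.spiked_fold
    spike_mass_n = n_spike * spike_freq_n
    if spike_mass_t >= 0.5:
        raise ValueError("spiked clones would dominate the repertoire")

    nt = config.n_templates
    spike_t = int(round(nt * config.spiked_tumor_frequency))
    spike_n = int(round(nt * spike_freq_n))

    bg_ids = [f"bgclone{i:05d}" for i in range(config.clone_richness)]
    spike_ids = [f"{sample_id}_spike{i}" for i in range(n_spike)]

    def draw(bg_templates: int, spike_count: int) -> pd.DataFrame:
        counts = rng.multinomial(bg_templates, background_p)
        seqs = list(bg_ids)
        cnts = list(counts)
        if spike_count > 0:
            seqs += spike_ids
            cnts += [spike_count] * n_spike
        prod = [True] * len(seqs)
        n_np = max(2, config.clone_richness // 10)
        np_templates = int(round((bg_templates + spike_count * n_spike)
                                 * config.nonproductive_fraction))
        if np_templates > 0:
            np_counts = rng.multinomial(np_templates, np.full(n_np, 1.0 / n_np))
            seqs += [f"npclone{i:04d}" for i in range(n_np)]
            cnts += list(np_counts)
            prod += [False] * n_np
        df = pd.DataFrame({"sequence": seqs, "templates": cnts, "productive": prod})
        return df[df["templates"] > 0].reset_index(drop=True)

    bg_t = nt - spike_t * n_spike
    bg_n = nt - spike_n * n_spike
    tumor = Repertoire(sample_id=sample_id, clones=draw(bg_t, spike_t))
    normal = Repertoire(sample_id=f"{sample_id}_N", clones=draw(bg_n, spike_n))
    return tumor, normal


def generate_mutation_neoantigen(config: CohortConfig, truth: pd.DataFrame,
                                 rng: np.random.Generator) -> pd.DataFrame:
    """Nonsynonymous counts and observed neoantigens with a planted editing effect.

    x is drawn from a two-component (hypermutated / non-hypermutated)
    lognormal mixture, redrawn while below the expectation model's zero
    crossing so E(x) > 0 for every sample.  Observed neoantigens are
    ``max(0, round(E(x) * m + noise))`` with m = ``editing_strength`` for
    edited samples and 1 otherwise.
    """
    config.validate()
    model = ExpectedNeoantigenModel()
    floor = int(np.ceil(model.zero_crossing)) + 1
    n = len(truth)
    hyper = rng.random(n) < config.hypermutated_fraction
    edited = rng.random(n) < config.editing_fraction

    x = np.empty(n, dtype=int)
    for i in range(n):
        mu = config.hyper_log_mean if hyper[i] else config.nonhyper_log_mean
        draw = 0
        while draw < floor:
            draw = int(round(np.exp(rng.normal(mu, config.mutation_log_sd))))
        x[i] = draw

    expected = model.expected(x)
    m = np.where(edited, config.editing_strength, 1.0)
    observed = np.maximum(
        0, np.round(expected * m + rng.normal(0, config.neoantigen_noise_sd, n))
    ).astype(int)

    out = pd.DataFrame(
        {
            "nonsynonymous_count": x,
            "observed_neoantigens": observed,
            "true_hypermutated": hyper,
            "true_edited": edited,
        },
        index=truth.index,
    )
    return out


def generate_microbiome_survival(config: CohortConfig, truth: pd.DataFrame,
                                 rng: np.random.Generator):
    """Genus compositions with planted prognostic taxa, and PH survival times.

    Designated taxa receive per-sample standard-normal log-scale
    perturbations of their Dirichlet concentration; those perturbations are
    the taxon truth variables entering the log-hazard.  Survival is
    exponential (constant baseline hazard scaled so the median at zero
    log-hazard is ``baseline_median_years``) with independent uniform
    censoring at rate ``censoring_rate`` and administrative censoring at
    ``follow_up_years``.
    """
    config.validate()
    n = len(truth)
    taxa = [f"g__Taxon{i:03d}" for i in range(config.n_taxa)]
    n_risk, n_prot = config.n_risk_taxa, config.n_protective_taxa
    signs = pd.Series(0, index=taxa, dtype=int)
    risk_taxa = taxa[:n_risk]
    prot_taxa = taxa[n_risk:n_risk + n_prot]
    signs[risk_taxa] = 1
    signs[prot_taxa] = -1

    base = np.exp(rng.normal(0.0, 1.0, size=config.n_taxa))
    # designated taxa get a solidly detectable baseline share
    floor_conc = np.quantile(base, 0.75)
    base[: n_risk + n_prot] = np.maximum(base[: n_risk + n_prot], floor_conc)
    conc = config.dirichlet_concentration * base / base.sum()

    perturb = rng.normal(0.0, 1.0, size=(n, n_risk + n_prot))
    comp = np.empty((n, config.n_taxa))
    for i in range(n):
        alpha = conc.copy()
        alpha[: n_risk + n_prot] *= np.exp(perturb[i])
        comp[i] = rng.dirichlet(alpha)
    abundance = pd.DataFrame(comp, index=truth.index, columns=taxa)

    # the hazard reads the realized (z-scored) abundance of the designated
    # taxa, so a linear risk model over standardized abundances is the
    # correctly specified target
    designated = comp[:, : n_risk + n_prot]
    z = (designated - designated.mean(axis=0)) / designated.std(axis=0, ddof=1)

    hc = config.hazard_coefficients
    levels = truth["true_icr_level"].map({"Low": 0, "Medium": 1, "High": 2}).to_numpy()
    lp = (
        hc.get("icr", 0.0) * levels
        + hc.get("edited", 0.0) * truth["true_edited"].to_numpy(float)
        + hc.get("risk_taxon", 0.0) * z[:, :n_risk].sum(axis=1)
        + hc.get("protective_taxon", 0.0) * z[:, n_risk:n_risk + n_prot].sum(axis=1)
    )

    base_rate = np.log(2.0) / config.baseline_median_years
    t_event = rng.exponential(1.0, size=n) / (base_rate * np.exp(lp))
    censored = rng.random(n) < config.censoring_rate
    c_time = rng.uniform(0.0, t_event)  # uniform on (0, T) for censored cases
    time = np.where(censored, c_time, t_event)
    event = (~censored).astype(int)
    over = time > config.follow_up_years
    time = np.where(over, config.follow_up_years, time)
    event = np.where(over, 0, event)
    time = np.maximum(time, 1e-6)

    survival = pd.DataFrame({"time": time, "event": event}, index=truth.index)
    truth_out = truth.copy()
    truth_out["true_linear_predictor"] = lp
    return abundance, survival, truth_out, signs


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full linked cohort bundle from one config and seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    expr, truth = generate_expression(config, rng)
    mutations = generate_mutation_neoantigen(config, truth, rng)
    truth = truth.join(mutations[["true_edited"]])
    abundance, survival, truth, taxa_signs = generate_microbiome_survival(config, truth, rng)

    tcr_missing = config.missing_assay_fractions.get("tcr", 0.0)
    n_missing = int(np.ceil(tcr_missing * config.n_samples))
    missing = set(rng.choice(truth.index.to_numpy(), size=n_missing, replace=False)) if n_missing else set()
    repertoires = {}
    for sample in truth.index:
        if sample in missing:
            continue
        repertoires[sample] = generate_repertoire_pair(
            config, sample, truth.loc[sample, "true_icr_level"], rng
        )

    return Cohort(
        config=config,
        expression=expr,
        repertoires=repertoires,
        mutations=mutations.drop(columns=["true_edited", "true_hypermutated"]),
        abundance=abundance,
        survival=survival,
        truth_samples=truth,
        truth_taxa=taxa_signs,
    )


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write the cohort bundle as the plain-text formats the analysis reads."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    cohort.expression.to_csv(out / "expression.tsv", sep="\t", float_format=fmt)
    cohort.abundance.to_csv(out / "abundance.tsv", sep="\t", float_format=fmt)
    cohort.mutations.to_csv(out / "mutations.csv")
    cohort.survival.to_csv(out / "survival.csv", float_format=fmt)
    cohort.truth_samples.to_csv(out / "ground_truth_samples.csv", float_format=fmt)
    cohort.truth_taxa.rename("risk_sign").to_csv(out / "ground_truth_taxa.csv")
    tcr_dir = out / "tcr"
    tcr_dir.mkdir(exist_ok=True)
    for sample, (tumor, normal) in cohort.repertoires.items():
        tumor.clones.to_csv(tcr_dir / f"{sample}_tumor.tsv", sep="\t", index=False)
        normal.clones.to_csv(tcr_dir / f"{sample}_normal.tsv", sep="\t", index=False)
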