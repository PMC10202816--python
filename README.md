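# micoprog

Multi-omics prognostic integration for colon cancer cohorts: immune
transcriptomics, TCR repertoires, somatic immunoediting, and the tumor
microbiome, tied together by shared survival machinery.

## What it computes

Colorectal tumors with an active Th1/cytotoxic microenvironment, evidence
of immune-mediated neoantigen depletion, and a favorable tumor microbiome
have markedly better outcomes. `micoprog` implements the computations
behind that kind of analysis as a tested, reusable pipeline:

- **ICR score and immune subtypes** — the mean log2 expression of the
  20-gene Immunologic Constant of Rejection signature, and Low/Medium/High
  subtypes from resampling consensus clustering (Ward inner linkage,
  complete outer linkage on `1 − consensus`, cluster number by the
  Calinski–Harabasz criterion), plus generic ssGSEA-style single-sample
  enrichment.
- **TCR repertoire metrics** — Shannon entropy `H = −Σ p log2 p` over
  productive clones, Pielou evenness `J = H / log2 S`, clonality `1 − J`,
  and tumor-enriched clone calling (> 0.1% tumor frequency and ≥ 32-fold
  over matched normal).
- **Somatic editing** — nonsynonymous variant filtering (VAF ≥ 5%,
  depth > 3, population AF ≤ 1%), TMB over a 40 Mb capture with
  hypermutation at > 12/Mb, MSI labeling (instability score > 0.4),
  neoantigen calling (mutant < 500 nM, wild-type > 500 nM), the genetic
  immunoediting ratio `GIE = O / E(x)` with
  `E(x) = −2.38770 + 0.09171·x`, and the 4-level IES composite of ICR ×
  GIE.
- **Microbiome profiling** — compositional closure, the 10%-prevalence /
  1%-abundance genus filter, alpha diversity (observed, Chao1, Shannon,
  inverse Simpson), taxa harmonization, and paired tumor/normal
  differential abundance with BH FDR.
- **The MBR risk signature** — a relaxed elastic-net Cox model over
  z-scored genus abundances, tuned by 5-fold cross-validated Harrell
  concordance over a (relaxation γ, penalty λ) grid; scores transfer to
  new cohorts using the training standardization and binarize at 0
  (negative = low risk).
- **mICRoScore** — high only for samples that are both ICR-high and
  MBR-low; plus Kaplan–Meier / log-rank / Cox reporting, the adjusted
  multivariable biomarker comparison (age, stage, MSI, CMS), and a
  density-matched cohort-subsampling experiment.

A synthetic-cohort generator (`micoprog.synthetic`) plants all of this
structure — ICR groups, clonality targets, an editing effect, prognostic
taxa, proportional-hazards survival — with known ground truth, so every
stage is testable end to end without any external data.

## Worked example

```python
import pandas as pd
from micoprog.synthetic import CohortConfig, generate_cohort
from micoprog.icr import consensus_cluster, assign_icr_labels
from micoprog.mbr import train_mbr, score_mbr
from micoprog.integrate import build_cohort_table, survival_by_group_report

cohort = generate_cohort(CohortConfig(seed=7))

clusters = consensus_cluster(cohort.expression, n_reps=250, seed=7)
icr = assign_icr_labels(clusters, cohort.expression)

model = train_mbr(cohort.abundance, cohort.survival, seed=7)
mbr = score_mbr(model, cohort.abundance)

table = build_cohort_table(cohort.survival, icr=icr, mbr=mbr)
report = survival_by_group_report(cohort.survival, table["micro_score"])
```

With seed 7 this prints a three-cluster solution (82 samples per ICR
group), a 12-genus MBR classifier with cross-validated concordance 0.771,
and a 40-sample mICRoScore-high group:

```
chosen k: 3
classifier size: 12   cv concordance: 0.771
S(5y | mICRoScore low)  = 0.653
S(5y | mICRoScore high) = 1.000
log-rank chi2 = 23.73, p = 1.1e-06
```

The mICRoScore-high subgroup — immune-active tumors with a low-risk
microbiome — shows near-perfect five-year survival against 65% in the
rest of the cohort (hazard ratio 0.099, 95% CI 0.031–0.312), which is the
planted behavior the generator encodes and the pipeline recovers.

The same flows are available from the shell:

```sh
micoprog simulate --seed 7 --out cohort/
micoprog icr --expr cohort/expression.tsv --out icr_out/
micoprog tcr summarize cohort/tcr/S0000_tumor.tsv --out tcr.csv
micoprog mbr train --table cohort/abundance.tsv --survival cohort/survival.csv --model mbr.tsv
```

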