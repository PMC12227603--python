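# ctcflow

Re-assessment of HER2 status in metastatic gastric cancer from circulating
tumor cells (CTCs), built as a tested analysis pipeline: flow-cytometry
event gating, a Gaussian-intersection HER2 positivity cutoff, the
cytokeratin/vimentin EMT-index, cohort statistics, and mutation-landscape
set comparisons.

## The problem

HER2-positive gastric cancer is treatable with trastuzumab, but HER2 status
is conventionally read from tumor tissue, which undersamples a
heterogeneous disease: patients whose tissue is HER2-negative can still
carry HER2-expressing CTCs in peripheral blood, and those patients fare
worse without targeted therapy. This package implements the computational
side of a CTC-based re-assessment: who is HER2-positive by blood even when
tissue says otherwise, how that relates to epithelial–mesenchymal
transition (EMT), and how the resulting patient groups differ.

## The core quantities

* **CTC definition (gating).** Events are five-channel fluorescence
  measurements (Hoechst/nuclei, FITC-cytokeratin, PE-vimentin,
  PE-Cy7-CD45, AF647-HER2). After spillover compensation
  (`measured = true · S`, estimated from single-stain controls), a
  four-round sort cascade retains nucleated, cytokeratin-positive,
  CD45-negative events — the CTCs.
* **HER2 positivity cutoff.** Two control cell lines give Gaussian
  intensity models (negative: μ₁ = 50, σ₁ = 23.7; positive: μ₂ = 76,
  σ₂ = 46.1). The decision boundary is the variance-weighted crossover

  T = (μ₁σ₂² + μ₂σ₁²)/(σ₁² + σ₂²) = 55.44 → cutoff **> 56**

  (ceiling to the next integer; strict comparison).
* **EMT-index.** vim/(ck + vim) ∈ [0, 1]; 0 fully epithelial, 1 fully
  mesenchymal.
* **Groups.** A = tissue HER2-positive (A′ = subset with CTC data);
  B = tissue-negative but CTC HER2-positive; C = negative in both. Tissue
  status follows the IHC/FISH rule (0/1+ negative; 3+ positive; 2+ resolved
  by FISH ratio > 2.0).
* **Statistics.** Concordance, Spearman correlation, Kruskal–Wallis and
  pairwise rank tests, Kaplan–Meier curves with a k-sample log-rank test,
  chi-square association, and set algebra over binary gene × sample
  mutation matrices (three-group Venn partitions, CTC-vs-tissue
  comparisons, EMT-gene annotation).

## Worked example

The packaged 23-patient cohort table drives the default pipeline:

```sh
ctcflow cohort --out results
```

prints

```
HER2 positivity cutoff: > 56 (raw crossover 55.4352)
Patients: 23  groups A=9 (A'=9) B=8 C=6
Tissue/CTC concordance: 13/23 (57%)
Spearman rho (HER2 intensity ~ EMT-index): 0.765
Median CTC count: 9   median EMT-index: 0.17
  EMT-index A': median 0.180 (0.15-0.23), n=9
  EMT-index B: median 0.175 (0.16-0.25), n=8
  EMT-index C: median 0.150 (0.14-0.16), n=6
```

Reading: 8 of 23 patients are HER2-positive only by blood (group B) — the
candidates a tissue-only assessment would miss; HER2 intensity and
EMT-index are strongly rank-correlated (ρ = 0.765); group C sits at a
visibly lower EMT-index than A′ and B.

The numbered scripts under `analysis/` run each stage as a narrative:
`01_threshold.py` (cutoff derivation), `02_cohort_statistics.py` (the
report above plus Kruskal–Wallis/pairwise p-values),
`03_gating_simulation.py` (spillover estimation, compensation and planted
CTC recovery at 10⁵ events), `04_survival_simulation.py` (Kaplan–Meier and
log-rank on simulated cohorts), `05_mutation_landscape.py` (Venn partition
and CTC-vs-tissue comparison on a simulated mutation matrix). Each writes
its tables to `results/`.

Other CLI subcommands: `simulate`, `gate`, `classify`, `landscape`,
`report` (see `ctcflow <cmd> --help`).

## Layout

```
src/ctcflow/      library (gating, her2, cohort, landscape, synthetic, io, pipeline, cli)
analysis/         numbered narrative drivers
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   models, assumptions, parameter choices, limitations
```
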