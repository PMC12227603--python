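# Methods

This note records the models behind `ctcflow`, the parameter choices that
matter, and what the synthetic data do and do not establish.

## Flow-cytometry model and compensation

Events live on five channels (Hoechst, FITC-cytokeratin, PE-vimentin,
PE-Cy7-CD45, AF647-HER2) in arbitrary fluorescence units. The measurement
model is linear mixing on top of an autofluorescence floor:

    measured = baseline + stain · S,

where `S` is the spillover matrix (unit diagonal; `S[j,k]` = fraction of
channel-j stain read in channel k). Compensation solves `c · S = m` as a
linear system — never by forming `S⁻¹` explicitly — and refuses matrices
with condition number above 10⁸. When baselines are supplied they are
subtracted before unmixing and restored afterwards, so only the stain
component is unmixed; without baselines the contract is the bare linear
round trip, exact to ~10⁻⁹ relative error for condition numbers below 10³.

Spillover is estimated from single-stain controls as the ratio of median
off-channel signal above baseline to median on-channel signal above
baseline, clipped below at zero. Medians rather than means keep a handful
of aberrant events from skewing the estimate; a control whose on-channel
median does not exceed baseline is rejected as degenerate.

## The sort cascade

A CTC is a nucleated, cytokeratin-positive, CD45-negative event surviving
four sequential sorting rounds (CK⁺ enrichment twice, then the full
nuclei⁺/CK⁺/CD45⁻ gate twice). Gates are strict inequalities — boundary
events are excluded. Numeric cutoffs are not part of the assay definition
(only "positive"/"negative" channels are), so they are configuration
parameters; defaults (CK > 40, CD45 < 40, Hoechst > 50) sit at the
geometric midpoints between the simulated population modes, and
`suggest_cutoff` places a gate for real data by fitting a two-component
Gaussian mixture on log-intensity and splitting the component means. The
physical re-collection between sorts is modeled as an optional per-round
Bernoulli carryover loss, default 0 (no recovery efficiency is published).

With the default populations the gated channels are separated by ≥ 4
log-scale standard deviations, which makes planted-CTC recall and precision
≥ 0.99 at 10⁵ events; that is a property of well-separated populations, not
a guarantee for marginal real-world separations.

## HER2 cutoff and EMT-index

The positivity boundary comes from two control cell-line Gaussians
(negative: μ₁ = 50, σ₁ = 23.7; positive: μ₂ = 76, σ₂ = 46.1) via the
variance-weighted crossover T = (μ₁σ₂² + μ₂σ₁²)/(σ₁² + σ₂²) = 55.435,
rounded **up** to the integer cutoff 56 and applied strictly
(intensity > 56 ⇒ positive). Two deliberate caveats:

* the weighted-mean formula is *not* the exact intersection of two
  unequal-variance Gaussian densities (that solves a quadratic); the
  published rule is implemented as printed and not "corrected";
* ceiling (not nearest-integer rounding) is what reproduces the operating
  cutoff of 56 from 55.435; the choice is logged whenever it differs from
  the nearest integer.

Per-patient HER2 status is classified from the *mean* HER2 intensity over
the final CTC events; a per-event positive fraction is available for
exploration but never drives classification. The per-patient EMT-index is
vim/(ck + vim) applied to the per-patient mean CK and VIM signals (one
index per patient); computing per-event indices and averaging is also
possible but the signal-mean form is canonical.

## Cohort statistics

Tissue HER2 follows the IHC/FISH consensus rule (0/1+ negative, 3+
positive, 2+ resolved by FISH ratio strictly > 2.0). Groups: A =
tissue-positive (A′ = the CTC-measured subset, so either stratification is
reproducible), B = tissue-negative/CTC-positive, C = negative in both; a
tissue-negative patient without CTC data is rejected as unclassifiable
rather than guessed. Concordance is computed over patients with both
statuses, with percent reported by round-half-up (13/23 → 57).

Standard machinery is delegated: Spearman/Kruskal–Wallis/Mann–Whitney/
chi-square to `scipy.stats`, Kaplan–Meier and the k-sample log-rank test to
`lifelines`. Conventions: Kruskal–Wallis on all-identical data returns
(H = 0, p = 1); the KM median is the smallest observed time with survival
≤ 0.5, reported as "not reached" when the curve never gets there; the
pairwise contrast is a two-sided Mann–Whitney (the original pairwise
procedure is unspecified); the three-curve PFS comparison uses the log-rank
test (likewise unnamed at source); no multiplicity correction is applied by
default, with Holm available as an option. Group medians are kept at full
precision (group B's eight EMT values have median 0.175) with a 2-decimal
display rendering.

## Synthetic data

The generators define the study conditions for every stage whose raw data
are unpublished. One integer seed drives everything; all internal streams
derive from it, so identical (spec, seed) gives byte-identical outputs.

* **Events.** Log-normal stain signals per channel (flow intensities are
  positive and right-skewed) on a baseline of 5 units, mixed through a
  spillover matrix with mild cross-talk between spectrally adjacent
  fluorophores (FITC→PE 12%, PE→PE-Cy7 6%, PE→FITC 3%, PE-Cy7→AF647 2%).
  Leukocytes: Hoechst 500, CK 4, VIM 80, CD45 400, HER2 4 (medians); CTCs:
  CK 400, CD45 4, HER2 and VIM set by the scenario. Log-scale SD 0.45
  everywhere. No doublets, debris, or scatter channels are modeled.
* **Cohorts.** Group weights 13:8:6 over A/B/C. Per-group log-normal mean
  HER2 intensity, truncated above the cutoff for group B and at-or-below it
  for group C, so CTC status is group-consistent by construction; logit-
  normal EMT-index with medians 0.18/0.175/0.15; exponential PFS with
  hazards ln2/15.7, ln2/7.0 and ln2/40 per month (group C's median lies
  beyond typical follow-up, i.e. "not reached"); censoring is uniform
  administrative, C ~ U(0, W) with W solved per group so the expected
  censored fraction is 25%; CTC counts are a shifted negative binomial with
  mean 9 (support ≥ 1); 4/13 of group-A patients carry no CTC measurement,
  mirroring sampling after therapy start. HER2 and EMT are coupled through
  a Gaussian copula at target Spearman ρ = 0.765 using the exact bivariate-
  normal map r = 2 sin(πρ/6).

  A subtlety worth recording: pooled Spearman correlation equals the copula
  target only when every patient shares one marginal transform. The group-
  dependent marginals (and in particular the B/C truncation at the cutoff)
  are each monotone *within* group, so the coupling is exact per group but
  attenuated when groups are pooled. Coupling-recovery checks therefore run
  on a single-group untruncated cohort, where recovery at n = 2000 is
  within ±0.05 for targets in {−0.5, 0, 0.5, 0.765}. Under the default
  three-group conditions the pooled correlation lands near 0.78 — the group
  separation itself restores concordance — which is why the end-to-end
  pipeline recovery also holds.

  The per-event distribution of HER2 signal within a patient's CTCs is a
  modeling choice (log-normal); only per-patient summaries are published.
* **Mutation matrices.** Independent Bernoulli calls per gene × sample.
  The default model's gene compartments echo the observed three-group Venn
  structure (6 genes in all groups, 5 shared by A and B, 9 private to A, 5
  private to B) with rates 0.35/0.40/0.65 for the groups' eligible genes —
  chosen so per-sample counts center near medians 7/6.5/4 — and a 0.85
  multiplier for tissue samples. Real per-sample calls exist only as a
  published heat-map figure and are deliberately not transcribed
  (figure-read values are unreliable); the set algebra is validated against
  hand-enumerated toys and a per-gene bit-mask oracle instead.

Passing tests on these generators show that the *pipeline* recovers what it
is fed under the stated laws; they do not certify instrument noise models,
doublet behavior, or real-world population separations.

## Problem sizes and numerical choices

Simulation scales were chosen to keep every check cheap while leaving
comfortable statistical margins: 10⁵ events for gating recall/precision,
n = 2000 cohorts for coupling recovery (±0.05), 10 × n = 500 cohorts for
the KM closed-form check (the mean of replicate medians damps the ~0.45-
month sampling noise of a single median), 1000 replicates for log-rank and
Kruskal–Wallis null calibration (type-I error in [0.03, 0.07] at α = 0.05),
and 200 replicates for planted-rate ordering (≥ 95%). Compensation
tolerances: 10⁻⁹ relative round-trip error below condition number 10³;
refusal above 10⁸.

## Known limitations

* No FCS file reading; events are exchanged as CSV. Channel-mapped FCS
  ingestion would bolt onto `read_events_csv`'s contract.
* No Cox regression, covariate adjustment, or interval censoring; no
  variant calling or annotation (matrices are consumed post-calling).
* Tissue-rule and cutoff conventions at boundaries (FISH ratio exactly 2.0
  → negative; intensity exactly at cutoff → negative) follow the strict
  inequalities of the published rules; real assays may differ at ties.
* Documented source-data caveats are preserved, not fixed: the cohort
  table's EMT range (0.14–0.25) differs from the prose range (0.15–0.24),
  group B's median EMT-index is 0.175 against a printed 0.17, and two
  different group-A median PFS values appear in different sections.
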