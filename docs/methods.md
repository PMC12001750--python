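# Methods

This note documents the statistical models, the defaults and why they
were chosen, the synthetic-data generator's assumptions, and the known
limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Fragmentation-signature classifier

**Premise.** Tumor-derived cfDNA is shorter than normal cfDNA. A
single-primer-pair repeated-element assay observes fragment length only
through amplifiability: loci with short expected inserts gain read
share when fragments shorten. The classifier therefore works on
relative amplicon representation, never absolute depth.

**Stage 1 — amplicon filtering.** On training *controls* only, counts
are depth-normalized per sample and each amplicon is tested for a batch
effect (Kruskal–Wallis across batch labels, Benjamini–Hochberg FDR,
drop at q < 0.05), and dropped regardless if its median normalized
count falls below 10% of the median over amplicons (this floor also
removes all-zero amplicons). Both the statistic and the floor are this
package's concrete choices for the filtering contract; requiring ≥2
batches with ≥3 controls each makes the test defined, and a single
batch raises an error telling the caller to skip filtering explicitly
rather than silently doing nothing.

**Stage 2 — per-arm signatures.** Counts are renormalized within each
chromosome arm (each sample's arm profile sums to 1; acrocentric short
arms carry no usable loci and are excluded from panels by default).
Each arm's samples × amplicons matrix is factorized by NMF with
Frobenius loss, coordinate-descent updates, deterministic
non-negative-SVD (nndsvda) initialization, tolerance 1e-6, ≤500
iterations. The amplicon-side factor is column-normalized so each
signature is a probability distribution over the arm's amplicons.
Sample exposures are recomputed by non-negative least squares against
the signature dictionary — the same projection at train and score time,
so a new sample is treated exactly like a training sample. A single
shared signature count k is used for all arms; it is chosen by
stratified cross-validation as the smallest k whose pooled out-of-fold
sensitivity at the target specificity is within ε = 0.01 of the best
over the grid ("plateau" rule).

**Stage 3 — fragmentation-consistent selection.** Each signature's
insert-length centroid (expected insert length under the signature's
distribution) is compared with the panel median. A signature is kept
iff (centroid below median AND exposures higher in cancer) or
(centroid above median AND exposures lower in cancer), by one-sided
Mann–Whitney tests at BH q < 0.1. This encodes the direction the
biology dictates and discards dimensions that merely separate classes
by batch or noise. If nothing is selected the pipeline falls back to
all signatures with a warning, so scoring stays defined.

**Stage 4 — scoring and threshold.** A Gaussian-kernel SVM (C = 1,
γ = scale) on standardized selected exposures. The sigmoid (Platt) map
is fitted on *out-of-fold* margins from a stratified 5-fold split, and
the positivity threshold is the out-of-fold control-score quantile at
the target specificity — both choices prevent training-set optimism
from leaking into the specificity calibration.

## Threshold calibration

With n controls and target specificity s, m = ⌈n(1−s)⌉ exceedances are
allowed and the threshold is the (n−m)-th order statistic of the
control scores; s = 1 returns the maximum. The held-out false-positive
rate of such a threshold is itself random: approximately
Beta(m+1, n−m), mean ≈ m/(n+1), on top of binomial sampling in the
held-out set. Calibration tests therefore use an acceptance bound of
the compound mean plus three compound standard deviations, computed
from the actual n's — not a tuned constant. Fewer than 1/(1−s)
controls trigger a warning (the quantile is then coarse).

## Global aneuploidy score

Features are per-arm fractions of total counts expressed as z-scores
against training-control means/SDs (39 autosomal arms on a real panel;
sex arms excluded to avoid sex confounding — the feature construction
is this package's stand-in for an unpublished original). Because
fractions are used, the score is depth-invariant. Training augments
real controls and cancers with in-silico aneuploid samples: a control's
counts on 1–5 random arms are multiplied by 1 + t/2 (single-copy gain)
or 1 − t/2 (loss) for t ∈ {0.01, 0.02, 0.05, 0.1, 0.2}, then
multinomially re-sampled to the original depth. In-silico samples are
regenerated inside each cross-validation fold from that fold's controls
only: an aneuploid twin shares its source control's noise realization,
and generating twins before the split would leak held-out controls into
training (this was observed and fixed during development).

## Protein-17 score

log10(x+1) transform, per-analyte standardization with training
statistics, Gaussian-kernel SVM with out-of-fold Platt calibration,
threshold at the control quantile. The model family is this package's
stand-in for the original unpublished pipeline; the analyte list and
the 99.5%-specificity thresholding are the fixed parts of the
contract. The model stores the canonical analyte order, so scoring is
invariant to input column order; missing analytes are an error, not
imputed.

## Multi-well mutation statistic

Per qualifying well (total reads ≥ 100), MAF = mutant/total; the
per-mutation pooled MAF is Σmutant/Σtotal. The background pool holds
well-level MAFs from two sources: variants observed in the patient's
plasma amplicons that are absent from the adenoma tissue, and all
variants of a matched no-cancer control run over the same amplicons
(≥50 pooled values required). The per-mutation score is −log of the
add-one empirical tail probability of the pooled MAF under the pool,
(1 + #{pool ≥ maf})/(pool+1) — never zero, capped at log(pool+1). The
aggregate is the Fisher-style sum of mutation scores.

The null distribution assumes every target MAF is background. Because
sequencing error is strongly position-specific, each target's null rate
is drawn from the Jeffreys Beta posterior of that same variant's
control-run counts (the control run exists precisely to provide a
variant-matched background measurement), and a pooled mutant count is
drawn binomially at the mutation's observed total depth;
p = (1 + #{null ≥ observed})/(n_null + 1), positive iff p < 0.01.
Two alternatives were evaluated and rejected during development:
resampling pooled background-variant rates is anti-conservative (a
target whose error rate exceeds the finite pool's maximum always looks
extreme), and adding the observed targets to the resampling pool
(permutation exchangeability) is calibrated but caps power at rank
granularity (with one mutation and ~60 background variants, p can
never reach 0.01). The matched-posterior null is both calibrated and
powered; its residual conservatism comes from posterior width, which
is why the control run is sequenced deeper than each patient run (4×
by default in the generator).

## Evaluation layer

Positivity at thresholds 0.78 (fragmentation), 0.71 (aneuploidy), 0.96
(protein); two comparison modes: `raw_strict` (score > threshold, for
full-precision scores) and `printed_rounded` (two-decimal score ≥
threshold, required when re-scoring tables published at two decimals,
where a rounded tie counts as positive). Combinations are
any-positive; missing member calls count negative with a warning.
Wilson score 95% intervals (no continuity correction, z = 1.959964)
for all proportions. Case subgroups are mutually exclusive in priority
order — HGD (any size), then ≥2 cm, then ≥1–<2 cm — an inference
verified by the packaged cohort, whose subgroup sizes 8/19/13 sum to
the 40 cases. Literature comparator estimates apply published stool-
test subgroup sensitivities (FIT 46/42/21%, stool-DNA 69/68/38%,
next-generation stool-DNA 74.6/68/38%) to this cohort's subgroup
sizes, rounding each expected count to the nearest integer.
Percentages are rounded half-away-from-zero to one decimal. Two cells
of the published combination table are reproduced from the per-case
scores rather than as printed: one cell is internally inconsistent
with its own component row (an OR-combination cannot be less sensitive
than a member assay), and two cells were printed at truncated rather
than rounded precision. Mutation calls are excluded from combinations
(known-mutation tracking has no screening analogue).

Duplicate-aliquot reproducibility is the Pearson correlation of
log-scale scores, floored at 0.01 — the two-decimal resolution at which
scores are reported. Without the floor a single near-zero calibrated
score dominates the correlation through unbounded log leverage.

## Synthetic-data generator

What it emulates, per sample: baseline amplicon propensities
(log-normal, σ = 0.5) with per-batch multipliers (log-normal,
σ = 0.05); negative-binomial counts with dispersion 0.1 (variance
m + 0.1m²; amplicon assays are over-dispersed, and this puts a CV
floor of √0.1 ≈ 32% on every amplicon regardless of depth); a latent
tumor fraction t that mixes in a tumor component whose within-arm
amplicon weights are tilted toward short inserts by exp(−β(L−L_min))
and whose altered arms (1–3 of 10) are multiplied by 1 ± t/2; a
per-subject fragmentation state (tilt with SD 0.012/bp) shared between
replicate aliquots; log-normal protein baselines with case elevations
on 6 of 17 analytes; and the partitioned well assay (95 wells, ≤300
genome equivalents, per-variant log-normal error rates shared with the
matched control run).

Key defaults and their rationale:

| parameter | default | units | why |
|---|---|---|---|
| arms × amplicons/arm | 10 × 900 | — | arm-fraction CV ≈ 1.5%, scaled toward the real assay's ~9000 loci/arm; smaller panels drown arm-dosage signal in counting noise |
| depth_mean | 200 | reads/amplicon | depth beyond this buys little (dispersion-dominated noise) |
| nb_dispersion | 0.1 | — | over-dispersion typical of amplicon counting |
| beta_frag | 0.16 | per bp | calibrated so tumor fractions ≥5% are detectable at the 99.5% threshold while fractions <2% are not trivially separable |
| host_tilt_sd | 0.012 | per bp | inter-subject fragmentation variation; gives duplicate aliquots reproducibly different scores, mirroring the duplicate-plasma analysis |
| tumor_fraction_range | 0.01–0.2 (log-uniform) | — | cancers; adenoma-like cases default to 0.002–0.05 |
| wells / GE / depth | 95 / 300 / 2000 | — | the partitioned assay's stated geometry |
| error_rate_median, σ | 1e-4, 0.35 | —, log10 | realistic per-position error scale and spread |
| control_depth_factor | 4 | — | the single reference run serves all patients and is sequenced deeper so its estimation error does not dominate the mutation null |

The within-arm application of the fragmentation tilt (arm totals
preserved) is deliberate: fragment-length preference is compositional,
while arm dosage is governed by copy number; applying the tilt
globally creates pseudo-aneuploidy on every arm and entangles the two
assays' signals.

What the generator does **not** emulate: genome sequence content, GC
bias, library-prep chemistry, inter-arm correlation structure,
assay-platform effects in the protein panel, comorbidity-driven
control heterogeneity, or UMI-level sequencing artifacts. Passing
tests on this generator therefore show that the *algorithms* recover
the structure they assume at realistic noise levels — not that the
assays would achieve these operating points on real plasma.

## Problem sizes used in the test suite

Unit tests run on 4–10-arm panels with 40–400 amplicons per arm and
cohorts of ~100 samples. The calibration suite uses 5000 synthetic
controls and 800 cancers (split evenly into training and held-out
halves), 2000 simulated null well-assays with 20 000 Monte-Carlo null
draws each, 100 power simulations, and two independent 100-pair
duplicate-aliquot experiments with paper-scale (330 control / 380
cancer) training cohorts. These sizes keep the full suite within a
few minutes while leaving the binomial acceptance bands meaningful.

## Known limitations

- The original filtering, feature-construction, protein-model, and
  mutation-score procedures are unpublished beyond their contracts;
  every stand-in here is declared as such above.
- The original 706-sample training scores are not reproducible (raw
  counts unpublished); the published thresholds 0.78/0.71/0.96 are
  taken as given when re-scoring the packaged cohort, and the
  package's own calibration machinery is validated on synthetic data
  instead.
- Control-level per-sample scores of the study cohort are unpublished;
  the packaged control rows are synthetic, constrained to the
  published control positivity counts, and are used only where control
  calls (specificity columns) enter.
- `choose_dimension` re-fits the full pipeline per fold and per grid
  point; it is meant for moderate cohorts, not the 5000-sample
  calibration runs.
- The mutation statistic requires a matched control run for a
  calibrated null; without one it falls back to pool resampling, which
  is documented as anti-conservative in the tail.
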