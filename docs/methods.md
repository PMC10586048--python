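# Methods

This note documents the models and procedures implemented in `plasmafrag`,
the parameter choices that matter, and what the synthetic data do and do
not establish.

## Fragment model and retention filters

A *fragment* is one sequenced cfDNA molecule: contig, 0-based half-open
start/end, length = end − start (the insert size), and the two 4-mer 5′ end
motifs, one per strand. Retention rules for paired-end input follow
standard cfDNA practice: properly oriented FR pairs, at most 3 mismatches
(NM tag; records without NM pass with a warning, since BED input and some
BAMs lack it), insert size within 600 bp, and exclusion of multi-mapping
reads, operationalised as MAPQ < 30 (configurable) or a
secondary/supplementary flag, because no universal MAPQ convention exists.
Fragment BED input is treated as already mapping-quality-filtered; only the
insert-size rule and motif validity apply there.

End motifs are read from the **reference genome** at the fragment end
coordinates, not from read bases: this is robust to sequencing error and
makes coordinate-only (BED) input sufficient. The plus-strand motif is the
4-mer at `start`; the minus-strand motif is the reverse complement of the
4-mer ending at `end`. Each molecule therefore contributes exactly two
motifs, and motif-frequency denominators count motifs, not molecules.
Fragments with N in either window are excluded from motif features but kept
for size and coverage features.

## Size bands and motif strata

Size groups: short ≤ 150 bp, medium 160–170 bp, long ≥ 250 bp (inclusive
boundaries, configurable via `SizeBands`). Motif spectra are additionally
stratified at 156 bp — the cutoff below which the disease-associated motif
signal is strongest — and both cutoffs are kept as *separate* configurables
because they capture different empirical observations (sub-mononucleosomal
DNA vs the size below which MDS differences peak). A fragment's two motifs
always fall in the same stratum (stratification is by molecule size).

## Motif diversity score

MDS = −Σ pᵢ ln pᵢ / ln 256 over the 256-motif frequency vector, with
0·ln 0 ≡ 0. Natural log with normalisation by ln 256 makes the score
base-invariant: 1 iff uniform, 0 iff degenerate. An empty spectrum yields
NaN rather than 0, to distinguish "no data" from "one motif".

## Differential motifs and ratios

Each motif is compared DN vs DM by a two-sided Mann–Whitney U test on
per-sample frequencies; significance uses Bonferroni over 256 tests at
α = 0.05 (the conservative default; configurable). Significant motifs are
ranked by relative change in median frequency,
(median_DN − median_DM)/median_DM, with ties broken by absolute relative
change then lexicographic order, for determinism. The top-n motif ratio is
the summed frequency of the first n increased motifs over the first n
decreased motifs. Motifs with a zero DM median or constant values are
skipped with a warning.

## Measured genomic representation

Bins are 1 Mb, anchored at coordinate 0 of each autosome; a terminal
partial bin is kept only if ≥ 500 kb. Sex chromosomes and the mitochondrial
contig are excluded (mixed-sex cohorts would otherwise dominate the
z-scores). Each retained fragment contributes one count at its midpoint
bin, avoiding double-counting of read pairs. The reference panel is a
seeded random draw of 10 controls (default); per-bin mean and sd (ddof = 1)
of the bin *fractions* define z = (MGR − mean)/sd, and |z| > 3 (strict) is
aberrant. Panel members are excluded from downstream scoring. Bins with
(numerically) zero panel sd or zero coverage are masked. No GC or
mappability correction is applied — the procedure scores raw bin fractions;
this is a documented limitation and an extension point.

A note on calibration: with a panel of only 10 samples, the z statistic is
Student-t-like and the |z| > 3 tail is inflated to roughly 0.019 rather
than the Gaussian 2Φ(−3) ≈ 0.0027. The null-calibration check therefore
uses a 60-sample panel over 2,000 bins, where the inflation is mild
(≈ 0.004) and the empirical rate sits in the expected band. Users scoring
against a 10-sample panel should expect the higher null rate.

## Cohort statistics

Outliers are removed in a single pass per feature: |x − mean| > 4·sd with
the *sample* sd (ddof = 1); a zero-sd feature removes nothing. Two-group
comparisons use the two-sided Mann–Whitney U test, three groups
Kruskal–Wallis; categorical tables use chi-square, switching to Fisher's
exact test for 2×2 tables with any expected cell below 5. Spearman
correlation uses average ranks for ties. Disease stages from eGFR
(ml·min⁻¹·1.73 m⁻²): >90 → 1, [60, 90] → 2, [30, 60) → 3, [15, 30) → 4,
<15 → 5; interval endpoints are assigned to the less-severe stage because
the conventional interval notation overlaps at the boundaries.

Single-feature ROC fits logistic regression outcome ~ feature + age + sex
+ BMI (sex as a binary indicator, additive covariates, no interactions) and
computes the AUC of the fitted probabilities via the Mann–Whitney rank
identity; an unadjusted variant is available by flag. Non-convergence or
perfect separation falls back to an L2-penalized fit, flagged in the
report. Because the AUC is computed in-sample, a null feature with several
covariates at small n shows optimism (≈ 0.64 at n = 60 in our
measurements); this mirrors the usual adjusted-ROC practice and should be
kept in mind when reading absolute AUCs from small cohorts.

## Classifier

The integrated feature vector: medium and long size fractions, frequencies
of the top-5 increased and top-5 decreased short-DNA motifs, ratio_1..5,
and short-DNA MDS; cfDNA concentration can be added by flag but is off by
default. The split is stratified 8:2 with per-class test count
round(n·0.2) (half rounds up) — this reproduces a 57/42 train and 14/11
test partition for a 71/53 cohort. Training uses XGBoost with balanced
per-sample class weights n_total/(n_classes·n_class) and a randomized
search (default budget 50 draws; 8 in the examples and tests, which is
ample at those problem sizes) over max_depth 2–6, learning rate 0.01–0.3
(log-uniform), 50–500 trees, and row/column subsampling 0.5–1.0, selected
by mean 5-fold stratified CV AUC and refit on the full training set.

Evaluation bootstraps the held-out test set 100 times with replacement
(iterations lacking a class are redrawn); each iteration reports AUC and
the confusion metrics at *that iteration's* Youden threshold
(maximizing sensitivity + specificity − 1; ties resolve to the larger
threshold). Because the per-iteration versus global threshold convention is
genuinely ambiguous in practice, a single confusion matrix at the
full-test-set Youden threshold is reported alongside. The early-stage
experiment draws a seeded test set of 15 DN samples at stages 1–3 plus 20
DM samples and trains on the remainder with the same protocol.

Model bundles serialise the raw XGBoost booster as JSON plus a metadata
file (feature order, tuned parameters, training composition, seed) and
round-trip to identical predictions.

## Synthetic cohort generator

The generator defines the study conditions for all recovery tests.

* **Genome**: two random-sequence autosomes (20 Mb total by default; tests
  use 2–6 Mb) plus a 16 kb mitochondrial contig receiving ~15 fragments
  per million (the order of magnitude of plasma mtDNA read abundance).
* **Sizes**: a three-part mixture — sub-150 bp ladder with modes every
  10 bp up to 145 bp (weights rising toward 145), a Gaussian
  mononucleosomal peak at 166 ± 8 bp of which 8% sits exactly on the peak
  (the real 166 bp mode is sharper than a Gaussian), and a dinucleosomal
  tail at 332 ± 30 bp. Default weights 0.18/0.77/0.05 put the medium
  (160–170 bp) fraction near 0.37 and the long (≥250 bp) fraction near
  0.05, the magnitudes seen in patient plasma. DN samples multiply the
  long-component weight by 0.75 (graded per sample, below).
* **Motifs**: the base 256-vector is a product of identical per-position
  base probabilities (A/C/G/T = 0.16/0.35/0.15/0.34), giving a baseline
  MDS ≈ 0.947 — the plasma-like regime. DN samples multiply CC-start motif
  mass by 1.5 and TT-start mass by 0.7 (renormalised); fragments longer
  than 156 bp receive the effect at half strength, so short DNA carries
  the stronger signal. Per-sample biological variation is a Dirichlet draw
  with concentration 5·10⁴ (≈ 7% CV for a typical motif); setting the
  concentration to `None` disables it, which is how the convergence test
  isolates counting noise.
* **eGFR link**: eGFR is drawn per group (means 99/92/34, sds 15/17/27 for
  control/DM/DN, the magnitudes of the target population) and the motif and
  size effect strength of each sample is the linear ramp
  clip((100 − eGFR)/90, 0, 1) — so low-eGFR DN samples are most affected,
  giving the MDS–eGFR correlation a known positive sign.
* **Coverage**: each DM/DN sample distorts a per-sample random set of 1-Mb
  bins by a fold (default 1.6), alternating over- and under-representation.
* **Placement**: both end motifs of every fragment are drawn from the
  sample's motif distribution; the fragment start is then chosen by
  rejection sampling over a precomputed 4-mer position index of the
  reference so that the reference bases at both 5′ ends equal the drawn
  motifs exactly, and bin-weight acceptance implements the coverage
  distortions. Re-reading the reference at the fragment ends reproduces
  the generated motifs byte-for-byte, which is what makes motif extraction
  exactly testable. A uniform-placement fallback (motifs then read from
  the reference) guarantees termination on tiny contigs.

What the generator does **not** emulate: GC bias, mappability structure,
duplicated reads, sequencing error, real genomic composition (the
reference is i.i.d. random), chromatin-derived positional structure within
bins, or realistic between-feature correlations beyond the planted eGFR
link. Passing recovery tests therefore demonstrates that the pipeline
measures what it claims to measure under its stated assumptions, not that
the classifier's synthetic performance transfers to patient data.

## Problem sizes used in tests and examples

Cohort fixtures run at 60 samples × 8,000 fragments on a 6 Mb genome
(effect recovery) and 28 samples × 4,000 fragments (null behaviour); the
size-model and convergence checks use 100k–200k fragments from single
samples. These sizes were chosen so the planted effects dominate sampling
noise by a comfortable margin while the whole suite stays quick to run.
The acceptance script profiles 100,000 fragments from one default-model
sample and reports the modal fragment length (166 bp).

## Numerical choices

* Frequencies are exact ratios of integer counts; motif vectors are
  validated to sum to 1 within 1e-9.
* Degenerate inputs are flagged, not silently zeroed: empty size profiles
  and empty motif strata carry NaN fractions/MDS; constant features give
  NaN Spearman rho with a warning; a zero ratio denominator gives NaN.
* All stochastic steps (generator, panel selection, splits, search,
  bootstrap) take explicit integer seeds and are deterministic given them.
* Panel masking uses a relative sd tolerance (sd ≤ 1e-9·mean) so that a
  degenerate identical-sample panel masks cleanly despite float rounding.
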