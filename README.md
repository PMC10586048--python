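# plasmafrag

Plasma cell-free DNA (cfDNA) fragmentomics for liquid-biopsy research, with
a focus on separating diabetic nephropathy (DN) from uncomplicated diabetes
mellitus (DM). The package provides a tested implementation of the full
analysis chain — aligned fragments in, classifier performance out — plus a
synthetic cohort generator so that every stage can be exercised and
validated without access to restricted patient sequencing data.

## What it computes

For each plasma sample, starting from aligned paired-end fragments (BAM/SAM
or fragment BED) and a reference FASTA:

* **Size profile** — fragment-length histogram and the fractions of short
  (≤150 bp), medium (160–170 bp, the mononucleosomal peak at 166 bp) and
  long (≥250 bp) DNA.
* **End-motif spectrum** — the frequency of each of the 256 4-mers at the
  5′ end of each strand, overall and stratified at 156 bp, and the motif
  diversity score

  MDS = −Σᵢ pᵢ ln pᵢ / ln 256,  pᵢ = frequency of motif i,

  which is 1 for uniform motif usage and 0 when one motif dominates. Kidney
  damage shifts cfDNA ends toward "CC"-start motifs (a DNASE1L3 cleavage
  signature), lowering the MDS of short DNA.
* **Differential motifs and motif ratios** — per-motif Mann–Whitney
  comparison of DN vs DM, and ratio_n = Σᵢ₌₁ⁿ f(upᵢ) / Σᵢ₌₁ⁿ f(downᵢ) over
  the top-n increased/decreased motifs.
* **Measured genomic representation (MGR)** — the fraction of fragments in
  each 1-Mb bin, z-scored against a reference panel of 10 random control
  samples; bins with |z| > 3 are aberrant.
* **Cohort statistics** — mean ± 4 sd outlier exclusion, Mann–Whitney /
  Kruskal–Wallis group tests, Spearman correlation with eGFR, eGFR-based
  disease staging (stages 1–5), and age/sex/BMI-adjusted logistic ROC.
* **Integrated classifier** — stratified 8:2 split, randomized-search
  XGBoost with 5-fold CV and balanced class weights, 100-iteration
  bootstrap evaluation (AUC, sensitivity, specificity, NPV, PPV) and a
  Youden-threshold confusion matrix, plus an early-stage (stages 1–3)
  experiment.

The synthetic generator (`plasmafrag.simulate`) emulates the features the
analyses assume — the 166 bp peak with a 10-bp sub-150 bp ladder, a long
dinucleosomal tail whose mass differs by group, group-specific CC/TT motif
biases written into the reference so extraction is exactly consistent,
planted aberrant coverage bins, and metadata with a monotone eGFR–effect
link — and exposes the generating truth for recovery tests.

## Worked example

`examples/classify_dn.py` simulates a 60-sample cohort (20 control, 20 DM,
20 DN; 8,000 fragments per sample on a 6 Mb toy genome) and runs the whole
pipeline:

```
top increased motifs in DN (short DNA): ['CCAA', 'CCTA', 'CCCC', 'CCTC', 'CCCT']
top decreased motifs in DN (short DNA): ['TTAC', 'TTCT', 'TTTC', 'TTCC']
Spearman MDS(short) ~ eGFR: rho = 0.53 (p = 4.9e-04)
test AUC: 1.000 +/- 0.000
sensitivity 1.000, specificity 1.000
Youden-threshold confusion on the full test set: {'tp': 4, 'fp': 0, 'tn': 4, 'fn': 0}
```

The recovered differential motifs start with CC (increased in DN) and TT
(decreased), matching the planted nuclease signature; short-DNA motif
diversity correlates positively with kidney function; and the integrated
model separates the held-out DN and DM samples. The other example scripts
cover cohort simulation and file output (`simulate_cohort.py`), per-sample
feature extraction (`size_and_motif_features.py`) and MGR z-scoring
(`mgr_zscores.py`).

## Layout

```
src/plasmafrag/
  simulate.py    synthetic cohort generator (+ truth for recovery tests)
  fragments.py   BAM/SAM/BED reading, retention filters, end-motif extraction
  features.py    size profiles, motif spectra, MDS, differential motifs, ratios
  mgr.py         1-Mb bin grids, reference panels, coverage z-scores
  stats.py       outliers, rank tests, eGFR staging/correlation, adjusted ROC
  classify.py    splits, XGBoost training, bootstrap evaluation, early stage
  pipeline.py    cohort-level orchestration
examples/        narrative scripts, one per capability
docs/methods.md  model assumptions, parameter choices, limitations
```
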