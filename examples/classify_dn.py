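"""The integrated DN-vs-DM classifier, end to end.

Simulates a 60-sample cohort (20 control / 20 DM / 20 DN), extracts all
fragmentomic features, finds the differentially used short-DNA end motifs,
assembles the integrated feature vector (size fractions, top differential
motif frequencies, motif ratios, short-DNA MDS), performs a stratified 8:2
split, tunes an XGBoost model by randomized search with 5-fold CV, and
evaluates the held-out test set with 100 bootstrap iterations.
"""

import numpy as np

from plasmafrag import (
    GeneratorConfig,
    MgrModel,
    correlate_egfr,
    dn_vs_dm_workflow,
    features_from_cohort,
    generate_cohort,
)

cohort = generate_cohort(
    GeneratorConfig(
        seed=7, n_control=20, n_dm=20, n_dn=20,
        genome_length=6_000_000, fragments_per_sample=8_000,
        mgr_model=MgrModel(n_aberrant_bins={"control": 0, "DM": 1, "DN": 1}),
    )
)
cf = features_from_cohort(cohort)
res = dn_vs_dm_workflow(cf, seed=11, search_budget=8, iterations=100)

print("top increased motifs in DN (short DNA):", res.ratio_set.up_motifs)
print("top decreased motifs in DN (short DNA):", res.ratio_set.down_motifs)
rho, p = correlate_egfr(res.table, "mds_short")
print(f"Spearman MDS(short) ~ eGFR: rho = {rho:.2f} (p = {p:.1e})")

s = res.report.summary()
print(f"test AUC: {s['auc']['mean']:.3f} +/- {s['auc']['sd']:.3f}")
print(f"sensitivity {s['sensitivity']['mean']:.3f}, "
      f"specificity {s['specificity']['mean']:.3f}")
print(f"Youden-threshold confusion on the full test set: {s['confusion']}")
print("\nThe increased motifs start with CC and the decreased ones with TT "
      "(the planted nuclease signature); motif diversity of short DNA "
      "tracks kidney function (positive rho); the bootstrap AUC shows the "
      "integrated model separates DN from DM on held-out samples.")
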