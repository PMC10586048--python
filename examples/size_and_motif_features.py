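"""Per-sample fragmentomic features: size fractions, end-motif spectra and
the motif diversity score (MDS).

Builds a 12-sample synthetic cohort in memory and prints the group medians
of the features that differ between diabetic nephropathy (DN) and diabetes
(DM) plasma: the fraction of long (>=250 bp) DNA drops in DN, and the MDS
of short (<=156 bp) DNA drops because CC-start motifs become over-used.
"""

import pandas as pd

from plasmafrag import GeneratorConfig, generate_cohort, motif_spectrum, size_profile
from plasmafrag.motifs import MOTIFS

cohort = generate_cohort(
    GeneratorConfig(seed=2, n_control=4, n_dm=4, n_dn=4,
                    genome_length=4_000_000, fragments_per_sample=5_000)
)
meta = cohort.metadata.set_index("sample_id")

rows = {}
for sid, frag in cohort.fragments.items():
    prof = size_profile(frag)
    short = motif_spectrum(frag, "short")
    cc = sum(short.frequency(m) for m in MOTIFS if m.startswith("CC"))
    rows[sid] = dict(
        group=meta.loc[sid, "group"],
        frac_medium=prof.frac_medium,
        frac_long=prof.frac_long,
        mds_short=short.mds,
        cc_start_freq=cc,
    )

table = pd.DataFrame.from_dict(rows, orient="index")
print(table.groupby("group").median().round(4))
print("\nDN rows: lower frac_long and mds_short, higher CC-start motif "
      "frequency — the fragmentation signature of nuclease (DNASE1L3-like) "
      "activity in damaged kidney.")
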