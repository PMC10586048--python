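"""End-to-end orchestration: fragments -> per-sample features -> cohort
table -> differential motifs -> classification.

Works directly on in-memory fragment tables (e.g. a generated
:class:`~plasmafrag.simulate.SyntheticCohort`) or on files written by
:func:`~plasmafrag.simulate.write_fragments` and read back through
:mod:`plasmafrag.fragments`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import classify, features, mgr
from .features import MotifRatioSet, SizeBands
from .fragments import contig_counts, mito_abundance
from .motifs import MOTIFS
from .simulate import SyntheticCohort


@dataclass
class CohortFeatures:
    """Sample x feature table (with metadata columns) plus the short-stratum
    motif-frequency matrix used for differential-motif analysis."""

    table: pd.DataFrame  # indexed by sample_id
    short_freq: pd.DataFrame  # samples x 256, columns "short_<MOTIF>"
    panel: mgr.ReferencePanel | None


def sample_features(
    frag_df: pd.DataFrame,
    bands: SizeBands | None = None,
    mito_contig: str = "chrM",
) -> dict:
    """Size fractions, per-stratum MDS and mitochondrial abundance for one
    sample's fragment table."""
    bands = bands or SizeBands()
    prof = features.size_profile(frag_df, bands)
    out = dict(
        n_fragments=prof.n_fragments,
        frac_short=prof.frac_short,
        frac_medium=prof.frac_medium,
        frac_long=prof.frac_long,
        mito_per_million=mito_abundance(contig_counts(frag_df), mito_contig),
    )
    for stratum in ("all", "short", "long"):
        spec = features.motif_spectrum(frag_df, stratum, bands.stratum_cutoff)
        out[f"mds_{stratum}"] = spec.mds
        if stratum == "short":
            out["_short_spectrum"] = spec
    return out


def build_cohort_table(
    fragments: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    bands: SizeBands | None = None,
    mito_contig: str = "chrM",
    n_ref: int = 10,
    seed: int = 0,
) -> CohortFeatures:
    """Compute all per-sample features and MGR aberrant-bin fractions.

    The MGR reference panel is built from ``n_ref`` randomly chosen control
    samples; panel members keep their features but get a NaN aberrant
    fraction (they are excluded from scoring).
    """
    bands = bands or SizeBands()
    meta = metadata.set_index("sample_id")
    grid = mgr.BinGrid.from_contig_lengths(
        contig_lengths, bin_size=1_000_000
    )
    counts = {sid: grid.bin_counts(df) for sid, df in fragments.items()}
    control_ids = [s for s in meta.index if meta.loc[s, "group"] == "control"]
    panel = None
    if n_ref > 0 and len(control_ids) >= n_ref:
        panel = mgr.build_panel(
            {s: counts[s] for s in control_ids}, grid, n_ref=n_ref, seed=seed
        )
    rows = {}
    short_rows = {}
    for sid, df in fragments.items():
        feats = sample_features(df, bands, mito_contig)
        spec = feats.pop("_short_spectrum")
        short_rows[sid] = spec.freq
        if panel is not None and sid not in panel.member_ids:
            feats["aberrant_fraction"] = mgr.score_sample(
                counts[sid], panel
            ).aberrant_fraction
        else:
            feats["aberrant_fraction"] = np.nan
        feats["in_reference_panel"] = bool(
            panel is not None and sid in panel.member_ids
        )
        rows[sid] = feats
    table = pd.DataFrame.from_dict(rows, orient="index")
    short_freq = pd.DataFrame.from_dict(short_rows, orient="index")
    short_freq.columns = ["short_" + m for m in MOTIFS]
    table = table.join(meta, how="left")
    table = table.join(short_freq)
    return CohortFeatures(table=table, short_freq=short_freq, panel=panel)


def features_from_cohort(cohort: SyntheticCohort, **kwargs) -> CohortFeatures:
    return build_cohort_table(
        cohort.fragments,
        cohort.metadata,
        cohort.truth["contig_lengths"],
        mito_contig=cohort.truth["config"]["mito_contig"],
        **kwargs,
    )


@dataclass
class DnVsDmResult:
    ratio_set: MotifRatioSet
    motif_report: pd.DataFrame
    split: classify.SplitPlan
    bundle: classify.ModelBundle
    report: classify.EvaluationReport
    table: pd.DataFrame


def add_motif_ratios(
    cohort_features: CohortFeatures, ratio_set: MotifRatioSet, max_n: int = 5
) -> pd.DataFrame:
    """Append per-sample ratio_1..ratio_n columns from the short-stratum
    spectrum and the cohort's differential-motif lists."""
    table = cohort_features.table
    sf = cohort_features.short_freq.to_numpy()
    cols = {}
    for i, sid in enumerate(cohort_features.short_freq.index):
        cols[sid] = features.motif_ratios(sf[i], ratio_set, max_n)
    ratios = pd.DataFrame.from_dict(cols, orient="index")
    return table.drop(columns=ratios.columns, errors="ignore").join(ratios)


def dn_vs_dm_workflow(
    cohort_features: CohortFeatures,
    seed: int = 0,
    search_budget: int = 50,
    iterations: int = 100,
    test_fraction: float = 0.2,
    alpha: float = 0.05,
    include_concentration: bool = False,
) -> DnVsDmResult:
    """The integrated classification workflow on a featurised cohort:
    differential short-DNA motifs (DN vs DM), motif ratios, feature
    assembly, stratified split, randomized-search XGBoost training and
    bootstrap evaluation."""
    table = cohort_features.table
    dn_dm = table[table["group"].isin(["DN", "DM"])]
    ratio_set, motif_report = features.differential_motifs(
        cohort_features.short_freq.loc[dn_dm.index].rename(
            columns=lambda c: c.removeprefix("short_")
        ),
        dn_dm["group"],
        alpha=alpha,
    )
    if not ratio_set.up_motifs or not ratio_set.down_motifs:
        raise ValueError(
            "no significantly increased/decreased motifs; cannot assemble "
            "the ratio features"
        )
    full = add_motif_ratios(cohort_features, ratio_set)
    dn_dm = full[full["group"].isin(["DN", "DM"])]
    X = classify.assemble_features(
        dn_dm, ratio_set, include_concentration=include_concentration
    )
    y = (dn_dm.loc[X.index, "group"] == "DN").astype(int)
    plan = classify.stratified_split(
        dn_dm.loc[X.index, "group"], test_fraction, seed
    )
    bundle = classify.train_model(
        X.loc[plan.train_ids], y.loc[plan.train_ids].to_numpy(),
        search_budget=search_budget, seed=seed,
    )
    report = classify.evaluate_bundle(
        bundle, X.loc[plan.test_ids], y.loc[plan.test_ids].to_numpy(),
        iterations=iterations, seed=seed,
    )
    return DnVsDmResult(
        ratio_set=ratio_set,
        motif_report=motif_report,
        split=plan,
        bundle=bundle,
        report=report,
        table=full,
    )
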