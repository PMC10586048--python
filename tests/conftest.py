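"""Shared fixtures: synthetic cohorts at desk scale.

All data are generated at test time; nothing is read from disk except what
the tests themselves write to tmp paths.
"""

import numpy as np
import pandas as pd
import pytest

from plasmafrag.simulate import (
    GeneratorConfig,
    MgrModel,
    MotifModel,
    SizeModel,
    generate_cohort,
)


def effect_config(seed: int = 7) -> GeneratorConfig:
    """A 60-sample cohort (20 control / 20 DM / 20 DN) with the default
    disease effects on: CC-motif enrichment, TT depletion, long-fragment
    depletion, planted aberrant bins, eGFR-linked effect strength."""
    return GeneratorConfig(
        seed=seed,
        n_control=20,
        n_dm=20,
        n_dn=20,
        genome_length=6_000_000,
        n_autosomes=2,
        fragments_per_sample=8000,
        mgr_model=MgrModel(n_aberrant_bins={"control": 0, "DM": 1, "DN": 1}),
    )


def null_config(seed: int = 19) -> GeneratorConfig:
    """Same machinery with every group effect switched off: DM and DN are
    drawn from identical distributions."""
    return GeneratorConfig(
        seed=seed,
        n_control=0,
        n_dm=14,
        n_dn=14,
        genome_length=4_000_000,
        n_autosomes=2,
        fragments_per_sample=4000,
        size_model=SizeModel(
            long_depletion={"control": 1.0, "DM": 1.0, "DN": 1.0}
        ),
        motif_model=MotifModel(
            cc_enrichment={"control": 1.0, "DM": 1.0, "DN": 1.0},
            tt_depletion={"control": 1.0, "DM": 1.0, "DN": 1.0},
        ),
        mgr_model=MgrModel(n_aberrant_bins={"control": 0, "DM": 0, "DN": 0}),
    )


@pytest.fixture(scope="session")
def effect_cohort():
    return generate_cohort(effect_config())


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(null_config())


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 samples, 2 Mb genome, 2,000 fragments each — for I/O round trips."""
    cfg = GeneratorConfig(
        seed=3,
        n_control=1,
        n_dm=1,
        n_dn=1,
        genome_length=2_000_000,
        fragments_per_sample=2000,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_fragment_table(contigs, starts, ends, motifs_plus, motifs_minus):
    return pd.DataFrame(
        {
            "contig": contigs,
            "start": starts,
            "end": ends,
            "length": np.asarray(ends) - np.asarray(starts),
            "motif_plus": motifs_plus,
            "motif_minus": motifs_minus,
            "valid_motif": True,
        }
    )
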