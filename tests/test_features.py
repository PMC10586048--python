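"""Size profiles, motif spectra, MDS, differential motifs and motif ratios,
checked against closed forms and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import plasmafrag as pf
from plasmafrag.features import (
    MotifRatioSet,
    SizeBands,
    differential_motifs,
    mds,
    motif_ratio,
    motif_ratios,
    motif_spectrum,
    size_profile,
)
from plasmafrag.motifs import MOTIFS

from conftest import make_fragment_table


def table_from_motifs(pairs, length=100):
    n = len(pairs)
    return make_fragment_table(
        ["chr1"] * n,
        np.zeros(n, dtype=int),
        np.full(n, length),
        [p for p, _ in pairs],
        [m for _, m in pairs],
    )


# ---------------------------------------------------------------------------
# size profile
# ---------------------------------------------------------------------------


class TestSizeProfile:
    def test_four_fragment_enumeration(self):
        prof = size_profile([100, 165, 166, 300])
        assert prof.frac_short == 0.25
        assert prof.frac_medium == 0.50
        assert prof.frac_long == 0.25
        assert prof.histogram.sum() == 4

    def test_gap_length_belongs_to_no_band(self):
        prof = size_profile([155] * 10)
        assert prof.frac_short == prof.frac_medium == prof.frac_long == 0

    def test_empty_input_flagged(self):
        prof = size_profile([])
        assert prof.n_fragments == 0
        assert math.isnan(prof.frac_short)

    def test_band_boundaries_inclusive(self):
        prof = size_profile([150, 160, 170, 250])
        assert prof.frac_short == 0.25
        assert prof.frac_medium == 0.50
        assert prof.frac_long == 0.25

    @given(st.lists(st.integers(min_value=1, max_value=600), min_size=1,
                    max_size=200))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_histogram_conserves_count_and_fractions_bounded(self, lengths):
        prof = size_profile(lengths)
        assert prof.histogram.sum() == len(lengths)
        for f in (prof.frac_short, prof.frac_medium, prof.frac_long):
            assert 0 <= f <= 1
        assert prof.frac_short + prof.frac_medium + prof.frac_long <= 1 + 1e-12


# ---------------------------------------------------------------------------
# motif spectrum
# ---------------------------------------------------------------------------


class TestMotifSpectrum:
    def test_single_fragment_two_motifs(self):
        spec = motif_spectrum(table_from_motifs([("CCAC", "ATAA")]))
        assert spec.frequency("CCAC") == 0.5
        assert spec.frequency("ATAA") == 0.5
        assert spec.n_motifs == 2
        assert spec.freq.sum() == pytest.approx(1.0)

    def test_uniform_over_all_motifs(self):
        pairs = [(m, m) for m in MOTIFS]
        spec = motif_spectrum(table_from_motifs(pairs))
        assert np.allclose(spec.freq, 1 / 256)

    def test_length_156_is_short_not_long(self):
        df = table_from_motifs([("AAAA", "AAAA")], length=156)
        assert motif_spectrum(df, "short", 156).n_motifs == 2
        assert motif_spectrum(df, "long", 156).n_motifs == 0

    def test_empty_stratum_flagged(self):
        df = table_from_motifs([("AAAA", "AAAA")], length=300)
        spec = motif_spectrum(df, "short")
        assert spec.n_motifs == 0
        assert math.isnan(spec.mds)

    def test_stratified_counts_sum_to_all(self, tiny_cohort):
        df = tiny_cohort.fragments[tiny_cohort.sample_ids[0]]
        ns = motif_spectrum(df, "short").n_motifs
        nl = motif_spectrum(df, "long").n_motifs
        na = motif_spectrum(df, "all").n_motifs
        assert ns + nl == na
        combined = (
            motif_spectrum(df, "short").freq * ns
            + motif_spectrum(df, "long").freq * nl
        )
        assert np.allclose(combined / na, motif_spectrum(df, "all").freq)


# ---------------------------------------------------------------------------
# MDS
# ---------------------------------------------------------------------------


class TestMds:
    def test_uniform_is_one(self):
        assert mds(np.full(256, 1 / 256)) == pytest.approx(1.0)

    def test_degenerate_is_zero(self):
        v = np.zeros(256)
        v[7] = 1.0
        assert mds(v) == 0.0

    def test_two_motif_split_closed_form(self):
        v = np.zeros(256)
        v[0] = v[255] = 0.5
        assert mds(v) == pytest.approx(math.log(2) / math.log(256))
        assert mds(v) == pytest.approx(0.125)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=256,
                 max_size=256).filter(lambda v: sum(v) > 1e-6),
        st.randoms(use_true_random=False),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounds_and_permutation_invariance(self, v, rnd):
        v = np.asarray(v)
        score = mds(v)
        assert 0 <= score <= 1 + 1e-12
        perm = list(range(256))
        rnd.shuffle(perm)
        assert mds(v[perm]) == pytest.approx(score)


# ---------------------------------------------------------------------------
# brute-force oracle on tiny inputs
# ---------------------------------------------------------------------------


def brute_force_features(rows, cutoff=156):
    """Direct-loop recomputation of fractions, motif frequencies and MDS."""
    lengths = [e - s for _, s, e in [(r[0], r[1], r[2]) for r in rows]]
    n = len(rows)
    frac_short = sum(1 for L in lengths if L <= 150) / n
    frac_medium = sum(1 for L in lengths if 160 <= L <= 170) / n
    frac_long = sum(1 for L in lengths if L >= 250) / n
    counts = {}
    for (_, s, e, mp, mm) in rows:
        if e - s <= cutoff:
            for m in (mp, mm):
                counts[m] = counts.get(m, 0) + 1
    total = sum(counts.values())
    freq = {m: c / total for m, c in counts.items()}
    ent = -sum(p * math.log(p) for p in freq.values())
    return frac_short, frac_medium, frac_long, freq, ent / math.log(256)


def test_features_match_brute_force_enumeration(rng):
    motif_choices = np.array(MOTIFS)
    rows = []
    for _ in range(40):
        s = int(rng.integers(0, 1000))
        L = int(rng.integers(60, 400))
        rows.append(
            ("chr1", s, s + L, str(rng.choice(motif_choices)),
             str(rng.choice(motif_choices)))
        )
    df = make_fragment_table(
        [r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows],
        [r[3] for r in rows], [r[4] for r in rows],
    )
    fs, fm, fl, freq, entropy = brute_force_features(rows)
    prof = size_profile(df)
    assert prof.frac_short == pytest.approx(fs)
    assert prof.frac_medium == pytest.approx(fm)
    assert prof.frac_long == pytest.approx(fl)
    spec = motif_spectrum(df, "short")
    for m, f in freq.items():
        assert spec.frequency(m) == pytest.approx(f)
    assert spec.mds == pytest.approx(entropy)


# ---------------------------------------------------------------------------
# differential motifs
# ---------------------------------------------------------------------------


def freq_frame(rows):
    df = pd.DataFrame(rows, dtype=float)
    # fill remaining motifs with a shared constant column mass
    rest = [m for m in MOTIFS if m not in df.columns]
    filler = (1 - df.sum(axis=1)) / len(rest)
    return pd.concat(
        [df, pd.DataFrame({m: filler for m in rest})], axis=1
    )


class TestDifferentialMotifs:
    def test_relative_median_change_arithmetic(self):
        """Hand-set spectra with CCAC medians 0.0044 vs 0.0042 give a
        +4.76% relative change."""
        rows = [
            {"CCAC": 0.0043}, {"CCAC": 0.0044}, {"CCAC": 0.0045},
            {"CCAC": 0.0041}, {"CCAC": 0.0042}, {"CCAC": 0.0043},
        ]
        table = freq_frame(rows)
        labels = ["DN"] * 3 + ["DM"] * 3
        _, report = differential_motifs(table, labels, correction="none",
                                        alpha=1.1)
        rel = report.set_index("motif").loc["CCAC", "relative_change"]
        assert rel == pytest.approx((0.0044 - 0.0042) / 0.0042)
        assert rel == pytest.approx(0.047619, abs=1e-6)

    def test_label_permutation_yields_no_significant_motifs(self, rng):
        """Identically distributed groups produce no Bonferroni-significant
        motifs."""
        n = 20
        base = np.full(256, 1 / 256)
        mat = rng.dirichlet(base * 2000, size=n)
        table = pd.DataFrame(mat, columns=MOTIFS)
        labels = np.array(["DN"] * 10 + ["DM"] * 10)
        hits = 0
        for _ in range(10):
            rng.shuffle(labels)
            ratio_set, report = differential_motifs(table, labels)
            hits += len(ratio_set.up_motifs) + len(ratio_set.down_motifs)
        assert hits == 0

    def test_synthetic_cohort_recovers_planted_motif_directions(
        self, effect_cohort
    ):
        meta = effect_cohort.metadata.set_index("sample_id")
        rows, labels = [], []
        for sid, df in effect_cohort.fragments.items():
            g = meta.loc[sid, "group"]
            if g not in ("DM", "DN"):
                continue
            spec = motif_spectrum(df, "short")
            rows.append(spec.freq)
            labels.append(g)
        table = pd.DataFrame(rows, columns=MOTIFS)
        ratio_set, _ = differential_motifs(table, labels)
        assert len(ratio_set.up_motifs) >= 3
        assert len(ratio_set.down_motifs) >= 3
        assert all(m.startswith("CC") for m in ratio_set.up_motifs)
        assert all(m.startswith("TT") for m in ratio_set.down_motifs)

    def test_requires_two_samples_per_group(self):
        table = freq_frame([{"CCAC": 0.004}] * 3)
        with pytest.raises(ValueError):
            differential_motifs(table, ["DN", "DM", "DM"])


# ---------------------------------------------------------------------------
# motif ratios
# ---------------------------------------------------------------------------


class TestMotifRatio:
    rs = MotifRatioSet(up_motifs=["CCAC", "CCCC"], down_motifs=["TTAT", "TTCA"])

    def make_freq(self, vals):
        v = np.zeros(256)
        for m, f in vals.items():
            v[MOTIFS.index(m)] = f
        return v

    def test_equal_sums_give_one(self):
        freq = self.make_freq(
            {"CCAC": 0.02, "CCCC": 0.01, "TTAT": 0.01, "TTCA": 0.02}
        )
        assert motif_ratio(freq, self.rs, 2) == pytest.approx(1.0)

    def test_top1_arithmetic(self):
        freq = self.make_freq({"CCAC": 0.02, "TTAT": 0.01})
        assert motif_ratio(freq, self.rs, 1) == pytest.approx(2.0)

    def test_uniform_spectrum_any_lists_give_one(self):
        freq = np.full(256, 1 / 256)
        for n in (1, 2):
            assert motif_ratio(freq, self.rs, n) == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        freq = self.make_freq({"CCAC": 0.02})
        assert math.isnan(motif_ratio(freq, self.rs, 1))

    def test_ratios_dict_pads_with_nan(self):
        freq = np.full(256, 1 / 256)
        out = motif_ratios(freq, self.rs, max_n=5)
        assert out["ratio_1"] == pytest.approx(1.0)
        assert math.isnan(out["ratio_3"])
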