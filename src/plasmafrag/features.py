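"""Per-sample fragmentomic features: size profiles, 256-motif spectra,
motif diversity score (MDS), differential motifs, and motif ratios.

Size groups follow the conventional plasma-DNA bands: short (<=150 bp,
sub-mononucleosomal), medium (160-170 bp, the mononucleosomal peak) and
long (>=250 bp, di-/polynucleosomal). Motif spectra can additionally be
stratified at 156 bp, the cutoff below which disease-associated end-motif
signal is strongest; both cutoffs are configurable.

The MDS is the Shannon entropy of the 256-category end-motif distribution
normalised by log(256): 1 for a uniform motif usage, 0 when a single motif
carries all mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .motifs import MOTIFS, MOTIF_INDEX, N_MOTIFS

Stratum = Literal["all", "short", "long"]


@dataclass
class SizeBands:
    """Size-group boundaries in bp (all inclusive)."""

    short_max: int = 150
    medium_low: int = 160
    medium_high: int = 170
    long_min: int = 250
    stratum_cutoff: int = 156  # short stratum is length <= cutoff
    max_length: int = 600


@dataclass
class SizeProfile:
    """Fragment-length histogram (index = length in bp) and band fractions."""

    histogram: np.ndarray
    n_fragments: int
    frac_short: float
    frac_medium: float
    frac_long: float

    @property
    def modal_length(self) -> int:
        return int(np.argmax(self.histogram))


@dataclass
class MotifSpectrum:
    """256-motif frequency vector for one sample and size stratum."""

    freq: np.ndarray
    n_motifs: int
    stratum: Stratum
    mds: float

    def frequency(self, motif: str) -> float:
        return float(self.freq[MOTIF_INDEX[motif.upper()]])


@dataclass
class MotifRatioSet:
    """Ordered differential-motif lists (most-changed first) feeding the
    top-n motif ratios."""

    up_motifs: list[str] = field(default_factory=list)
    down_motifs: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# size profile
# ---------------------------------------------------------------------------


def _as_lengths(fragments) -> np.ndarray:
    if isinstance(fragments, pd.DataFrame):
        return fragments["length"].to_numpy()
    return np.asarray(list(fragments), dtype=np.int64)


def size_profile(fragments, bands: SizeBands | None = None) -> SizeProfile:
    """Length histogram plus short/medium/long band fractions.

    An empty input yields a zero histogram with NaN fractions.
    """
    bands = bands or SizeBands()
    lengths = _as_lengths(fragments)
    hist = np.bincount(
        np.clip(lengths, 0, bands.max_length), minlength=bands.max_length + 1
    )
    n = len(lengths)
    if n == 0:
        return SizeProfile(hist, 0, float("nan"), float("nan"), float("nan"))
    frac_short = float((lengths <= bands.short_max).mean())
    frac_medium = float(
        ((lengths >= bands.medium_low) & (lengths <= bands.medium_high)).mean()
    )
    frac_long = float((lengths >= bands.long_min).mean())
    return SizeProfile(hist, n, frac_short, frac_medium, frac_long)


# ---------------------------------------------------------------------------
# motif spectrum + MDS
# ---------------------------------------------------------------------------


def motif_spectrum(
    fragments: pd.DataFrame,
    stratum: Stratum = "all",
    cutoff: int = 156,
) -> MotifSpectrum:
    """Frequency of each of the 256 end motifs, counting both strands' 5'
    motifs of every fragment in the requested size stratum (short =
    length <= cutoff). Fragments flagged ``valid_motif=False`` are excluded.
    """
    df = fragments
    if "valid_motif" in df.columns:
        df = df[df["valid_motif"]]
    if stratum == "short":
        df = df[df["length"] <= cutoff]
    elif stratum == "long":
        df = df[df["length"] > cutoff]
    elif stratum != "all":
        raise ValueError(f"unknown stratum {stratum!r}")
    counts = np.zeros(N_MOTIFS, dtype=np.int64)
    for col in ("motif_plus", "motif_minus"):
        codes = df[col].map(MOTIF_INDEX)
        counts += np.bincount(codes.to_numpy(dtype=np.int64),
                              minlength=N_MOTIFS)
    n = int(counts.sum())
    if n == 0:
        return MotifSpectrum(np.zeros(N_MOTIFS), 0, stratum, float("nan"))
    freq = counts / n
    return MotifSpectrum(freq, n, stratum, mds(freq))


def mds(freq) -> float:
    """Motif diversity score: normalised Shannon entropy of a 256-motif
    frequency vector (natural log over log 256; 0*log 0 = 0)."""
    if isinstance(freq, MotifSpectrum):
        if freq.n_motifs == 0:
            return float("nan")
        freq = freq.freq
    p = np.asarray(freq, dtype=float)
    if p.sum() <= 0:
        return float("nan")
    p = p / p.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(N_MOTIFS))


# ---------------------------------------------------------------------------
# differential motifs
# ---------------------------------------------------------------------------


def differential_motifs(
    freq_table: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    group_a: str = "DN",
    group_b: str = "DM",
    alpha: float = 0.05,
    top_n: int = 5,
    correction: Literal["bonferroni", "none"] = "bonferroni",
) -> tuple[MotifRatioSet, pd.DataFrame]:
    """Per-motif two-sided Mann-Whitney comparison of group_a vs group_b.

    ``freq_table`` is samples x 256 motif frequencies (columns named by
    motif). Motifs significant after multiple-testing correction are ranked
    by relative change in median frequency,
    ``(median_a - median_b) / median_b``; ties break by absolute relative
    change, then lexicographic motif order. Returns the top-``top_n``
    increased and decreased motif lists plus the full per-motif report.
    """
    labels = np.asarray(labels)
    in_a = labels == group_a
    in_b = labels == group_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("need at least 2 samples per group")
    records = []
    for motif in MOTIFS:
        if motif not in freq_table.columns:
            continue
        va = freq_table.loc[in_a, motif].to_numpy(dtype=float)
        vb = freq_table.loc[in_b, motif].to_numpy(dtype=float)
        med_a, med_b = float(np.median(va)), float(np.median(vb))
        if np.ptp(np.concatenate([va, vb])) == 0:
            warnings.warn(f"motif {motif} constant across samples; skipped",
                          stacklevel=2)
            continue
        if med_b == 0:
            warnings.warn(
                f"motif {motif} has zero median in {group_b}; skipped",
                stacklevel=2,
            )
            continue
        p = float(sps.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        records.append(
            dict(
                motif=motif,
                median_a=med_a,
                median_b=med_b,
                relative_change=(med_a - med_b) / med_b,
                pvalue=p,
            )
        )
    report = pd.DataFrame(records)
    if len(report) == 0:
        return MotifRatioSet(), report
    m = N_MOTIFS if correction == "bonferroni" else 1
    report["pvalue_adjusted"] = np.minimum(report["pvalue"] * m, 1.0)
    report["significant"] = report["pvalue_adjusted"] < alpha

    sig = report[report["significant"]]
    up = sig[sig["relative_change"] > 0].copy()
    down = sig[sig["relative_change"] < 0].copy()
    up["absrel"] = up["relative_change"].abs()
    down["absrel"] = down["relative_change"].abs()
    up = up.sort_values(["absrel", "motif"], ascending=[False, True])
    down = down.sort_values(["absrel", "motif"], ascending=[False, True])

    rank = pd.Series(index=report["motif"], dtype=float)
    for r, motif in enumerate(up["motif"], start=1):
        rank[motif] = r
    for r, motif in enumerate(down["motif"], start=1):
        rank[motif] = -r
    report["rank"] = rank.to_numpy()

    ratio_set = MotifRatioSet(
        up_motifs=list(up["motif"].head(top_n)),
        down_motifs=list(down["motif"].head(top_n)),
    )
    return ratio_set, report


# ---------------------------------------------------------------------------
# motif ratios
# ---------------------------------------------------------------------------


def motif_ratio(spectrum, ratio_set: MotifRatioSet, n: int) -> float:
    """Top-n motif ratio: summed frequency of the first ``n`` increased
    motifs over the summed frequency of the first ``n`` decreased motifs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(ratio_set.up_motifs) or n > len(ratio_set.down_motifs):
        raise ValueError(f"ratio set holds fewer than {n} motifs per side")
    freq = spectrum.freq if isinstance(spectrum, MotifSpectrum) else np.asarray(spectrum)
    num = sum(freq[MOTIF_INDEX[m]] for m in ratio_set.up_motifs[:n])
    den = sum(freq[MOTIF_INDEX[m]] for m in ratio_set.down_motifs[:n])
    if den == 0:
        return float("nan")
    return float(num / den)


def motif_ratios(spectrum, ratio_set: MotifRatioSet, max_n: int = 5) -> dict[str, float]:
    """ratio_1 .. ratio_max_n as a dict (NaN where the set is too small)."""
    out = {}
    avail = min(len(ratio_set.up_motifs), len(ratio_set.down_motifs))
    for n in range(1, max_n + 1):
        out[f"ratio_{n}"] = (
            motif_ratio(spectrum, ratio_set, n) if n <= avail else float("nan")
        )
    return out
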