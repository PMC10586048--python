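"""Synthetic plasma cfDNA cohort generator.

Generates a toy reference genome (two autosomes plus a short mitochondrial
contig), per-sample fragment sets with the statistical structure that plasma
cfDNA analyses assume, and matching clinical metadata, so that every
downstream stage of the pipeline is testable without restricted patient data.

The generative model has four coupled parts:

* **Size model** — a three-component mixture: a sub-150 bp ladder with 10-bp
  periodic modes (nuclease trimming of nucleosomal DNA), a Gaussian
  mononucleosomal peak at 166 bp, and a dinucleosomal/long tail around
  332 bp. Diseased (DN) samples carry less long DNA.
* **Motif model** — a 256-category 4-mer 5' end-motif distribution built from
  per-position base preferences; DN samples enrich "CC"-start motifs and
  deplete "TT"-start motifs, with a stronger effect on short (<=156 bp)
  fragments. Per-sample biological variation is Dirichlet.
* **Coverage model** — per-sample distorted 1-Mb bins (over/under-represented
  by a fold factor) emulating aberrant genomic representation.
* **Metadata model** — group-specific age/sex/BMI/eGFR/cfDNA-concentration
  draws, with the motif and size effect strength of each DN sample linearly
  coupled to its eGFR, so correlation-recovery tests have a known sign.

Both 5' motifs of every fragment are drawn from the sample's motif
distribution, and the fragment is then *placed* on the reference at a
position where the reference bases at both ends equal the drawn motifs
(rejection sampling over a precomputed 4-mer position index). Reading the
reference back at the fragment ends therefore reproduces the generated
motifs exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .motifs import (
    MOTIFS,
    N_MOTIFS,
    REVCOMP_CODE,
    codes_to_seq,
    kmer_codes,
)

GROUPS = ("control", "DM", "DN")


class ConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# configuration blocks
# ---------------------------------------------------------------------------


@dataclass
class SizeModel:
    """Three-component fragment-length mixture (bp).

    ``short_weight`` covers the sub-150 bp periodic ladder, ``medium_weight``
    the mononucleosomal Gaussian, ``long_weight`` the dinucleosomal tail.
    ``long_depletion`` multiplies the long-component weight per group
    (values < 1 deplete long DNA, as seen in DN plasma).
    """

    short_weight: float = 0.18
    medium_weight: float = 0.77
    long_weight: float = 0.05
    mono_peak_bp: int = 166
    mono_sd_bp: float = 8.0
    # fraction of the mononucleosomal component sitting exactly on the peak
    # (the 166 bp mode of real size profiles is sharper than a Gaussian)
    mono_mode_frac: float = 0.08
    periodicity_bp: int = 10
    ladder_top_bp: int = 145
    n_ladder_modes: int = 8
    ladder_sd_bp: float = 2.5
    di_peak_bp: int = 332
    di_sd_bp: float = 30.0
    min_bp: int = 50
    max_bp: int = 600
    long_depletion: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "DM": 1.0, "DN": 0.75}
    )

    def validate(self) -> None:
        w = np.array([self.short_weight, self.medium_weight, self.long_weight])
        if (w < 0).any():
            raise ConfigError("size mixture weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("size mixture weights must sum to 1")
        if not 0 < self.min_bp <= self.max_bp:
            raise ConfigError("invalid length bounds")


@dataclass
class MotifModel:
    """Per-group 256-motif distributions.

    The base distribution is the product of identical per-position base
    probabilities (A, C, G, T); group effects multiply the probability of
    motifs starting with "CC" (``cc_enrichment``) and "TT"
    (``tt_depletion``) and renormalise. The effect on fragments longer than
    ``stratum_cutoff_bp`` is attenuated by ``long_attenuation`` (short cfDNA
    carries the stronger disease signal). ``dirichlet_concentration`` sets
    per-sample biological variation; ``None`` disables it.
    """

    position_probs: tuple[float, float, float, float] = (0.16, 0.35, 0.15, 0.34)
    cc_enrichment: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "DM": 1.0, "DN": 1.5}
    )
    tt_depletion: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "DM": 1.0, "DN": 0.7}
    )
    long_attenuation: float = 0.5
    dirichlet_concentration: float | None = 5e4
    stratum_cutoff_bp: int = 156

    def base_vector(self) -> np.ndarray:
        p = np.asarray(self.position_probs, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError("position_probs must be a probability vector")
        v = np.einsum("i,j,k,l->ijkl", p, p, p, p).ravel()
        return v / v.sum()

    def group_vector(self, group: str, strength: float = 1.0) -> np.ndarray:
        """Expected motif vector for ``group`` at effect ``strength`` in [0, 1]."""
        return _apply_motif_effect(
            self.base_vector(),
            self.cc_enrichment.get(group, 1.0),
            self.tt_depletion.get(group, 1.0),
            strength,
        )


@dataclass
class MgrModel:
    """Planted coverage distortions: per-group number of aberrant 1-Mb bins
    and the fold by which their representation is distorted (alternating
    over-/under-representation)."""

    n_aberrant_bins: dict[str, int] = field(
        default_factory=lambda: {"control": 0, "DM": 2, "DN": 3}
    )
    distortion_fold: float = 1.6
    bin_size: int = 1_000_000


@dataclass
class EgfrModel:
    """Group-wise eGFR draws (ml/min/1.73 m^2) and the linear link mapping a
    sample's eGFR to the strength of its motif/size effects (strength 0 at
    ``link_high`` and 1 at ``link_low``)."""

    mean: dict[str, float] = field(
        default_factory=lambda: {"control": 99.0, "DM": 92.0, "DN": 34.0}
    )
    sd: dict[str, float] = field(
        default_factory=lambda: {"control": 15.0, "DM": 17.0, "DN": 27.0}
    )
    minimum: float = 5.0
    maximum: float = 130.0
    link_high: float = 100.0
    link_low: float = 10.0

    def strength(self, egfr: float) -> float:
        s = (self.link_high - egfr) / (self.link_high - self.link_low)
        return float(np.clip(s, 0.0, 1.0))


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_control: int = 53
    n_dm: int = 53
    n_dn: int = 71
    genome_length: int = 20_000_000
    n_autosomes: int = 2
    mito_length: int = 16_000
    mito_contig: str = "chrM"
    fragments_per_sample: int = 200_000
    mito_share: float = 1.5e-5
    size_model: SizeModel = field(default_factory=SizeModel)
    motif_model: MotifModel = field(default_factory=MotifModel)
    mgr_model: MgrModel = field(default_factory=MgrModel)
    egfr_model: EgfrModel = field(default_factory=EgfrModel)

    def validate(self) -> None:
        if min(self.n_control, self.n_dm, self.n_dn) < 0:
            raise ConfigError("group sizes must be non-negative")
        if self.fragments_per_sample <= 0:
            raise ConfigError("fragments_per_sample must be positive")
        if self.genome_length < 2_000_000:
            raise ConfigError("genome_length must be at least 2 Mb")
        if self.n_autosomes < 1:
            raise ConfigError("need at least one autosome")
        if not 0 <= self.mito_share < 1:
            raise ConfigError("mito_share must be in [0, 1)")
        self.size_model.validate()
        self.motif_model.base_vector()

    def contig_lengths(self) -> dict[str, int]:
        per = self.genome_length // self.n_autosomes
        lengths = {f"chr{i + 1}": per for i in range(self.n_autosomes)}
        lengths[self.mito_contig] = self.mito_length
        return lengths


@dataclass
class SyntheticCohort:
    """A generated cohort: reference sequences, per-sample fragment tables,
    metadata, and the generating truth for recovery tests."""

    reference: dict[str, str]
    fragments: dict[str, pd.DataFrame]
    metadata: pd.DataFrame
    truth: dict

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata["sample_id"])


# ---------------------------------------------------------------------------
# motif-vector machinery
# ---------------------------------------------------------------------------

_CC_MASK = np.array([m.startswith("CC") for m in MOTIFS])
_TT_MASK = np.array([m.startswith("TT") for m in MOTIFS])


def _apply_motif_effect(
    base: np.ndarray, cc: float, tt: float, strength: float
) -> np.ndarray:
    """Scale CC-/TT-start motif mass by effect multipliers interpolated
    towards 1 by ``strength`` and renormalise."""
    mult = np.ones(N_MOTIFS)
    mult[_CC_MASK] = 1.0 + (cc - 1.0) * strength
    mult[_TT_MASK] = 1.0 + (tt - 1.0) * strength
    v = base * mult
    return v / v.sum()


# ---------------------------------------------------------------------------
# fragment length sampling
# ---------------------------------------------------------------------------


def sample_lengths(
    rng: np.random.Generator, n: int, sm: SizeModel, long_multiplier: float = 1.0
) -> np.ndarray:
    """Draw ``n`` fragment lengths from the mixture, with the long-component
    weight multiplied by ``long_multiplier`` (renormalised)."""
    w = np.array(
        [sm.short_weight, sm.medium_weight, sm.long_weight * long_multiplier]
    )
    w = w / w.sum()
    comp = rng.choice(3, size=n, p=w)
    out = np.empty(n, dtype=float)

    short = comp == 0
    if short.any():
        centers = sm.ladder_top_bp - sm.periodicity_bp * np.arange(sm.n_ladder_modes)
        mode_w = np.arange(sm.n_ladder_modes, 0, -1.0)  # heavier near the top
        mode_w /= mode_w.sum()
        which = rng.choice(sm.n_ladder_modes, size=int(short.sum()), p=mode_w)
        out[short] = rng.normal(centers[which], sm.ladder_sd_bp)

    medium = comp == 1
    if medium.any():
        k = int(medium.sum())
        vals = rng.normal(sm.mono_peak_bp, sm.mono_sd_bp, k)
        vals[rng.random(k) < sm.mono_mode_frac] = sm.mono_peak_bp
        out[medium] = vals

    long_ = comp == 2
    if long_.any():
        out[long_] = rng.normal(sm.di_peak_bp, sm.di_sd_bp, int(long_.sum()))

    return np.clip(np.rint(out), sm.min_bp, sm.max_bp).astype(np.int64)


# ---------------------------------------------------------------------------
# reference + placement
# ---------------------------------------------------------------------------


class _ContigIndex:
    """Position index of a contig: for each 4-mer code, the sorted start
    positions at which it occurs in the reference."""

    def __init__(self, codes: np.ndarray):
        self.length = len(codes)
        self.k4 = kmer_codes(codes)
        order = np.argsort(self.k4, kind="stable")
        counts = np.bincount(self.k4, minlength=N_MOTIFS)
        self.positions = order.astype(np.int64)
        self.counts = counts.astype(np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)


def _place_fragments(
    rng: np.random.Generator,
    idx: _ContigIndex,
    mp_codes: np.ndarray,
    mm_codes: np.ndarray,
    lengths: np.ndarray,
    bin_weights: np.ndarray,
    bin_size: int,
    max_rounds: int = 4000,
) -> np.ndarray:
    """Choose start positions so that the reference 4-mer at ``start`` equals
    the drawn plus-strand motif and the 4-mer ending at ``start + length``
    is the reverse complement of the drawn minus-strand motif, with bins
    accepted proportionally to ``bin_weights``. Returns start positions."""
    n = len(mp_codes)
    starts = np.full(n, -1, dtype=np.int64)
    target_end4 = REVCOMP_CODE[mm_codes].astype(np.int64)
    wmax = bin_weights.max() if len(bin_weights) else 1.0
    unresolved = np.arange(n)
    # drop fragments whose plus motif never occurs on this contig (tiny
    # contigs only); they fall back to a uniform draw below
    for _ in range(max_rounds):
        if unresolved.size == 0:
            break
        m = mp_codes[unresolved]
        cnt = idx.counts[m]
        drawable = cnt > 0
        if not drawable.all():
            unresolved = unresolved[drawable]
            if unresolved.size == 0:
                break
            m = mp_codes[unresolved]
            cnt = idx.counts[m]
        j = (rng.random(unresolved.size) * cnt).astype(np.int64)
        s = idx.positions[idx.offsets[m] + j]
        e = s + lengths[unresolved]
        ok = e <= idx.length
        e4 = np.minimum(e, idx.length) - 4
        ok &= idx.k4[np.clip(e4, 0, len(idx.k4) - 1)] == target_end4[unresolved]
        if len(bin_weights) > 1 or wmax != 1.0:
            w = bin_weights[np.minimum((s + lengths[unresolved] // 2) // bin_size,
                                       len(bin_weights) - 1)]
            ok &= rng.random(unresolved.size) < (w / wmax)
        starts[unresolved[ok]] = s[ok]
        unresolved = unresolved[~ok]

    # fallback for anything unresolved: uniform placement (motifs will be
    # re-read from the reference, so consistency still holds)
    left = starts < 0
    if left.any():
        hi = np.maximum(idx.length - lengths[left], 1)
        starts[left] = (rng.random(int(left.sum())) * hi).astype(np.int64)
    return starts


def _build_reference(rng: np.random.Generator, contig_lengths: Mapping[str, int]):
    codes = {c: rng.integers(0, 4, size=n, dtype=np.uint8)
             for c, n in contig_lengths.items()}
    return codes


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

_AGE = {"control": (43.1, 8.6), "DM": (58.7, 8.6), "DN": (55.1, 7.7)}
_BMI = {"control": (23.3, 3.4), "DM": (24.3, 3.5), "DN": (24.8, 2.7)}
_MALE_FRAC = {"control": 0.45, "DM": 0.53, "DN": 0.76}
_LOG_CONC = {"control": (-3.0, 0.35), "DM": (-3.0, 0.35), "DN": (-2.65, 0.45)}


def _draw_metadata(rng: np.random.Generator, group: str, egfr_model: EgfrModel):
    age = float(np.clip(rng.normal(*_AGE[group]), 18, 80))
    bmi = float(np.clip(rng.normal(*_BMI[group]), 15, 40))
    sex = "M" if rng.random() < _MALE_FRAC[group] else "F"
    egfr = float(
        np.clip(
            rng.normal(egfr_model.mean[group], egfr_model.sd[group]),
            egfr_model.minimum,
            egfr_model.maximum,
        )
    )
    conc = float(np.exp(rng.normal(*_LOG_CONC[group])))
    return age, sex, bmi, egfr, conc


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort. Deterministic given ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    contig_lengths = config.contig_lengths()
    ref_codes = _build_reference(rng, contig_lengths)
    indices = {c: _ContigIndex(codes) for c, codes in ref_codes.items()}
    autosomes = [c for c in contig_lengths if c != config.mito_contig]
    auto_len = np.array([contig_lengths[c] for c in autosomes], dtype=float)
    auto_p = auto_len / auto_len.sum()
    bin_size = config.mgr_model.bin_size
    n_bins = {c: max(1, int(np.ceil(contig_lengths[c] / bin_size)))
              for c in autosomes}
    total_bins = int(sum(n_bins.values()))

    base_vec = config.motif_model.base_vector()
    conc = config.motif_model.dirichlet_concentration

    sample_plan = (
        [("control", i) for i in range(config.n_control)]
        + [("DM", i) for i in range(config.n_dm)]
        + [("DN", i) for i in range(config.n_dn)]
    )

    fragments: dict[str, pd.DataFrame] = {}
    meta_rows = []
    truth_samples = {}

    for group, i in sample_plan:
        sid = f"{group}_{i:03d}"
        age, sex, bmi, egfr, cfdna_conc = _draw_metadata(
            rng, group, config.egfr_model
        )
        strength = config.egfr_model.strength(egfr)

        # per-sample motif distributions (short / long strata)
        if conc is None:
            sample_base = base_vec
        else:
            g = rng.gamma(np.maximum(base_vec * conc, 1e-12))
            sample_base = g / g.sum()
        cc = config.motif_model.cc_enrichment.get(group, 1.0)
        tt = config.motif_model.tt_depletion.get(group, 1.0)
        vec_short = _apply_motif_effect(sample_base, cc, tt, strength)
        vec_long = _apply_motif_effect(
            sample_base, cc, tt, strength * config.motif_model.long_attenuation
        )

        # lengths, with graded long-fragment depletion
        dep = config.size_model.long_depletion.get(group, 1.0)
        long_mult = 1.0 + (dep - 1.0) * strength
        n = config.fragments_per_sample
        lengths = sample_lengths(rng, n, config.size_model, long_mult)

        # contig assignment
        n_mito = rng.binomial(n, config.mito_share)
        contig_ids = np.empty(n, dtype=np.int64)  # -1 = mito
        contig_ids[:] = rng.choice(len(autosomes), size=n, p=auto_p)
        if n_mito:
            contig_ids[rng.choice(n, size=n_mito, replace=False)] = -1

        # aberrant-bin weights (per autosomal bin, global index)
        k_ab = config.mgr_model.n_aberrant_bins.get(group, 0)
        fold = config.mgr_model.distortion_fold
        bin_w_global = np.ones(total_bins)
        ab_bins = np.sort(rng.choice(total_bins, size=min(k_ab, total_bins),
                                     replace=False))
        for r, b in enumerate(ab_bins):
            bin_w_global[b] = fold if r % 2 == 0 else 1.0 / fold

        # motif draws per stratum
        short_mask = lengths <= config.motif_model.stratum_cutoff_bp
        mp = np.empty(n, dtype=np.int64)
        mm = np.empty(n, dtype=np.int64)
        for mask, vec in ((short_mask, vec_short), (~short_mask, vec_long)):
            k = int(mask.sum())
            if k:
                mp[mask] = rng.choice(N_MOTIFS, size=k, p=vec)
                mm[mask] = rng.choice(N_MOTIFS, size=k, p=vec)

        # placement per contig
        starts = np.empty(n, dtype=np.int64)
        bin_offset = 0
        for ci, contig in enumerate(autosomes):
            mask = contig_ids == ci
            nb = n_bins[contig]
            w = bin_w_global[bin_offset:bin_offset + nb]
            bin_offset += nb
            if not mask.any():
                continue
            starts[mask] = _place_fragments(
                rng, indices[contig], mp[mask], mm[mask], lengths[mask],
                w, bin_size,
            )
        mito_mask = contig_ids == -1
        if mito_mask.any():
            mito_lengths = np.minimum(lengths[mito_mask],
                                      config.mito_length - 8)
            lengths[mito_mask] = mito_lengths
            starts[mito_mask] = _place_fragments(
                rng, indices[config.mito_contig], mp[mito_mask],
                mm[mito_mask], mito_lengths, np.ones(1), bin_size,
            )

        # finalise: re-read motifs from the reference (guaranteed identical
        # for indexed placements; defines motifs for fallback placements)
        contig_names = np.array(autosomes + [config.mito_contig])
        name_idx = np.where(contig_ids >= 0, contig_ids, len(autosomes))
        ends = starts + lengths
        mp_final = np.empty(n, dtype=np.int64)
        mm_rc_final = np.empty(n, dtype=np.int64)
        for ci, contig in enumerate(list(autosomes) + [config.mito_contig]):
            mask = name_idx == ci
            if not mask.any():
                continue
            k4 = indices[contig].k4
            mp_final[mask] = k4[starts[mask]]
            mm_rc_final[mask] = k4[ends[mask] - 4]
        mm_final = REVCOMP_CODE[mm_rc_final]

        motif_arr = np.array(MOTIFS)
        frag = pd.DataFrame(
            {
                "contig": contig_names[name_idx],
                "start": starts,
                "end": ends,
                "length": lengths,
                "motif_plus": motif_arr[mp_final],
                "motif_minus": motif_arr[mm_final],
                "strand": np.where(rng.random(n) < 0.5, "+", "-"),
            }
        )
        fragments[sid] = frag
        meta_rows.append(
            dict(sample_id=sid, group=group, age=age, sex=sex, bmi=bmi,
                 egfr=egfr, concentration=cfdna_conc)
        )
        truth_samples[sid] = dict(
            group=group,
            effect_strength=strength,
            long_multiplier=long_mult,
            expected_motifs_short=vec_short.tolist(),
            expected_motifs_long=vec_long.tolist(),
            aberrant_bins=ab_bins.tolist(),
            n_mito=int(n_mito),
        )

    metadata = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "group", "age", "sex", "bmi", "egfr",
                 "concentration"],
    )
    reference = {c: codes_to_seq(codes) for c, codes in ref_codes.items()}
    truth = dict(
        config=_config_to_dict(config),
        group_vectors={
            g: config.motif_model.group_vector(g).tolist() for g in GROUPS
        },
        base_vector=base_vec.tolist(),
        contig_lengths=contig_lengths,
        samples=truth_samples,
    )
    return SyntheticCohort(
        reference=reference, fragments=fragments, metadata=metadata, truth=truth
    )


def _config_to_dict(config: GeneratorConfig) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return conv(config)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_fragments(cohort: SyntheticCohort, out_dir: str | Path) -> dict:
    """Write the cohort to disk: a FASTA reference, one BED6 fragment file
    per sample (chrom, start, end, fragment_id, length, strand-of-read1),
    a metadata TSV and a JSON truth file. Returns a manifest of paths."""
    out = Path(out_dir)
    frag_dir = out / "fragments"
    frag_dir.mkdir(parents=True, exist_ok=True)

    fasta = out / "reference.fa"
    with open(fasta, "w") as fh:
        for contig, seq in cohort.reference.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")

    bed_paths = {}
    for sid, df in cohort.fragments.items():
        path = frag_dir / f"{sid}.bed"
        bed = pd.DataFrame(
            {
                "chrom": df["contig"],
                "start": df["start"],
                "end": df["end"],
                "name": [f"{sid}:{j}" for j in range(len(df))],
                "score": df["length"],
                "strand": df["strand"],
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)
        bed_paths[sid] = str(path)

    meta_path = out / "metadata.tsv"
    cohort.metadata.to_csv(meta_path, sep="\t", index=False)

    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(cohort.truth, fh)

    return dict(
        reference=str(fasta),
        fragments=bed_paths,
        metadata=str(meta_path),
        truth=str(truth_path),
    )
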