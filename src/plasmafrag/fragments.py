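"""Reading aligned paired-end cfDNA data and extracting fragment end motifs.

Input is either a coordinate-level fragment BED (chrom, start, end, name,
score, strand) or a BAM/SAM of paired-end alignments. Retention filters
follow standard cfDNA practice: properly oriented pairs, at most 3
mismatches, insert size within 600 bp, and no multi-mapping (MAPQ cutoff or
secondary-alignment flag). The two 5' 4-mer end motifs of each fragment are
read from the *reference* genome at the fragment end coordinates — robust to
base-call errors and sufficient for BED-only input.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .motifs import kmer_codes, seq_to_codes, MOTIFS, REVCOMP_CODE

FRAGMENT_COLUMNS = [
    "contig", "start", "end", "length", "motif_plus", "motif_minus",
    "valid_motif",
]


class ReferenceMismatchError(KeyError):
    """Input refers to a contig absent from the reference."""


@dataclass(frozen=True)
class Fragment:
    """One sequenced cfDNA molecule."""

    contig: str
    start: int
    end: int
    motif_plus: str
    motif_minus: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FilterPolicy:
    """Retention rules for aligned read pairs.

    ``max_mismatches`` uses the NM tag (records lacking NM pass with a
    warning); multi-mapping is operationalised as MAPQ below ``min_mapq`` or
    a secondary/supplementary flag. Set a field to ``None`` to disable the
    corresponding filter.
    """

    max_mismatches: int | None = 3
    max_insert: int | None = 600
    require_proper_orientation: bool = True
    exclude_multimapped: bool = True
    min_mapq: int = 30

    def __post_init__(self):
        for name in ("max_mismatches", "max_insert"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be non-negative")


#: fully permissive policy (used for lossless round-trips of generated data)
PERMISSIVE = FilterPolicy(
    max_mismatches=None,
    max_insert=None,
    require_proper_orientation=False,
    exclude_multimapped=False,
    min_mapq=0,
)


@dataclass
class FilterStats:
    """Counts of records/pairs dropped per retention rule."""

    n_records: int = 0
    n_pairs: int = 0
    dropped_unmapped: int = 0
    dropped_multimapped: int = 0
    dropped_mismatch: int = 0
    dropped_orientation: int = 0
    dropped_insert_size: int = 0
    dropped_malformed: int = 0
    invalid_motif: int = 0
    retained: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# reference handling
# ---------------------------------------------------------------------------


def load_reference(reference) -> dict[str, np.ndarray]:
    """Normalise a reference (FASTA path, pyfaidx.Fasta, or dict of contig
    strings) into encoded uint8 base-code arrays."""
    if isinstance(reference, dict):
        first = next(iter(reference.values()), None)
        if isinstance(first, np.ndarray):
            return reference  # already encoded
        return {c: seq_to_codes(str(s)) for c, s in reference.items()}
    if isinstance(reference, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(reference))
        return {name: seq_to_codes(str(fa[name][:])) for name in fa.keys()}
    # pyfaidx.Fasta or similar mapping of records
    return {name: seq_to_codes(str(reference[name][:]))
            for name in reference.keys()}


def _extract_motifs(
    df: pd.DataFrame, ref_codes: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Attach reference-derived end motifs to a (contig, start, end) table."""
    n = len(df)
    plus = np.full(n, "NNNN", dtype=object)
    minus = np.full(n, "NNNN", dtype=object)
    valid = np.zeros(n, dtype=bool)
    motif_arr = np.array(MOTIFS, dtype=object)
    for contig, grp in df.groupby("contig", sort=False):
        if contig not in ref_codes:
            raise ReferenceMismatchError(
                f"contig {contig!r} not present in reference"
            )
        k4 = kmer_codes(ref_codes[contig])
        clen = len(ref_codes[contig])
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        in_bounds = (starts >= 0) & (ends <= clen) & (ends - starts >= 4)
        ploc = np.clip(starts, 0, len(k4) - 1)
        mloc = np.clip(ends - 4, 0, len(k4) - 1)
        pc = k4[ploc]
        mc = k4[mloc]
        ok = in_bounds & (pc >= 0) & (mc >= 0)
        idx = grp.index.to_numpy()
        plus[df.index.get_indexer(idx[ok])] = motif_arr[pc[ok]]
        minus[df.index.get_indexer(idx[ok])] = motif_arr[REVCOMP_CODE[mc[ok]]]
        valid[df.index.get_indexer(idx)] = ok
    out = df.copy()
    out["motif_plus"] = plus
    out["motif_minus"] = minus
    out["valid_motif"] = valid
    return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_fragments(
    path: str | Path,
    reference,
    policy: FilterPolicy | None = None,
) -> tuple[pd.DataFrame, FilterStats]:
    """Read a fragment BED or a BAM/SAM, apply the retention policy, and
    return a fragment table with reference-derived end motifs plus the
    filter statistics.

    Fragments whose motif window contains N are retained (for size and
    coverage features) but flagged ``valid_motif=False`` and counted in
    ``FilterStats.invalid_motif``.
    """
    policy = policy or FilterPolicy()
    path = Path(path)
    ref_codes = load_reference(reference)
    if path.suffix.lower() in {".bam", ".sam", ".cram"}:
        df, stats = _read_pairs(path, policy)
    else:
        df, stats = _read_bed(path, policy)
    df = _extract_motifs(df, ref_codes)
    stats.invalid_motif = int((~df["valid_motif"]).sum())
    stats.retained = len(df)
    return df.reset_index(drop=True), stats


def _read_bed(path: Path, policy: FilterPolicy) -> tuple[pd.DataFrame, FilterStats]:
    stats = FilterStats()
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["contig", "start", "end"],
            dtype={0: str, 1: np.int64, 2: np.int64},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed BED {path}: {exc}") from exc
    stats.n_records = stats.n_pairs = len(raw)
    bad = raw["end"] <= raw["start"]
    stats.dropped_malformed = int(bad.sum())
    raw = raw[~bad]
    if policy.max_insert is not None:
        too_long = (raw["end"] - raw["start"]) > policy.max_insert
        stats.dropped_insert_size = int(too_long.sum())
        raw = raw[~too_long]
    raw = raw.copy()
    raw["length"] = raw["end"] - raw["start"]
    return raw, stats


def _read_pairs(path: Path, policy: FilterPolicy) -> tuple[pd.DataFrame, FilterStats]:
    import pysam

    stats = FilterStats()
    pending: dict[str, tuple] = {}
    rows = []
    nm_warned = False
    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            stats.n_records += 1
            if rec.is_secondary or rec.is_supplementary:
                stats.dropped_multimapped += 1
                continue
            if rec.is_unmapped or rec.mate_is_unmapped or not rec.is_paired:
                stats.dropped_unmapped += 1
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else None
            info = (
                rec.reference_name, rec.reference_start, rec.reference_end,
                rec.is_reverse, rec.mapping_quality, nm,
            )
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = info
                continue
            stats.n_pairs += 1
            row, reason, warn_nm = _evaluate_pair(mate, info, policy)
            if warn_nm and not nm_warned:
                warnings.warn(
                    "records without NM tag pass the mismatch filter",
                    stacklevel=2,
                )
                nm_warned = True
            if reason is not None:
                setattr(stats, reason, getattr(stats, reason) + 1)
            else:
                rows.append(row)
    # orphan reads whose mate never appeared
    stats.dropped_unmapped += len(pending)
    df = pd.DataFrame(rows, columns=["contig", "start", "end"])
    if len(df):
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["length"] = df["end"] - df["start"]
    else:
        df = pd.DataFrame(
            {"contig": pd.Series(dtype=str),
             "start": pd.Series(dtype=np.int64),
             "end": pd.Series(dtype=np.int64),
             "length": pd.Series(dtype=np.int64)}
        )
    return df, stats


def _evaluate_pair(a: tuple, b: tuple, policy: FilterPolicy):
    """Apply pair-level filters; returns (row, drop_reason, nm_missing)."""
    (ctg_a, s_a, e_a, rev_a, mq_a, nm_a) = a
    (ctg_b, s_b, e_b, rev_b, mq_b, nm_b) = b
    nm_missing = nm_a is None or nm_b is None
    if policy.exclude_multimapped and min(mq_a, mq_b) < policy.min_mapq:
        return None, "dropped_multimapped", nm_missing
    if policy.max_mismatches is not None:
        for nm in (nm_a, nm_b):
            if nm is not None and nm > policy.max_mismatches:
                return None, "dropped_mismatch", nm_missing
    if policy.require_proper_orientation:
        left, right = (a, b) if s_a <= s_b else (b, a)
        fr = (ctg_a == ctg_b) and (not left[3]) and right[3]
        if not fr:
            return None, "dropped_orientation", nm_missing
    start = min(s_a, s_b)
    end = max(e_a, e_b)
    if end <= start:
        return None, "dropped_malformed", nm_missing
    if policy.max_insert is not None and end - start > policy.max_insert:
        return None, "dropped_insert_size", nm_missing
    return (ctg_a, start, end), None, nm_missing


# ---------------------------------------------------------------------------
# mitochondrial abundance
# ---------------------------------------------------------------------------


def contig_counts(frag_df: pd.DataFrame) -> dict[str, int]:
    return frag_df["contig"].value_counts().to_dict()


def mito_abundance(
    fragments_per_contig: Mapping[str, int], mito_contig: str = "chrM"
) -> float:
    """Mitochondrial fragments per million counted fragments.

    Each retained fragment is one read pair, so this equals the conventional
    mitochondrial reads-per-million-reads measure.
    """
    total = sum(fragments_per_contig.values())
    if total <= 0:
        raise ValueError("total mapped count must be positive")
    return 1e6 * fragments_per_contig.get(mito_contig, 0) / total
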