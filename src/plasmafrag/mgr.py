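"""Measured genomic representation (MGR): 1-Mb bin coverage z-scores.

The MGR of a bin is the fraction of a sample's counted fragments whose
midpoint falls in that bin. A reference panel of randomly chosen control
samples provides a per-bin mean and standard deviation; a scored sample's
per-bin z-score is (MGR - mean) / sd, and bins with z < -3 or z > 3 (strict)
are called aberrant. The per-sample summary is the fraction of unmasked bins
flagged aberrant.

No GC or mappability correction is applied; raw bin fractions are used
(documented limitation). The grid covers autosomes only; bins are anchored
at coordinate 0 of each contig and a terminal partial bin is kept only if at
least ``min_final`` bp long.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

Z_THRESHOLD = 3.0

_DEFAULT_EXCLUDE = ("chrM", "chrMT", "M", "MT", "chrX", "chrY", "X", "Y")


@dataclass
class BinGrid:
    """Ordered, non-overlapping, half-open bins covering the autosomes."""

    table: pd.DataFrame  # columns: contig, start, end

    @classmethod
    def from_contig_lengths(
        cls,
        contig_lengths: Mapping[str, int],
        bin_size: int = 1_000_000,
        min_final: int = 500_000,
        exclude: Sequence[str] = _DEFAULT_EXCLUDE,
    ) -> "BinGrid":
        rows = []
        for contig, length in contig_lengths.items():
            if contig in exclude:
                continue
            start = 0
            while start < length:
                end = min(start + bin_size, length)
                if end - start >= min(min_final, bin_size):
                    rows.append((contig, start, end))
                start = end
        if not rows:
            raise ValueError("bin grid is empty; genome too small or excluded")
        return cls(pd.DataFrame(rows, columns=["contig", "start", "end"]))

    @property
    def n_bins(self) -> int:
        return len(self.table)

    def bin_counts(self, fragments: pd.DataFrame) -> np.ndarray:
        """Count fragments per bin by midpoint; fragments outside the grid
        (excluded contigs, dropped terminal tails) are not counted."""
        counts = np.zeros(self.n_bins, dtype=np.int64)
        mids = (fragments["start"].to_numpy() + fragments["end"].to_numpy()) // 2
        contigs = fragments["contig"].to_numpy()
        for contig, grp in self.table.groupby("contig", sort=False):
            mask = contigs == contig
            if not mask.any():
                continue
            edges = np.append(grp["start"].to_numpy(), grp["end"].to_numpy()[-1])
            m = mids[mask]
            which = np.searchsorted(edges, m, side="right") - 1
            ok = (which >= 0) & (which < len(grp)) & (m < edges[-1])
            # guard against gaps from a dropped terminal bin
            ok &= m >= edges[0]
            np.add.at(counts, grp.index.to_numpy()[which[ok]], 1)
        return counts


@dataclass
class ReferencePanel:
    """Per-bin MGR mean/sd over the reference control samples."""

    grid: BinGrid
    mean: np.ndarray
    sd: np.ndarray
    masked: np.ndarray  # True = excluded from scoring
    member_ids: list[str]

    @property
    def n_ref(self) -> int:
        return len(self.member_ids)

    @property
    def n_unmasked(self) -> int:
        return int((~self.masked).sum())


@dataclass
class MgrResult:
    """Per-bin MGR, z-scores, aberrant flags, and the aberrant-bin fraction
    over unmasked bins. Masked bins carry NaN z-scores."""

    mgr: np.ndarray
    z: np.ndarray
    aberrant: np.ndarray
    aberrant_fraction: float
    n_unmasked: int


def mgr_fractions(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample has zero counted fragments on the grid")
    return counts / total


def build_panel(
    control_counts: Mapping[str, np.ndarray],
    grid: BinGrid,
    n_ref: int = 10,
    seed: int = 0,
) -> ReferencePanel:
    """Build a reference panel from ``n_ref`` randomly chosen controls
    (seeded draw over sorted sample ids, so the member set is deterministic).
    Bins with zero panel sd or zero panel coverage are masked."""
    ids = sorted(control_counts)
    if len(ids) < n_ref:
        raise ValueError(
            f"need at least n_ref={n_ref} control samples, got {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    members = sorted(rng.choice(ids, size=n_ref, replace=False).tolist())
    mat = np.vstack([mgr_fractions(control_counts[s]) for s in members])
    if mat.shape[1] != grid.n_bins:
        raise ValueError("control count vectors do not match the grid")
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    # relative tolerance absorbs float rounding on a degenerate panel
    masked = (sd <= mean * 1e-9) | (mean == 0)
    return ReferencePanel(grid=grid, mean=mean, sd=sd, masked=masked,
                          member_ids=members)


def score_sample(sample_counts: np.ndarray, panel: ReferencePanel) -> MgrResult:
    """z-score a sample's bin counts against the panel; |z| > 3 (strict)
    flags a bin as aberrant."""
    counts = np.asarray(sample_counts, dtype=float)
    if counts.shape[0] != panel.grid.n_bins:
        raise ValueError("sample counts do not match the panel grid")
    mgr = mgr_fractions(counts)
    z = np.full(panel.grid.n_bins, np.nan)
    ok = ~panel.masked
    z[ok] = (mgr[ok] - panel.mean[ok]) / panel.sd[ok]
    aberrant = np.zeros(panel.grid.n_bins, dtype=bool)
    aberrant[ok] = np.abs(z[ok]) > Z_THRESHOLD
    n_unmasked = int(ok.sum())
    frac = float(aberrant.sum() / n_unmasked) if n_unmasked else float("nan")
    return MgrResult(
        mgr=mgr, z=z, aberrant=aberrant, aberrant_fraction=frac,
        n_unmasked=n_unmasked,
    )
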