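"""Strand-aware tag tracks and numeric genome tracks.

A :class:`TagTrack` stores, per chromosome and strand, the sorted 5' end
positions of mapped reads with multiplicities.  Windowed tag counting and
strand cross-correlation fragment-shift estimation operate on it.  A
:class:`NumericTrack` stores sorted non-overlapping scored intervals
(bedGraph semantics) and supports per-base window averaging.

All windows are inclusive on both ends: a halfwidth of ``h`` around center
``c`` covers the ``2 h + 1`` bases ``[c - h, c + h]``.  Windows overrunning
a chromosome end are truncated, not dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pwm import SiteList

STRANDS = ("+", "-")


class ShiftUndefinedError(ValueError):
    """Raised when fragment-shift estimation lacks tags on a strand."""


@dataclass
class TagTrack:
    """Per-chromosome, strand-separated multisets of read 5' positions."""

    #: data[chrom][strand] = (positions ascending, multiplicities >= 1)
    data: dict = field(default_factory=dict)
    name: str = "tags"

    @classmethod
    def from_positions(cls, records, name: str = "tags") -> "TagTrack":
        """Build from an iterable of ``(chrom, position, strand)`` tuples."""
        frame = pd.DataFrame(records, columns=["chrom", "pos", "strand"])
        return cls._from_frame(frame, name)

    @classmethod
    def _from_frame(cls, frame: pd.DataFrame, name: str) -> "TagTrack":
        data: dict = {}
        key = "count" if "count" in frame.columns else None
        for (chrom, strand), sub in frame.groupby(["chrom", "strand"], sort=True):
            if strand not in STRANDS:
                raise ValueError(f"invalid strand {strand!r}")
            if key is None:
                counts = sub.groupby("pos").size()
            else:
                counts = sub.groupby("pos")["count"].sum()
            positions = counts.index.to_numpy(dtype=np.int64)
            mult = counts.to_numpy(dtype=np.int64)
            if (mult < 1).any():
                raise ValueError("multiplicities must be >= 1")
            data.setdefault(chrom, {})[strand] = (positions, mult)
        return cls(data, name=name)

    def strand_arrays(self, chrom: str, strand: str):
        """``(positions, multiplicities)`` for one chromosome/strand."""
        empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        return self.data.get(chrom, {}).get(strand, empty)

    @property
    def chromosomes(self):
        return sorted(self.data)

    def total_tags(self, dedup: bool = False) -> int:
        total = 0
        for chrom in self.data:
            for strand in self.data[chrom]:
                pos, mult = self.data[chrom][strand]
                total += len(pos) if dedup else int(mult.sum())
        return total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.data):
            for strand in STRANDS:
                pos, mult = self.strand_arrays(chrom, strand)
                for p, m in zip(pos, mult):
                    rows.append((chrom, int(p), strand, int(m)))
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])


@dataclass
class NumericTrack:
    """Sorted non-overlapping ``(start, end, value)`` intervals per chromosome."""

    #: data[chrom] = (starts, ends, values) as aligned arrays
    data: dict = field(default_factory=dict)
    name: str = "track"

    @classmethod
    def from_intervals(cls, records, name: str = "track") -> "NumericTrack":
        """Build from ``(chrom, start, end, value)`` tuples (0-based half-open)."""
        frame = pd.DataFrame(records, columns=["chrom", "start", "end", "value"])
        data = {}
        for chrom, sub in frame.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if (starts >= ends).any():
                raise ValueError("intervals must satisfy start < end")
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping intervals on {chrom}")
            data[chrom] = (starts, ends, sub["value"].to_numpy(dtype=float))
        return cls(data, name=name)

    def interval_arrays(self, chrom: str):
        empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                 np.empty(0))
        return self.data.get(chrom, empty)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.data):
            starts, ends, values = self.data[chrom]
            for s, e, v in zip(starts, ends, values):
                rows.append((chrom, int(s), int(e), float(v)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def _binned_counts(positions, multiplicities, lo, hi):
    counts = np.zeros(hi - lo + 1)
    mask = (positions >= lo) & (positions <= hi)
    np.add.at(counts, positions[mask] - lo, multiplicities[mask])
    return counts


def estimate_fragment_shift(track: TagTrack, max_shift: int = 400,
                            smooth: int = 5) -> int:
    """Half the fragment length estimated by strand cross-correlation.

    For each chromosome, 1-bp binned plus- and minus-strand count vectors
    are cross-correlated at displacements ``d`` in ``[0, max_shift]``
    (minus-strand counts displaced upstream by ``d``); correlations are
    summed over chromosomes.  Because 1-bp counts are sparse, the peak is
    located on a ``smooth``-wide moving average and then refined to the
    raw-correlation maximum within that window (ties to the smallest
    ``d``); the estimate is ``round(d* / 2)``.
    """
    corr = np.zeros(max_shift + 1)
    any_plus = any_minus = False
    for chrom in track.chromosomes:
        ppos, pmult = track.strand_arrays(chrom, "+")
        mpos, mmult = track.strand_arrays(chrom, "-")
        any_plus |= len(ppos) > 0
        any_minus |= len(mpos) > 0
        if len(ppos) == 0 or len(mpos) == 0:
            continue
        lo = int(min(ppos.min(), mpos.min()))
        hi = int(max(ppos.max(), mpos.max()))
        plus = _binned_counts(ppos, pmult, lo, hi)
        minus = _binned_counts(mpos, mmult, lo, hi)
        # corr[d] = sum_x plus[x] * minus[x + d]
        from scipy.signal import correlate as _xcorr
        full = _xcorr(minus, plus, mode="full", method="fft")
        center = len(plus) - 1
        upto = min(max_shift, len(plus) - 1)
        corr[:upto + 1] += full[center:center + upto + 1]
    if not (any_plus and any_minus):
        raise ShiftUndefinedError("both strands must carry tags")
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        peak = int(np.argmax(np.convolve(corr, kernel, mode="same")))
        lo = max(0, peak - smooth // 2)
        hi = min(len(corr), peak + smooth // 2 + 1)
        d_star = lo + int(np.argmax(corr[lo:hi]))
    else:
        d_star = int(np.argmax(corr))  # first (smallest d) on ties
    return int(round(d_star / 2))


def count_tags(track: TagTrack, sites: SiteList, halfwidth: int,
               shift: int = 0, dedup: bool = True) -> np.ndarray:
    """Per-site tag counts in ``[center - halfwidth, center + halfwidth]``.

    Plus-strand positions are moved downstream by ``shift`` and
    minus-strand positions upstream by ``shift`` before counting.  With
    ``dedup``, multiple tags at the same position (per strand) count once.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    counts = np.zeros(len(sites), dtype=np.int64)
    frame = sites.frame
    for chrom, sub in frame.groupby("chrom", sort=False):
        centers = sub["center"].to_numpy()
        idx = sub.index.to_numpy()
        for strand, sign in (("+", +1), ("-", -1)):
            pos, mult = track.strand_arrays(chrom, strand)
            if len(pos) == 0:
                continue
            shifted = pos + sign * shift
            lo = np.searchsorted(shifted, centers - halfwidth, side="left")
            hi = np.searchsorted(shifted, centers + halfwidth, side="right")
            if dedup:
                counts[idx] += hi - lo
            else:
                cum = np.concatenate([[0], np.cumsum(mult)])
                counts[idx] += cum[hi] - cum[lo]
    return counts


def average_track(track: NumericTrack, sites: SiteList,
                  halfwidth: int) -> np.ndarray:
    """Per-site base-resolution mean of a numeric track over the window.

    Bases covered by no interval contribute value 0; the denominator is
    always the full (possibly chromosome-truncated) window width.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    means = np.zeros(len(sites))
    frame = sites.frame
    for chrom, sub in frame.groupby("chrom", sort=False):
        starts, ends, values = track.interval_arrays(chrom)
        for row in sub.itertuples():
            lo = max(0, row.center - halfwidth)
            hi = row.center + halfwidth  # inclusive
            width = hi - lo + 1
            if len(starts) == 0:
                continue
            first = np.searchsorted(ends, lo, side="right")
            last = np.searchsorted(starts, hi + 1, side="left")
            total = 0.0
            for k in range(first, last):
                overlap = min(hi + 1, ends[k]) - max(lo, starts[k])
                if overlap > 0:
                    total += overlap * values[k]
            means[row.Index] = total / width
    return means


def snp_density_track(snp_positions: SiteList,
                      region_halfwidth: int = 100) -> NumericTrack:
    """Per-base SNP count track for consumption by :func:`average_track`.

    ``region_halfwidth`` documents the extent around binding sites within
    which SNPs are expected to have been collected; the track itself simply
    records one interval per SNP position (counting duplicates).
    """
    del region_halfwidth  # collection extent; does not alter the track
    records = []
    counts = snp_positions.frame.groupby(["chrom", "center"]).size()
    for (chrom, pos), n in counts.items():
        records.append((chrom, int(pos), int(pos) + 1, float(n)))
    return NumericTrack.from_intervals(records, name="snp")
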