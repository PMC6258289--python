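"""Consensus peak set and median summit-coverage normalization.

The consensus is the per-base rule: a base belongs to the consensus iff peaks
from at least ``min_samples`` distinct samples cover it; maximal runs of such
bases form the consensus intervals. Each sample's coverage track is then
rescaled so that its median "summit coverage" — mean per-base coverage in the
central 50-bp bin of each consensus peak — equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import CoverageTrack
from .intervals import GenomicInterval, PeakSet, merge_intervals, overlap_pairs

__all__ = [
    "ConsensusPeakSet",
    "build_consensus",
    "summit_bin",
    "summit_coverage",
    "normalize_track",
    "NormalizationError",
]


@dataclass
class ConsensusPeakSet:
    """Merged consensus intervals with per-interval sample support."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    support: list[int] = field(default_factory=list)
    supporting_samples: list[tuple[str, ...]] = field(default_factory=list)
    min_samples: int = 2

    def __post_init__(self) -> None:
        if len(self.support) != len(self.intervals):
            raise ValueError("one support count per interval required")
        for i, (iv, sup) in enumerate(zip(self.intervals, self.support)):
            if sup < self.min_samples:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} support {sup} "
                    f"< min_samples {self.min_samples}"
                )
            if i and self.intervals[i - 1].chrom == iv.chrom and iv.start < self.intervals[i - 1].end:
                raise ValueError("consensus intervals must be non-overlapping and sorted")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def region_ids(self) -> list[str]:
        return [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.intervals]

    def to_peakset(self) -> PeakSet:
        return PeakSet("consensus", "NA", list(self.intervals), [float(s) for s in self.support])


def build_consensus(peak_sets: list[PeakSet], min_samples: int = 2) -> ConsensusPeakSet:
    """Per-base >=``min_samples``-distinct-sample support rule.

    A sample's own overlapping peaks are merged first so each sample counts
    at most once per base. Support per consensus interval = number of distinct
    samples with >=1 bp overlap.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if len(peak_sets) < min_samples:
        raise ValueError(
            f"{len(peak_sets)} peak sets given but min_samples={min_samples}"
        )
    merged_per_sample = [merge_intervals(ps.intervals) for ps in peak_sets]
    # sweep event boundaries per chromosome, counting distinct samples
    events: dict[str, list[tuple[int, int]]] = {}
    for ivs in merged_per_sample:
        for iv in ivs:
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    consensus: list[GenomicInterval] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        depth = 0
        run_start: int | None = None
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            while i < len(evs) and evs[i][0] == pos:
                depth += evs[i][1]
                i += 1
            if depth >= min_samples and run_start is None:
                run_start = pos
            elif depth < min_samples and run_start is not None:
                if pos > run_start:
                    consensus.append(GenomicInterval(chrom, run_start, pos))
                run_start = None
    cons_ps = PeakSet("consensus", "NA", consensus)
    sorted_ivs = cons_ps.intervals
    supporters: list[set[str]] = [set() for _ in sorted_ivs]
    for ps, merged in zip(peak_sets, merged_per_sample):
        for ci, _ in overlap_pairs(sorted_ivs, merged):
            supporters[ci].add(ps.sample_id)
    return ConsensusPeakSet(
        sorted_ivs,
        [len(s) for s in supporters],
        [tuple(sorted(s)) for s in supporters],
        min_samples,
    )


def summit_bin(interval: GenomicInterval, bin_bp: int = 50) -> tuple[int, int]:
    """Central ``bin_bp``-wide window of a peak, centered on
    ``floor((start+end)/2)`` and clipped to the peak span; peaks shorter than
    ``bin_bp`` use their full span."""
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    if len(interval) <= bin_bp:
        return interval.start, interval.end
    center = (interval.start + interval.end) // 2
    lo = center - bin_bp // 2
    hi = lo + bin_bp
    lo = max(lo, interval.start)
    hi = min(hi, interval.end)
    return lo, hi


def summit_coverage(
    consensus: ConsensusPeakSet, track: CoverageTrack, bin_bp: int = 50
) -> np.ndarray:
    """Mean per-base coverage in each consensus peak's central bin — one
    sample's column of the summit-coverage matrix."""
    out = np.empty(len(consensus), dtype=np.float64)
    for i, iv in enumerate(consensus):
        lo, hi = summit_bin(iv, bin_bp)
        out[i] = track.mean_over(iv.chrom, lo, hi)
    return out


class NormalizationError(ValueError):
    """Degenerate sample: median summit coverage is zero."""


def normalize_track(track: CoverageTrack, summit_values: np.ndarray) -> CoverageTrack:
    """Divide every coverage value by the sample's median summit coverage.

    The median is taken over all consensus peaks, zeros included. After
    normalization the median summit coverage recomputed on the same consensus
    equals 1.
    """
    med = float(np.median(np.asarray(summit_values, dtype=np.float64)))
    if med <= 0:
        raise NormalizationError(
            f"sample {track.sample_id}: median summit coverage is {med}"
        )
    return track.scaled(1.0 / med)
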