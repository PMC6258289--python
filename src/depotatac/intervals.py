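"""Genomic interval data model and BED-based interval algebra.

All coordinates are 0-based half-open (BED convention) on named chromosomes.
Chromosomes are ordered lexicographically by name; no genome build or sequence
is ever required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "BedParseError",
    "parse_bed",
    "write_bed",
    "overlap_pairs",
    "subtract_blacklist",
    "merge_intervals",
]

_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakSet:
    """An ordered collection of intervals from one sample.

    Intervals are kept sorted by ``(chrom, start, end)``; overlap within a
    sample is permitted. ``depot`` labels the anatomical origin of the sample
    ('A' abdominal, 'GF' gluteofemoral, 'NA' unknown/not applicable).
    """

    sample_id: str = "sample"
    depot: str = "NA"
    intervals: list[GenomicInterval] = field(default_factory=list)
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        if self.depot not in ("A", "GF", "NA"):
            raise ValueError(f"depot must be 'A', 'GF' or 'NA', got {self.depot!r}")
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (
                self.intervals[i].chrom,
                self.intervals[i].start,
                self.intervals[i].end,
            ),
        )
        self.intervals = [self.intervals[i] for i in order]
        if self.scores is not None:
            if len(self.scores) != len(self.intervals):
                raise ValueError("scores must have one value per interval")
            self.scores = [self.scores[i] for i in order]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def chromosomes(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})


class BedParseError(ValueError):
    """Raised for malformed BED input; names the offending line."""


def _open_maybe(path_or_stream):
    if hasattr(path_or_stream, "read"):
        return path_or_stream, False
    return open(path_or_stream, "rt"), True


def parse_bed(path_or_stream, sample_id: str = "sample", depot: str = "NA") -> PeakSet:
    """Read a BED3/BED6 file into a :class:`PeakSet`.

    Coordinates are taken as 0-based half-open. ``track``/``browser`` header
    lines and blank/comment lines are skipped; columns beyond 6 are ignored.
    Column 5 (score), when present and numeric, is retained.
    """
    handle, close = _open_maybe(path_or_stream)
    intervals: list[GenomicInterval] = []
    scores: list[float] = []
    any_score = False
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(f"line {lineno}: non-integer coordinate") from None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from None
            score = 0.0
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                    any_score = True
                except ValueError:
                    pass
            scores.append(score)
    finally:
        if close:
            handle.close()
    return PeakSet(sample_id, depot, intervals, scores if any_score else None)


def write_bed(peaks: PeakSet, path_or_stream) -> None:
    """Write a :class:`PeakSet` as BED (BED6 when strand or score carries
    information, BED3 otherwise)."""
    if hasattr(path_or_stream, "write"):
        handle, close = path_or_stream, False
    else:
        handle, close = open(path_or_stream, "wt"), True
    try:
        six = peaks.scores is not None or any(iv.strand != "." for iv in peaks)
        for i, iv in enumerate(peaks):
            if six:
                score = peaks.scores[i] if peaks.scores is not None else 0.0
                score_s = f"{score:g}"
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t{score_s}\t{iv.strand}\n"
                )
            else:
                handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    finally:
        if close:
            handle.close()


def _trees_by_chrom(peaks: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(peaks):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    return trees


def overlap_pairs(
    a: PeakSet | Sequence[GenomicInterval],
    b: PeakSet | Sequence[GenomicInterval],
    min_bp: int = 1,
) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` with ``a[i]`` and ``b[j]`` intersecting by at
    least ``min_bp`` bases. Symmetric under swapping the two sets (with the
    pair order swapped)."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    a_ivs = list(a)
    trees = _trees_by_chrom(b)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(a_ivs):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_bp:
                pairs.append((i, hit.data))
    pairs.sort()
    return pairs


def subtract_blacklist(peaks: PeakSet, blacklist: PeakSet) -> PeakSet:
    """Drop every peak that overlaps (>=1 bp) any blacklist interval.

    Input order is preserved; the operation is idempotent.
    """
    bad = {i for i, _ in overlap_pairs(peaks, blacklist)}
    keep = [i for i in range(len(peaks)) if i not in bad]
    return PeakSet(
        peaks.sample_id,
        peaks.depot,
        [peaks.intervals[i] for i in keep],
        [peaks.scores[i] for i in keep] if peaks.scores is not None else None,
    )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: maximal non-overlapping runs, strand discarded."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out
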