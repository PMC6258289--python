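"""Per-base fragment coverage tracks and bedGraph I/O.

Coverage is held as one dense float64 vector per chromosome. Sequenced
fragments are extended to a fixed length (default 150 bp) anchored at their
5' end before being piled up, mirroring standard tag-directory handling of
single-end accessibility data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, PeakSet

__all__ = ["CoverageTrack", "coverage_from_fragments", "write_bedgraph", "read_bedgraph"]


@dataclass
class CoverageTrack:
    """Fragment coverage for one sample: ``values[chrom][pos]`` = number of
    (extended) fragments covering base ``pos``. Values may be rescaled by a
    normalization scalar and are therefore floats."""

    sample_id: str = "sample"
    values: dict[str, np.ndarray] = field(default_factory=dict)
    total_fragments: int = 0

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 1:
                raise ValueError(f"coverage for {chrom} must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"negative coverage on {chrom}")
            self.values[chrom] = arr
        if self.total_fragments < 1 and any(
            arr.size and arr.max() > 0 for arr in self.values.values()
        ):
            raise ValueError("total_fragments must be >= 1 when any value > 0")

    def value_at(self, chrom: str, pos: int) -> float:
        arr = self.values.get(chrom)
        if arr is None or pos < 0 or pos >= arr.size:
            return 0.0
        return float(arr[pos])

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base coverage over ``[start, end)``; bases outside the
        stored vector count as zero."""
        if end <= start:
            raise ValueError("empty window")
        arr = self.values.get(chrom)
        if arr is None:
            return 0.0
        lo, hi = max(start, 0), min(end, arr.size)
        if hi <= lo:
            return 0.0
        return float(arr[lo:hi].sum(dtype=np.float64)) / (end - start)

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            self.sample_id,
            {c: a * float(factor) for c, a in self.values.items()},
            self.total_fragments,
        )

    def total_mass(self) -> float:
        return float(sum(a.sum(dtype=np.float64) for a in self.values.values()))


def coverage_from_fragments(
    fragments: PeakSet,
    extend_to: int = 150,
    anchor: str = "five_prime",
    chrom_lengths: dict[str, int] | None = None,
) -> CoverageTrack:
    """Pile up fragments after extending each to ``extend_to`` bases.

    ``anchor='five_prime'`` places the extended interval from the fragment's
    5' position (strand-aware; left-anchored when unstranded);
    ``anchor='center'`` centers it on the fragment midpoint. Extended
    intervals are clipped at position 0 and, when ``chrom_lengths`` is given,
    at the chromosome end — clipping trims the conserved mass accordingly.
    """
    if extend_to < 1:
        raise ValueError("extend_to must be >= 1")
    if anchor not in ("five_prime", "center"):
        raise ValueError("anchor must be 'five_prime' or 'center'")
    lengths: dict[str, int] = dict(chrom_lengths or {})
    spans: dict[str, list[tuple[int, int]]] = {}
    for iv in fragments:
        if anchor == "center":
            mid = iv.midpoint
            s = mid - extend_to // 2
        elif iv.strand == "-":
            s = iv.end - extend_to
        else:
            s = iv.start
        e = s + extend_to
        s = max(s, 0)
        spans.setdefault(iv.chrom, []).append((s, e))
        if iv.chrom not in lengths:
            lengths[iv.chrom] = e
        elif chrom_lengths is None and lengths[iv.chrom] < e:
            lengths[iv.chrom] = e
    values: dict[str, np.ndarray] = {}
    for chrom, length in lengths.items():
        diff = np.zeros(length + 1, dtype=np.float64)
        for s, e in spans.get(chrom, ()):
            e = min(e, length)
            if e > s:
                diff[s] += 1
                diff[e] -= 1
        values[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(fragments.sample_id, values, len(fragments))


def write_bedgraph(track: CoverageTrack, path_or_stream) -> None:
    """Write non-zero constant runs as bedGraph lines (chrom, start, end, value)."""
    if hasattr(path_or_stream, "write"):
        handle, close = path_or_stream, False
    else:
        handle, close = open(path_or_stream, "wt"), True
    try:
        handle.write(f"# total_fragments={track.total_fragments}\n")
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    handle.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
    finally:
        if close:
            handle.close()


def read_bedgraph(path_or_stream, sample_id: str = "sample") -> CoverageTrack:
    """Read a bedGraph file written by :func:`write_bedgraph` (zeros implicit)."""
    if hasattr(path_or_stream, "read"):
        handle, close = path_or_stream, False
    else:
        handle, close = open(path_or_stream, "rt"), True
    total = 0
    runs: dict[str, list[tuple[int, int, float]]] = {}
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser")):
                continue
            if line.startswith("#"):
                if "total_fragments=" in line:
                    total = int(line.split("total_fragments=")[1])
                continue
            chrom, s, e, v = line.split("\t")[:4]
            runs.setdefault(chrom, []).append((int(s), int(e), float(v)))
    finally:
        if close:
            handle.close()
    values = {}
    for chrom, rr in runs.items():
        length = max(e for _, e, _ in rr)
        arr = np.zeros(length, dtype=np.float64)
        for s, e, v in rr:
            arr[s:e] = v
        values[chrom] = arr
    return CoverageTrack(sample_id, values, total or 1)
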