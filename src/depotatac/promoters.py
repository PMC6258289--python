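"""Promoter accessibility: TSS+/-250 bp windows, RPKM ratio classification,
and TSS-centered average tag-density profiles.

Promoter windows are symmetric around the TSS in genomic coordinates (strand
does not change a symmetric window); tag-density profiles ARE strand-aware so
that "upstream" aligns across genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneAnnotation
from .coverage import CoverageTrack
from .intervals import PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "promoter_windows",
    "promoter_rpkm",
    "classify_promoters",
    "tss_tag_histogram",
]


def promoter_windows(genes: GeneAnnotation, half_width: int = 250) -> pd.DataFrame:
    """Per-gene window [TSS - half_width, TSS + half_width), clipped at 0.

    Returns a frame indexed by gene_id with chrom, win_start, win_end.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    df = genes.df
    start = df["tss"] - half_width
    clipped = start < 0
    if clipped.any():
        logger.info("%d promoter windows clipped at chromosome start", int(clipped.sum()))
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"],
            "win_start": start.clip(lower=0),
            "win_end": df["tss"] + half_width,
        }
    )
    return out.set_index("gene_id", drop=False)


def promoter_rpkm(
    fragments: PeakSet,
    windows: pd.DataFrame,
    extend_to: int = 150,
    anchor: str = "five_prime",
) -> pd.Series:
    """RPKM of (extended) fragments per promoter window.

    RPKM(gene) = n_fragments_overlapping_window /
    (window length in kb * total fragments in millions). A fragment counts
    when its extended interval overlaps the window by >=1 bp.
    """
    total = len(fragments)
    if total < 1:
        raise ValueError("fragment set is empty; RPKM undefined")
    trees: dict[str, IntervalTree] = {}
    for _, row in windows.iterrows():
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            int(row["win_start"]), int(row["win_end"]), row["gene_id"]
        )
    counts = dict.fromkeys(windows["gene_id"], 0)
    for iv in fragments:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        if anchor == "center":
            s = iv.midpoint - extend_to // 2
        elif iv.strand == "-":
            s = iv.end - extend_to
        else:
            s = iv.start
        e = s + extend_to
        s = max(s, 0)
        for hit in tree.overlap(s, e):
            counts[hit.data] += 1
    lengths_kb = (windows["win_end"] - windows["win_start"]) / 1000.0
    vals = pd.Series(counts, name="rpkm").reindex(windows["gene_id"])
    return vals / (lengths_kb.to_numpy() * (total / 1e6))


def classify_promoters(
    rpkm_a: pd.Series,
    rpkm_gf: pd.Series,
    cutoff: float = 1.5,
    pseudo: float = 0.05,
) -> pd.DataFrame:
    """Classify promoters by the A:GF accessibility ratio.

    ratio = (rpkm_A + pseudo) / (rpkm_GF + pseudo);
    'more-open-A' iff ratio >= cutoff, 'more-open-GF' iff ratio <= 1/cutoff,
    else 'no-difference'. Classes partition the genes and swap exactly under
    an A<->GF relabeling.
    """
    if cutoff <= 1:
        raise ValueError("cutoff must be > 1")
    rpkm_a, rpkm_gf = rpkm_a.align(rpkm_gf, join="inner")
    ratio = (rpkm_a + pseudo) / (rpkm_gf + pseudo)
    cls = np.where(
        ratio >= cutoff,
        "more-open-A",
        np.where(ratio <= 1.0 / cutoff, "more-open-GF", "no-difference"),
    )
    return pd.DataFrame(
        {"rpkm_A": rpkm_a, "rpkm_GF": rpkm_gf, "ratio": ratio, "class": cls}
    )


def tss_tag_histogram(
    track: CoverageTrack,
    genes: GeneAnnotation,
    flank: int = 250,
    resolution: int = 1,
) -> pd.Series:
    """Average coverage profile around gene TSSs, offsets -flank..+flank.

    Strand-aware: for '-' strand genes the offset axis runs antisense, so
    negative offsets are always gene-upstream. Positions off the stored
    coverage vector contribute 0.
    """
    if len(genes) == 0:
        raise ValueError("need >=1 gene")
    offsets = np.arange(-flank, flank + 1, resolution)
    acc = np.zeros(offsets.size, dtype=np.float64)
    for _, g in genes.df.iterrows():
        arr = track.values.get(g["chrom"])
        prof = np.zeros(offsets.size, dtype=np.float64)
        if arr is not None:
            if g["strand"] == "+":
                pos = g["tss"] + offsets
            else:
                pos = g["tss"] - offsets
            ok = (pos >= 0) & (pos < arr.size)
            prof[ok] = arr[pos[ok]]
        acc += prof
    return pd.Series(acc / len(genes), index=offsets, name=track.sample_id)
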