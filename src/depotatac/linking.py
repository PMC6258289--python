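"""Neighbor-bounded region-to-gene linking and its depot-match summary.

A depot-specific open region is linked to a depot-specific (signature) gene
when the region's midpoint falls inside the gene's linking window: up to
+/- max_dist (default 100 kb) around the TSS, clipped on each side at the
nearest boundary of any other annotated gene's span. A region lying in a
gene's window whose depot matches the gene's expression direction is a
"matched" link; otherwise "mismatched".
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation
from ._utils import round_half_up_pct

logger = logging.getLogger(__name__)

__all__ = ["linking_window", "link_regions_to_genes", "summarize_links"]

_DIR_TO_CALL = {"A-up": "A-specific", "GF-up": "GF-specific"}


def linking_window(
    gene_id: str, genes: GeneAnnotation, max_dist: int = 100_000
) -> tuple[int, int]:
    """Half-open linking window ``[start, end)`` for one gene.

    Each side extends at most ``max_dist`` from the TSS and stops at the
    nearest span boundary of any OTHER gene on the chromosome; a neighbor
    whose span covers the TSS collapses that side to the TSS (the TSS base
    itself is always retained). The upstream edge is additionally clipped
    at 0.
    """
    g = genes.gene(gene_id)
    tss = int(g["tss"])
    lo = max(tss - max_dist, 0)
    hi = tss + max_dist
    others = genes.df[(genes.df["chrom"] == g["chrom"]) & (genes.df["gene_id"] != gene_id)]
    for _, o in others.iterrows():
        s, e = int(o["start"]), int(o["end"])  # span, half-open
        if e <= tss:  # entirely upstream (in genomic coordinates)
            lo = max(lo, e)
        elif s > tss:  # entirely downstream
            hi = min(hi, s)
        else:  # span covers the TSS: collapse both sides to the TSS base
            lo = max(lo, tss)
            hi = min(hi, tss + 1)
    return lo, max(hi, tss + 1)


def link_regions_to_genes(
    regions: pd.DataFrame,
    signature: pd.DataFrame,
    genes: GeneAnnotation,
    max_dist: int = 100_000,
    overlap_mode: str = "midpoint",
) -> pd.DataFrame:
    """All (depot-specific region, signature gene) links.

    ``regions`` is a differential table restricted or restrictable to
    specific calls; its ``region_id`` must encode coordinates as
    ``chrom:start-end``. ``overlap_mode='midpoint'`` requires the region
    midpoint inside the window; ``'any'`` requires >=1 bp interval overlap.
    Returns rows (region_id, region_call, gene_id, gene_direction, distance,
    match) where distance = |region midpoint - TSS|.
    """
    if overlap_mode not in ("midpoint", "any"):
        raise ValueError("overlap_mode must be 'midpoint' or 'any'")
    spec = regions[regions["call"].isin(["A-specific", "GF-specific"])]
    coords = spec["region_id"].map(_parse_region_id)
    rows = []
    n_missing = 0
    for gene_id in signature["gene_id"]:
        if gene_id not in genes:
            n_missing += 1
            continue
        direction = signature.loc[gene_id, "direction"]
        g = genes.gene(gene_id)
        tss = int(g["tss"])
        lo, hi = linking_window(gene_id, genes, max_dist)
        for (chrom, start, end), call, rid in zip(
            coords, spec["call"], spec["region_id"]
        ):
            if chrom != g["chrom"]:
                continue
            mid = (start + end) // 2
            if overlap_mode == "midpoint":
                inside = lo <= mid < hi
            else:
                inside = min(end, hi) - max(start, lo) >= 1
            if inside and abs(mid - tss) <= max_dist:
                rows.append(
                    {
                        "region_id": rid,
                        "region_call": call,
                        "gene_id": gene_id,
                        "gene_direction": direction,
                        "distance": abs(mid - tss),
                        "match": call == _DIR_TO_CALL[direction],
                    }
                )
    if n_missing:
        logger.warning("%d signature genes absent from annotation; skipped", n_missing)
    out = pd.DataFrame(
        rows,
        columns=["region_id", "region_call", "gene_id", "gene_direction", "distance", "match"],
    )
    out.attrs["n_signature_genes_missing"] = n_missing
    return out


_RID_RE = re.compile(r"^(.+):(\d+)-(\d+)$")


def _parse_region_id(rid: str) -> tuple[str, int, int]:
    m = _RID_RE.match(rid)
    if not m:
        raise ValueError(f"region_id {rid!r} is not 'chrom:start-end'")
    return m.group(1), int(m.group(2)), int(m.group(3))


def summarize_links(links: pd.DataFrame, signature: pd.DataFrame) -> pd.DataFrame:
    """Per gene-direction class, tallies of matched and mismatched linkage.

    For each class ('A-up', 'GF-up'): total signature genes; distinct genes
    with >=1 matched / mismatched linked region; matched / mismatched link
    rows (region-gene pairs) and distinct regions; percentages of genes,
    rounded half-up to integers.
    """
    recs = {}
    for direction in ("A-up", "GF-up"):
        genes_in_class = signature[signature["direction"] == direction]["gene_id"]
        n_total = len(genes_in_class)
        sub = links[links["gene_direction"] == direction]
        mask = sub["match"].astype(bool)
        matched = sub[mask]
        mismatched = sub[~mask]
        recs[direction] = {
            "n_genes_total": n_total,
            "n_genes_with_matched_region": matched["gene_id"].nunique(),
            "n_genes_with_mismatched_region": mismatched["gene_id"].nunique(),
            "n_matched_links": len(matched),
            "n_mismatched_links": len(mismatched),
            "n_matched_regions": matched["region_id"].nunique(),
            "n_mismatched_regions": mismatched["region_id"].nunique(),
            "pct_matched_genes": round_half_up_pct(
                matched["gene_id"].nunique(), n_total
            ),
            "pct_mismatched_genes": round_half_up_pct(
                mismatched["gene_id"].nunique(), n_total
            ),
        }
    return pd.DataFrame(recs).T.rename_axis("gene_direction").astype(int)
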