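"""Gene annotation: chromosome, strand, span, TSS and TTS per gene.

Internally 0-based half-open like everything else; GTF input (1-based,
inclusive) is converted on read. The TSS of a ``+`` gene is its span start,
of a ``-`` gene the last base of its span; the TTS is the opposite end, so
``tss < tts`` on ``+`` and ``tss > tts`` on ``-``.
"""

from __future__ import annotations

import re

import pandas as pd

__all__ = ["GeneAnnotation", "read_gene_table", "read_gtf_genes"]

_REQUIRED = ["gene_id", "gene_name", "chrom", "strand", "start", "end"]


class GeneAnnotation:
    """Table of genes with derived ``tss``/``tts`` columns.

    Backed by a :class:`pandas.DataFrame` with columns
    ``gene_id, gene_name, chrom, strand, start, end, tss, tts`` and indexed
    by ``gene_id`` (unique).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        df = df.copy()
        if df["gene_id"].duplicated().any():
            dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene_id values: {dups[:5]}")
        bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
        if len(bad):
            raise ValueError(f"invalid gene spans for: {bad['gene_id'].tolist()[:5]}")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("gene strand must be '+' or '-'")
        plus = df["strand"] == "+"
        df["tss"] = df["end"] - 1
        df.loc[plus, "tss"] = df.loc[plus, "start"]
        df["tts"] = df["start"]
        df.loc[plus, "tts"] = df.loc[plus, "end"] - 1
        self.df = df.set_index("gene_id", drop=False)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.df.index

    def gene(self, gene_id: str) -> pd.Series:
        return self.df.loc[gene_id]

    def subset(self, gene_ids) -> "GeneAnnotation":
        keep = [g for g in gene_ids if g in self.df.index]
        return GeneAnnotation(self.df.loc[keep].reset_index(drop=True))

    def spans(self) -> pd.DataFrame:
        """Gene spans as (chrom, span_start, span_end) half-open, strand-free."""
        out = self.df[["gene_id", "chrom"]].copy()
        out["span_start"] = self.df["start"]
        out["span_end"] = self.df["end"]
        return out

    def to_table(self, path) -> None:
        self.df[_REQUIRED].to_csv(path, sep="\t", index=False)


def read_gene_table(path_or_stream) -> GeneAnnotation:
    """Read the 6-column tabular gene format
    (gene_id, gene_name, chrom, strand, start, end; 0-based half-open)."""
    df = pd.read_csv(path_or_stream, sep="\t", dtype={"chrom": str})
    return GeneAnnotation(df)


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_genes(path_or_stream) -> GeneAnnotation:
    """Extract ``gene`` feature records from a GTF file.

    GTF coordinates are 1-based inclusive and converted to 0-based half-open.
    """
    if hasattr(path_or_stream, "read"):
        handle, close = path_or_stream, False
    else:
        handle, close = open(path_or_stream, "rt"), True
    rows = []
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"GTF line {lineno}: fewer than 9 fields")
            if fields[2] != "gene":
                continue
            attrs = dict(_ATTR_RE.findall(fields[8]))
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise ValueError(f"GTF line {lineno}: gene record without gene_id")
            rows.append(
                {
                    "gene_id": gene_id,
                    "gene_name": attrs.get("gene_name", gene_id),
                    "chrom": fields[0],
                    "strand": fields[6],
                    "start": int(fields[3]) - 1,
                    "end": int(fields[4]),
                }
            )
    finally:
        if close:
            handle.close()
    return GeneAnnotation(pd.DataFrame(rows, columns=_REQUIRED))
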