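"""End-to-end pipeline orchestration and the summary report.

``run_pipeline`` composes the stages — blacklist filtering, consensus
building, median summit-coverage normalization, region signal
quantification, depot-specific region calling, cross-subject signature
intersection, promoter classification and region-to-gene linking — from a
single config, writing every stage artifact before the next begins, and
returns a :class:`SummaryReport` whose percentages are all integer
round-half-up of counts that are themselves in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._utils import round_half_up_pct
from .annotation import GeneAnnotation, read_gene_table
from .consensus import build_consensus, normalize_track, summit_coverage
from .coverage import coverage_from_fragments, write_bedgraph
from .differential import annotate_genomic_context, build_signal_matrix, test_differential
from .expression import intersect_signatures, read_de_table, signature_counts
from .intervals import (
    GenomicInterval,
    PeakSet,
    merge_intervals,
    overlap_pairs,
    parse_bed,
    subtract_blacklist,
    write_bed,
)
from .linking import link_regions_to_genes, summarize_links
from .promoters import classify_promoters, promoter_rpkm, promoter_windows, tss_tag_histogram

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SharedPeakStats", "SummaryReport", "shared_peak_stats", "run_pipeline"]


@dataclass
class SharedPeakStats:
    """Between-depot peak sharing, counted asymmetrically from each side."""

    n_A: int
    n_GF: int
    n_shared_of_A: int
    n_shared_of_GF: int
    pct_shared_of_A: int
    pct_shared_of_GF: int


def shared_peak_stats(peaks_a: PeakSet, peaks_gf: PeakSet) -> SharedPeakStats:
    """Count peaks common to both depots.

    A peak is "shared" when it overlaps (>=1 bp) at least one peak of the
    other depot; the count is anchored on each depot in turn and the
    percentages are round-half-up integers of the anchored counts.
    """
    if len(peaks_a) == 0 or len(peaks_gf) == 0:
        raise ValueError("both depot peak sets must be non-empty")
    shared_a = len({i for i, _ in overlap_pairs(peaks_a, peaks_gf)})
    shared_gf = len({j for _, j in overlap_pairs(peaks_a, peaks_gf)})
    return SharedPeakStats(
        len(peaks_a),
        len(peaks_gf),
        shared_a,
        shared_gf,
        round_half_up_pct(shared_a, len(peaks_a)),
        round_half_up_pct(shared_gf, len(peaks_gf)),
    )


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run. All thresholds default to the
    published analysis values, so a bare config runs the canonical pipeline."""

    sample_sheet: str
    gene_table: str
    expression_tables: dict[str, str]
    out_dir: str
    blacklist: str | None = None
    min_samples: int = 2
    alpha_region: float = 0.005
    alpha_gene: float = 0.05
    promoter_half_width: int = 250
    ratio_cutoff: float = 1.5
    max_link_dist: int = 100_000
    extend_to: int = 150
    summit_bin: int = 50
    pseudocount: float = 0.1
    rpkm_pseudo: float = 0.05
    histogram_flank: int = 250
    seed: int = 0
    write_tracks: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    @classmethod
    def for_dataset_dir(cls, data_dir, out_dir, **overrides) -> "PipelineConfig":
        """Config pointing at a directory written by ``write_dataset``."""
        d = Path(data_dir)
        with open(d / "manifest.yaml") as fh:
            manifest = yaml.safe_load(fh)
        expr = {s: str(d / p) for s, p in manifest["expression"].items()}
        return cls(
            sample_sheet=str(d / manifest["sample_sheet"]),
            gene_table=str(d / manifest["genes"]),
            expression_tables=expr,
            out_dir=str(out_dir),
            **overrides,
        )


@dataclass
class SummaryReport:
    """The headline numbers of one pipeline run, plus provenance."""

    n_peaks_A: int = 0
    n_peaks_GF: int = 0
    n_shared_of_A: int = 0
    n_shared_of_GF: int = 0
    pct_shared_of_A: int = 0
    pct_shared_of_GF: int = 0
    n_consensus_regions: int = 0
    n_A_specific_regions: int = 0
    n_GF_specific_regions: int = 0
    specific_region_ratio: float = 0.0
    n_signature_genes_A: int = 0
    n_signature_genes_GF: int = 0
    n_signature_genes_total: int = 0
    per_subject_de_counts: dict = field(default_factory=dict)
    promoter_classes: dict = field(default_factory=dict)
    genomic_context: dict = field(default_factory=dict)
    link_summary: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [
            "Depot-specific accessibility / expression integration report",
            "=" * 60,
            f"Peaks: A={self.n_peaks_A}  GF={self.n_peaks_GF}  "
            f"shared: {self.n_shared_of_A} ({self.pct_shared_of_A}% of A), "
            f"{self.n_shared_of_GF} ({self.pct_shared_of_GF}% of GF)",
            f"Consensus regions (>=2 samples): {self.n_consensus_regions}",
            f"Depot-specific regions: A={self.n_A_specific_regions} "
            f"GF={self.n_GF_specific_regions} "
            f"(A:GF ratio {self.specific_region_ratio:.2f})",
            f"Signature genes: A-up={self.n_signature_genes_A} "
            f"GF-up={self.n_signature_genes_GF} total={self.n_signature_genes_total}",
            f"Per-subject DE counts (p <= alpha): {self.per_subject_de_counts}",
            f"Promoter classes: {self.promoter_classes}",
            f"Genomic context of specific regions: {self.genomic_context}",
            "Link summary:",
        ]
        for direction, rec in self.link_summary.items():
            lines.append(f"  {direction}: {rec}")
        for note in self.notes:
            lines.append(f"NOTE: {note}")
        return "\n".join(lines) + "\n"


def _jsonable(obj):
    try:
        return int(obj)
    except (TypeError, ValueError):
        return str(obj)


def _file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Execute every stage and write all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet_path = Path(config.sample_sheet)
    sheet = pd.read_csv(sheet_path, sep="\t")
    for col in ("sample", "depot", "subject", "replicate", "peaks", "fragments"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    base = sheet_path.parent

    def _resolve(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    blacklist = (
        parse_bed(config.blacklist, sample_id="blacklist")
        if config.blacklist
        else None
    )

    # stage 1: per-sample peak calls (blacklist-filtered)
    peak_sets: dict[str, PeakSet] = {}
    for _, srow in sheet.iterrows():
        ps = parse_bed(_resolve(srow["peaks"]), srow["sample"], srow["depot"])
        n_in = len(ps)
        if blacklist is not None:
            ps = subtract_blacklist(ps, blacklist)
            logger.info("stage=blacklist sample=%s in=%d out=%d", srow["sample"], n_in, len(ps))
        peak_sets[srow["sample"]] = ps

    # stage 2: per-depot union peak sets and sharing stats
    union = {}
    for depot in ("A", "GF"):
        ivs = [
            iv
            for _, srow in sheet.iterrows()
            if srow["depot"] == depot
            for iv in peak_sets[srow["sample"]]
        ]
        union[depot] = PeakSet(f"union_{depot}", depot, merge_intervals(ivs))
        write_bed(union[depot], out / f"union_peaks_{depot}.bed")
    sharing = shared_peak_stats(union["A"], union["GF"])

    # stage 3: consensus
    consensus = build_consensus(list(peak_sets.values()), config.min_samples)
    cons_ps = consensus.to_peakset()
    write_bed(cons_ps, out / "consensus.bed")
    logger.info("stage=consensus n=%d", len(consensus))

    # stage 4: expression signature (independent of coverage)
    tables = {
        subj: read_de_table(path, subj)
        for subj, path in config.expression_tables.items()
    }
    de_counts = {s: int((t["p_value"] <= config.alpha_gene).sum()) for s, t in tables.items()}
    signature = intersect_signatures(tables, config.alpha_gene)
    signature.to_csv(out / "signature.tsv", sep="\t", index=False)
    n_a_up, n_gf_up, n_sig = signature_counts(signature)
    logger.info("stage=signature A-up=%d GF-up=%d", n_a_up, n_gf_up)

    genes = read_gene_table(config.gene_table)
    sig_genes = genes.subset([g for g in signature["gene_id"] if g in genes])

    # stage 5: per-sample coverage -> normalization -> signal columns,
    # processed sequentially so only one dense track is held at a time
    signal_cols: dict[str, pd.Series] = {}
    hist_acc: dict[str, pd.Series] = {}
    hist_n: dict[str, int] = {"A": 0, "GF": 0}
    depot_fragments: dict[str, list] = {"A": [], "GF": []}
    depot_frag_sets: dict[str, PeakSet] = {}
    for _, srow in sheet.iterrows():
        sample = srow["sample"]
        frags = parse_bed(_resolve(srow["fragments"]), sample, srow["depot"])
        depot_fragments[srow["depot"]].extend(frags.intervals)
        track = coverage_from_fragments(frags, config.extend_to)
        sv = summit_coverage(consensus, track, config.summit_bin)
        norm = normalize_track(track, sv)
        if config.write_tracks:
            write_bedgraph(norm, out / f"normalized_{sample}.bedgraph")
        mat1 = build_signal_matrix(consensus, {sample: norm})
        signal_cols[sample] = mat1[sample]
        if len(sig_genes):
            prof = tss_tag_histogram(norm, sig_genes, config.histogram_flank)
            depot = srow["depot"]
            hist_acc[depot] = prof if depot not in hist_acc else hist_acc[depot] + prof
            hist_n[depot] += 1
        del track, norm
    matrix = pd.DataFrame(signal_cols)
    matrix.to_csv(out / "signal_matrix.tsv", sep="\t")
    if hist_acc:
        hist = pd.DataFrame(
            {d: acc / hist_n[d] for d, acc in hist_acc.items()}
        ).rename_axis("offset")
        hist.to_csv(out / "tss_histogram.tsv", sep="\t")

    # stage 6: depot-specific region calling
    diff = test_differential(matrix, sheet, config.alpha_region, config.pseudocount)
    diff.to_csv(out / "differential.tsv", sep="\t", index=False)
    for call, fname in (("A-specific", "regions_A_specific.bed"), ("GF-specific", "regions_GF_specific.bed")):
        sub = diff[diff["call"] == call]
        ivs = []
        for rid in sub["region_id"]:
            chrom, span = rid.rsplit(":", 1)
            s, e = span.split("-")
            ivs.append((chrom, int(s), int(e)))
        with open(out / fname, "wt") as fh:
            for chrom, s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\n")
    n_a_spec = int((diff["call"] == "A-specific").sum())
    n_gf_spec = int((diff["call"] == "GF-specific").sum())
    ratio = n_a_spec / n_gf_spec if n_gf_spec else float("inf")

    # genomic context of the specific regions
    context: dict[str, dict[str, int]] = {}
    for call in ("A-specific", "GF-specific"):
        sub = diff[diff["call"] == call]
        ivs = []
        for rid in sub["region_id"]:
            chrom, span = rid.rsplit(":", 1)
            s, e = span.split("-")
            ivs.append(GenomicInterval(chrom, int(s), int(e)))
        cats = annotate_genomic_context(PeakSet("ctx", "NA", ivs), genes)
        tally: dict[str, int] = {}
        for c in cats:
            tally[c] = tally.get(c, 0) + 1
        context[call] = tally

    # stage 7: promoter classification of signature genes
    promoter_classes: dict[str, dict] = {}
    if len(sig_genes):
        for depot in ("A", "GF"):
            depot_frag_sets[depot] = PeakSet(
                f"pooled_{depot}", depot, depot_fragments[depot]
            )
        windows = promoter_windows(sig_genes, config.promoter_half_width)
        rpkm_a = promoter_rpkm(depot_frag_sets["A"], windows, config.extend_to)
        rpkm_gf = promoter_rpkm(depot_frag_sets["GF"], windows, config.extend_to)
        classes = classify_promoters(rpkm_a, rpkm_gf, config.ratio_cutoff, config.rpkm_pseudo)
        classes = classes.join(signature["direction"])
        classes.to_csv(out / "promoter_classes.tsv", sep="\t")
        for direction in ("A-up", "GF-up"):
            sub = classes[classes["direction"] == direction]
            n_dir = len(sub)
            rec = {"n_genes": n_dir}
            for cls in ("more-open-A", "more-open-GF", "no-difference"):
                n_cls = int((sub["class"] == cls).sum())
                rec[cls] = n_cls
                rec[f"pct_{cls}"] = round_half_up_pct(n_cls, n_dir)
            promoter_classes[direction] = rec

    # stage 8: region-to-gene linking
    links = link_regions_to_genes(diff, signature, genes, config.max_link_dist)
    links.to_csv(out / "links.tsv", sep="\t", index=False)
    summary = summarize_links(links, signature)
    summary.to_csv(out / "link_summary.tsv", sep="\t")

    notes = []
    for direction, rec in summary.iterrows():
        exact = (
            100.0 * rec["n_genes_with_matched_region"] / rec["n_genes_total"]
            if rec["n_genes_total"]
            else 0.0
        )
        if abs(exact - int(exact)) >= 0.5:
            notes.append(
                f"{direction}: matched-gene percentage {exact:.1f} rounds half-up "
                f"to {rec['pct_matched_genes']} (truncation would differ)"
            )

    report = SummaryReport(
        n_peaks_A=sharing.n_A,
        n_peaks_GF=sharing.n_GF,
        n_shared_of_A=sharing.n_shared_of_A,
        n_shared_of_GF=sharing.n_shared_of_GF,
        pct_shared_of_A=sharing.pct_shared_of_A,
        pct_shared_of_GF=sharing.pct_shared_of_GF,
        n_consensus_regions=len(consensus),
        n_A_specific_regions=n_a_spec,
        n_GF_specific_regions=n_gf_spec,
        specific_region_ratio=ratio,
        n_signature_genes_A=n_a_up,
        n_signature_genes_GF=n_gf_up,
        n_signature_genes_total=n_sig,
        per_subject_de_counts=de_counts,
        promoter_classes=promoter_classes,
        genomic_context=context,
        link_summary={d: {k: int(v) for k, v in rec.items()} for d, rec in summary.iterrows()},
        notes=notes,
        provenance={
            "version": __version__,
            "parameters": {
                "min_samples": config.min_samples,
                "alpha_region": config.alpha_region,
                "alpha_gene": config.alpha_gene,
                "promoter_half_width": config.promoter_half_width,
                "ratio_cutoff": config.ratio_cutoff,
                "max_link_dist": config.max_link_dist,
                "extend_to": config.extend_to,
                "seed": config.seed,
            },
            "input_hashes": {
                "sample_sheet": _file_digest(sheet_path),
                "gene_table": _file_digest(config.gene_table),
            },
        },
    )
    report.to_json(out / "report.json")
    (out / "report.txt").write_text(report.to_text())
    return report
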