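"""Synthetic depot-structured ATAC + expression datasets with known truth.

The generator emulates the study design the pipeline targets: two depots
(A = abdominal, GF = gluteofemoral) x two subjects x two technical
replicates of accessibility data, a large shared peak fraction, a strongly
asymmetric depot-specific fraction (many more A-specific than GF-specific
regions), and per-subject differential-expression tables whose significant
gene sets only partially overlap.

Count model: fragments per peak per sample are negative-binomial around a
per-peak baseline (log-normal across peaks); depot-specific peaks are
elevated by 2^specific_log2fc in their matching depot only; a per-(subject,
peak) log-normal shift shared by the subject's samples mimics the large
between-subject differences seen in real donors; background fragments fall
as a Poisson process along each chromosome. Per-sample peak *calls* are
re-derived from the sampled counts via a detection threshold (with +/-20 bp
edge jitter), so consensus building has genuine work to do.

Expression model: observed per-subject log2 fold change = planted effect +
Gaussian noise; the p-value is the two-sided normal tail of
observed / noise_sd, giving the cross-subject intersection rule both true
and false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from intervaltree import IntervalTree

from .annotation import GeneAnnotation
from .coverage import coverage_from_fragments, write_bedgraph
from .intervals import GenomicInterval, PeakSet, write_bed
from .linking import linking_window

__all__ = ["SimulationConfig", "GroundTruth", "SimulatedDataset", "simulate_dataset", "write_dataset"]


class ConfigurationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the scaled-down study
    conditions every test runs under."""

    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 80
    n_shared_peaks: int = 200
    n_specific_peaks_A: int = 40
    n_specific_peaks_GF: int = 8
    peak_width: int = 400
    n_subjects: int = 2
    n_replicates_per_subject: int = 2
    baseline_fragments_per_peak: float = 100.0
    specific_log2fc: float = 2.5
    dispersion: float = 0.05
    background_fragment_rate: float = 0.05  # fragments per kb outside peaks
    n_signature_genes_A: int = 14
    n_signature_genes_GF: int = 10
    expression_log2fc: float = 2.0
    expression_noise_sd: float = 0.5
    subject_shift_sd: float = 0.25  # log2 units
    peak_baseline_log2_sd: float = 1.0
    detection_threshold: int = 40  # fragments needed for a per-sample peak call
    fragment_length: int = 50  # raw (pre-extension) fragment size
    link_max_dist: int = 100_000
    # fraction of signature genes deliberately given a nearby specific peak
    plant_matched_frac_A: float = 0.3
    plant_matched_frac_GF: float = 0.1
    plant_mismatched_frac_GF: float = 0.3
    # fraction of signature genes given a depot-matched specific peak right
    # on the TSS (promoter accessibility follows expression)
    promoter_peak_frac_A: float = 0.5
    promoter_peak_frac_GF: float = 0.15
    # per-subject counts of additional subject-private DE genes, making the
    # per-subject significant sets overlap only partially
    subject_private_de: tuple = (20, 5)
    min_gene_length: int = 2_000
    max_gene_length: int = 10_000

    def __post_init__(self) -> None:
        for name in (
            "n_chroms", "chrom_length", "n_genes", "n_shared_peaks",
            "n_specific_peaks_A", "n_specific_peaks_GF", "peak_width",
            "n_subjects", "n_replicates_per_subject",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_subjects < 1 or self.n_replicates_per_subject < 1:
            raise ConfigurationError("need >=1 subject and replicate")
        if self.n_signature_genes_A + self.n_signature_genes_GF > self.n_genes:
            raise ConfigurationError("more signature genes than genes")
        footprint = (
            self.n_peaks_total * self.peak_width
            + self.n_genes * self.max_gene_length
        )
        if footprint > 0.5 * self.n_chroms * self.chrom_length:
            raise ConfigurationError(
                f"element footprint {footprint} bp exceeds half the genome "
                f"({self.n_chroms * self.chrom_length} bp); peaks/genes cannot "
                "be placed without forced overlap"
            )

    @property
    def n_peaks_total(self) -> int:
        return self.n_shared_peaks + self.n_specific_peaks_A + self.n_specific_peaks_GF

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{depot}_s{subj}_r{rep}"
            for depot in ("A", "GF")
            for subj in range(1, self.n_subjects + 1)
            for rep in range(1, self.n_replicates_per_subject + 1)
        ]

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for depot in ("A", "GF"):
            for subj in range(1, self.n_subjects + 1):
                for rep in range(1, self.n_replicates_per_subject + 1):
                    rows.append(
                        {
                            "sample": f"{depot}_s{subj}_r{rep}",
                            "depot": depot,
                            "subject": subj,
                            "replicate": rep,
                        }
                    )
        return pd.DataFrame(rows)

    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class GroundTruth:
    """Planted labels: per peak {shared, A, GF}; per gene {none, A, GF};
    plus the noise-free (gene, peak) links implied by the final geometry."""

    peaks: pd.DataFrame  # peak_id, chrom, start, end, label
    genes: pd.DataFrame  # gene_id, label
    links: pd.DataFrame  # gene_id, peak_id, gene_label, peak_label, distance, match


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: GeneAnnotation
    peak_calls: dict[str, PeakSet]
    fragments: dict[str, PeakSet]
    expression: dict[str, pd.DataFrame]
    truth: GroundTruth
    counts: pd.DataFrame = field(repr=False, default=None)  # peaks x samples


def _place(
    rng: np.random.Generator,
    width: int,
    chroms: list[str],
    chrom_length: int,
    occupied: dict[str, IntervalTree],
    near: tuple[str, int, int, int] | None = None,
) -> tuple[str, int]:
    """Place one element of ``width`` bp avoiding ``occupied``.

    ``near=(chrom, anchor, lo_off, hi_off)`` biases placement to within an
    offset band of an anchor position (either side); falls back to uniform
    placement when the neighborhood is full.
    """
    for attempt in range(400):
        if near is not None and attempt < 200:
            chrom, anchor, lo_off, hi_off = near
            off = int(rng.integers(lo_off, hi_off))
            if rng.random() < 0.5:
                off = -off
            start = anchor + off - width // 2
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, chrom_length - width))
        if start < 0 or start + width > chrom_length:
            continue
        if not occupied[chrom].overlap(start, start + width):
            occupied[chrom].addi(start, start + width)
            return chrom, start
    raise ConfigurationError("could not place element; genome too crowded")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete dataset. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_lengths())
    occupied = {c: IntervalTree() for c in chroms}

    # --- genes ---------------------------------------------------------
    gene_rows = []
    for i in range(config.n_genes):
        length = int(rng.integers(config.min_gene_length, config.max_gene_length + 1))
        chrom, start = _place(rng, length, chroms, config.chrom_length, occupied)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append(
            {
                "gene_id": f"G{i:04d}",
                "gene_name": f"GENE{i:04d}",
                "chrom": chrom,
                "strand": strand,
                "start": start,
                "end": start + length,
            }
        )
    genes = GeneAnnotation(pd.DataFrame(gene_rows))
    gene_ids = list(genes.df["gene_id"])
    sig_pick = rng.permutation(config.n_genes)
    sig_a = [gene_ids[i] for i in sig_pick[: config.n_signature_genes_A]]
    sig_gf = [
        gene_ids[i]
        for i in sig_pick[
            config.n_signature_genes_A
            : config.n_signature_genes_A + config.n_signature_genes_GF
        ]
    ]
    gene_label = {g: "none" for g in gene_ids}
    gene_label.update({g: "A" for g in sig_a})
    gene_label.update({g: "GF" for g in sig_gf})

    # --- peaks: deliberate placements near signature genes first -------
    peak_rows: list[dict] = []

    def add_peak(label: str, near_gene: str | None = None, at_tss: str | None = None) -> None:
        if at_tss is not None:
            # promoter peak centered on the TSS; may overlap the gene span
            g = genes.gene(at_tss)
            chrom = g["chrom"]
            start = max(0, int(g["tss"]) - config.peak_width // 2)
            occupied[chrom].addi(start, start + config.peak_width)
        else:
            near = None
            if near_gene is not None:
                g = genes.gene(near_gene)
                near = (g["chrom"], int(g["tss"]), 5_000, min(80_000, config.link_max_dist))
            chrom, start = _place(
                rng, config.peak_width, chroms, config.chrom_length, occupied, near
            )
        peak_rows.append(
            {
                "peak_id": f"P{len(peak_rows):04d}",
                "chrom": chrom,
                "start": start,
                "end": start + config.peak_width,
                "label": label,
            }
        )

    n_planted_a = 0
    for g in sig_a:
        if rng.random() < config.promoter_peak_frac_A and n_planted_a < config.n_specific_peaks_A:
            add_peak("A", at_tss=g)
            n_planted_a += 1
        elif rng.random() < config.plant_matched_frac_A and n_planted_a < config.n_specific_peaks_A:
            add_peak("A", near_gene=g)
            n_planted_a += 1
    n_planted_gf = 0
    for g in sig_gf:
        if rng.random() < config.promoter_peak_frac_GF and n_planted_gf < config.n_specific_peaks_GF:
            add_peak("GF", at_tss=g)
            n_planted_gf += 1
        elif rng.random() < config.plant_matched_frac_GF and n_planted_gf < config.n_specific_peaks_GF:
            add_peak("GF", near_gene=g)
            n_planted_gf += 1
        if rng.random() < config.plant_mismatched_frac_GF and n_planted_a < config.n_specific_peaks_A:
            add_peak("A", near_gene=g)
            n_planted_a += 1
    for _ in range(config.n_specific_peaks_A - n_planted_a):
        add_peak("A")
    for _ in range(config.n_specific_peaks_GF - n_planted_gf):
        add_peak("GF")
    for _ in range(config.n_shared_peaks):
        add_peak("shared")
    truth_peaks = pd.DataFrame(
        peak_rows, columns=["peak_id", "chrom", "start", "end", "label"]
    )

    # --- per-sample fragment counts ------------------------------------
    n_peaks = len(truth_peaks)
    sheet = config.sample_sheet()
    base = config.baseline_fragments_per_peak * np.exp2(
        rng.normal(0.0, config.peak_baseline_log2_sd, size=n_peaks)
    )
    # per (subject, peak) shift shared by the subject's samples in both depots
    subj_shift = {
        s: rng.normal(0.0, config.subject_shift_sd, size=n_peaks)
        for s in range(1, config.n_subjects + 1)
    }
    labels = truth_peaks["label"].to_numpy()
    counts = {}
    for _, srow in sheet.iterrows():
        mean = base * np.exp2(subj_shift[srow["subject"]])
        boost = np.where(labels == srow["depot"], 2.0 ** config.specific_log2fc, 1.0)
        mean = mean * boost
        if config.dispersion > 1e-9:
            r = 1.0 / config.dispersion
            counts[srow["sample"]] = rng.negative_binomial(r, r / (r + mean))
        else:
            counts[srow["sample"]] = rng.poisson(mean)
    counts = pd.DataFrame(counts, index=truth_peaks["peak_id"])

    # --- fragments and peak calls per sample ----------------------------
    fragments: dict[str, PeakSet] = {}
    peak_calls: dict[str, PeakSet] = {}
    starts = truth_peaks["start"].to_numpy()
    ends = truth_peaks["end"].to_numpy()
    pchroms = truth_peaks["chrom"].to_numpy()
    frag_len = config.fragment_length
    for _, srow in sheet.iterrows():
        sample = srow["sample"]
        ivs: list[GenomicInterval] = []
        col = counts[sample].to_numpy()
        for i in range(n_peaks):
            n = int(col[i])
            if n == 0:
                continue
            lo, hi = starts[i], max(ends[i] - frag_len, starts[i] + 1)
            pos = rng.integers(lo, hi, size=n)
            chrom = pchroms[i]
            ivs.extend(GenomicInterval(chrom, int(p), int(p) + frag_len) for p in pos)
        # background fragments along each chromosome
        for chrom in chroms:
            n_bg = rng.poisson(
                config.background_fragment_rate * config.chrom_length / 1000.0
            )
            if n_bg:
                pos = rng.integers(0, config.chrom_length - frag_len, size=n_bg)
                ivs.extend(
                    GenomicInterval(chrom, int(p), int(p) + frag_len) for p in pos
                )
        fragments[sample] = PeakSet(sample, srow["depot"], ivs)
        called = np.flatnonzero(col >= config.detection_threshold)
        call_ivs = []
        for i in called:
            j1 = int(rng.integers(0, 21))
            j2 = int(rng.integers(0, 21))
            s = max(0, int(starts[i]) - j1)
            e = min(config.chrom_length, int(ends[i]) + j2)
            call_ivs.append(GenomicInterval(pchroms[i], s, e))
        peak_calls[sample] = PeakSet(sample, srow["depot"], call_ivs)

    # --- expression tables ----------------------------------------------
    true_lfc = np.zeros(config.n_genes)
    for k, g in enumerate(gene_ids):
        if gene_label[g] == "A":
            true_lfc[k] = config.expression_log2fc
        elif gene_label[g] == "GF":
            true_lfc[k] = -config.expression_log2fc
    null_idx = np.array(
        [k for k, g in enumerate(gene_ids) if gene_label[g] == "none"]
    )
    expression: dict[str, pd.DataFrame] = {}
    for subj in range(1, config.n_subjects + 1):
        subj_lfc = true_lfc.copy()
        # subject-private DE genes: significant in this subject only, so the
        # per-subject significant sets overlap only partially
        n_priv = (
            config.subject_private_de[subj - 1]
            if subj - 1 < len(config.subject_private_de)
            else 0
        )
        n_priv = min(n_priv, null_idx.size)
        if n_priv:
            priv = rng.choice(null_idx, size=n_priv, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_priv)
            subj_lfc[priv] += signs * config.expression_log2fc
        obs = subj_lfc + rng.normal(0.0, config.expression_noise_sd, config.n_genes)
        z = obs / config.expression_noise_sd
        p = 2.0 * stats.norm.sf(np.abs(z))
        expression[f"subject{subj}"] = pd.DataFrame(
            {"gene_id": gene_ids, "log2fc": obs, "p_value": p}
        )

    # --- noise-free links implied by the final geometry ------------------
    link_rows = []
    spec_peaks = truth_peaks[truth_peaks["label"].isin(["A", "GF"])]
    for g in sig_a + sig_gf:
        glab = gene_label[g]
        grow = genes.gene(g)
        lo, hi = linking_window(g, genes, config.link_max_dist)
        for _, prow in spec_peaks.iterrows():
            if prow["chrom"] != grow["chrom"]:
                continue
            mid = (prow["start"] + prow["end"]) // 2
            dist = abs(mid - int(grow["tss"]))
            if lo <= mid < hi and dist <= config.link_max_dist:
                link_rows.append(
                    {
                        "gene_id": g,
                        "peak_id": prow["peak_id"],
                        "gene_label": glab,
                        "peak_label": prow["label"],
                        "distance": dist,
                        "match": glab == prow["label"],
                    }
                )
    truth_links = pd.DataFrame(
        link_rows,
        columns=["gene_id", "peak_id", "gene_label", "peak_label", "distance", "match"],
    )
    truth = GroundTruth(
        truth_peaks,
        pd.DataFrame({"gene_id": gene_ids, "label": [gene_label[g] for g in gene_ids]}),
        truth_links,
    )
    return SimulatedDataset(config, genes, peak_calls, fragments, expression, truth, counts)


def write_dataset(dataset: SimulatedDataset, directory) -> dict:
    """Write every artifact as plain text and return the manifest.

    Per sample: peak-call BED, fragment BED, raw-coverage bedGraph. Plus the
    gene table, per-subject expression TSVs, sample sheet, a truth manifest
    (one row per peak and per gene) and the truth link table. The manifest
    (also saved as manifest.yaml) is sufficient to rerun every stage from
    files alone.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    manifest: dict = {
        "config": asdict(cfg),
        "samples": {},
        "n_peaks_total": len(dataset.truth.peaks),
        "n_genes": len(dataset.genes),
    }
    sheet = cfg.sample_sheet()
    peaks_paths, frag_paths = [], []
    for _, srow in sheet.iterrows():
        sample = srow["sample"]
        pk = d / f"peaks_{sample}.bed"
        fr = d / f"fragments_{sample}.bed"
        bg = d / f"coverage_{sample}.bedgraph"
        write_bed(dataset.peak_calls[sample], pk)
        write_bed(dataset.fragments[sample], fr)
        write_bedgraph(
            coverage_from_fragments(
                dataset.fragments[sample], chrom_lengths=cfg.chrom_lengths()
            ),
            bg,
        )
        manifest["samples"][sample] = {
            "depot": srow["depot"],
            "subject": int(srow["subject"]),
            "replicate": int(srow["replicate"]),
            "peaks": pk.name,
            "fragments": fr.name,
            "coverage": bg.name,
        }
        peaks_paths.append(pk.name)
        frag_paths.append(fr.name)
    dataset.genes.to_table(d / "genes.tsv")
    manifest["genes"] = "genes.tsv"
    manifest["expression"] = {}
    for subj, table in dataset.expression.items():
        path = d / f"expression_{subj}.tsv"
        table.to_csv(path, sep="\t", index=False)
        manifest["expression"][subj] = path.name
    sheet2 = sheet.copy()
    sheet2["peaks"] = peaks_paths
    sheet2["fragments"] = frag_paths
    sheet2.to_csv(d / "sample_sheet.tsv", sep="\t", index=False)
    manifest["sample_sheet"] = "sample_sheet.tsv"
    # truth manifest: one row per peak and per gene
    peaks_t = dataset.truth.peaks.copy()
    peaks_t.insert(0, "element_type", "peak")
    peaks_t = peaks_t.rename(columns={"peak_id": "element_id"})
    genes_t = dataset.truth.genes.copy()
    genes_t.insert(0, "element_type", "gene")
    genes_t = genes_t.rename(columns={"gene_id": "element_id"})
    truth = pd.concat([peaks_t, genes_t], ignore_index=True)
    truth.to_csv(d / "truth.tsv", sep="\t", index=False)
    dataset.truth.links.to_csv(d / "truth_links.tsv", sep="\t", index=False)
    manifest["truth"] = "truth.tsv"
    manifest["truth_links"] = "truth_links.tsv"
    with open(d / "manifest.yaml", "wt") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
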