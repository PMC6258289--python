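"""Neighbor-clipped linking windows (quadratic oracle), link tables and
summary tallies with round-half-up percentages."""

import numpy as np
import pandas as pd
import pytest

import depotatac as da


def genes_of(rows):
    return da.GeneAnnotation(
        pd.DataFrame(
            rows, columns=["gene_id", "gene_name", "chrom", "strand", "start", "end"]
        )
    )


def window_oracle(gene_id, genes, max_dist):
    """Direct restatement of the clipping rule over every other gene."""
    g = genes.gene(gene_id)
    tss = int(g["tss"])
    lo, hi = max(tss - max_dist, 0), tss + max_dist
    for _, o in genes.df.iterrows():
        if o["gene_id"] == gene_id or o["chrom"] != g["chrom"]:
            continue
        s, e = int(o["start"]), int(o["end"])
        if e <= tss:
            lo = max(lo, e)
        elif s > tss:
            hi = min(hi, s)
        else:
            lo, hi = max(lo, tss), min(hi, tss + 1)
    return lo, max(hi, tss + 1)


class TestLinkingWindow:
    def test_isolated_gene(self):
        g = genes_of([("g1", "G1", "chr1", "+", 500_000, 520_000)])
        assert da.linking_window("g1", g) == (400_000, 600_000)

    def test_upstream_neighbor_clips(self):
        g = genes_of(
            [
                ("g1", "G1", "chr1", "+", 500_000, 520_000),
                ("g2", "G2", "chr1", "+", 430_000, 450_000),
            ]
        )
        assert da.linking_window("g1", g) == (450_000, 600_000)

    def test_neighbor_overlapping_tss_collapses(self):
        g = genes_of(
            [
                ("g1", "G1", "chr1", "+", 500_000, 520_000),
                ("g2", "G2", "chr1", "-", 490_000, 510_000),
            ]
        )
        lo, hi = da.linking_window("g1", g)
        assert (lo, hi) == (500_000, 500_001)

    def test_clip_at_zero(self):
        g = genes_of([("g1", "G1", "chr1", "+", 50_000, 60_000)])
        assert da.linking_window("g1", g) == (0, 150_000)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for i, s in enumerate(sorted(rng.integers(0, 2_000_000, size=30))):
            rows.append(
                (f"g{i}", f"G{i}", "chr1", "+" if rng.random() < 0.5 else "-",
                 int(s) * 1, int(s) + int(rng.integers(1000, 30_000)))
            )
        genes = genes_of(rows)
        for gid in genes.df["gene_id"]:
            assert da.linking_window(gid, genes) == window_oracle(gid, genes, 100_000)

    def test_no_other_gene_span_inside_window(self):
        rng = np.random.default_rng(4)
        rows = [
            (f"g{i}", f"G{i}", "chr1", "+", int(s), int(s) + 5000)
            for i, s in enumerate(sorted(rng.integers(0, 1_000_000, size=20)))
        ]
        genes = genes_of(rows)
        for gid in genes.df["gene_id"]:
            lo, hi = da.linking_window(gid, genes)
            tss = int(genes.gene(gid)["tss"])
            assert lo <= tss < hi
            for _, o in genes.df.iterrows():
                if o["gene_id"] == gid:
                    continue
                # another gene's interior may not reach past its boundary
                inter = min(hi, o["end"]) - max(lo, o["start"])
                if inter > 0:
                    # only allowed when the neighbor overlaps the TSS itself
                    assert o["start"] <= tss < o["end"]


def diff_table(rows):
    return pd.DataFrame(rows, columns=["region_id", "call"])


def sig_table(rows):
    return (
        pd.DataFrame(rows, columns=["gene_id", "direction"])
        .set_index("gene_id", drop=False)
    )


class TestLinkRegions:
    def test_single_matched_link(self):
        genes = genes_of([("g1", "G1", "chr1", "+", 500_000, 520_000)])
        regions = diff_table([("chr1:479900-480100", "A-specific")])
        sig = sig_table([("g1", "A-up")])
        links = da.link_regions_to_genes(regions, sig, genes)
        assert len(links) == 1
        row = links.iloc[0]
        assert bool(row["match"]) and row["distance"] == 20_000

    def test_region_beyond_max_dist_excluded(self):
        genes = genes_of([("g1", "G1", "chr1", "+", 500_000, 520_000)])
        regions = diff_table([("chr1:349900-350100", "A-specific")])
        sig = sig_table([("g1", "A-up")])
        assert len(da.link_regions_to_genes(regions, sig, genes)) == 0

    def test_missing_gene_skipped_and_counted(self):
        genes = genes_of([("g1", "G1", "chr1", "+", 500_000, 520_000)])
        regions = diff_table([("chr1:479900-480100", "A-specific")])
        sig = sig_table([("g1", "A-up"), ("gX", "GF-up")])
        links = da.link_regions_to_genes(regions, sig, genes)
        assert links.attrs["n_signature_genes_missing"] == 1

    def test_matches_all_pairs_oracle(self, sim_dataset):
        ds = sim_dataset
        truth = ds.truth
        regions = diff_table(
            [
                (f"{r.chrom}:{r.start}-{r.end}",
                 "A-specific" if r.label == "A" else "GF-specific")
                for r in truth.peaks.itertuples()
                if r.label in ("A", "GF")
            ]
        )
        sig = sig_table(
            [
                (g.gene_id, "A-up" if g.label == "A" else "GF-up")
                for g in truth.genes.itertuples()
                if g.label != "none"
            ]
        )
        links = da.link_regions_to_genes(regions, sig, ds.genes)
        got = set(zip(links["region_id"], links["gene_id"]))
        expected = set()
        for gid in sig["gene_id"]:
            lo, hi = window_oracle(gid, ds.genes, 100_000)
            chrom = ds.genes.gene(gid)["chrom"]
            for _, r in regions.iterrows():
                c, span = r["region_id"].rsplit(":", 1)
                s, e = map(int, span.split("-"))
                mid = (s + e) // 2
                if c == chrom and lo <= mid < hi:
                    expected.add((r["region_id"], gid))
        assert got == expected
        # pipeline-level truth links agree on (gene, distance) structure
        assert (links["distance"] <= 100_000).all()

    def test_shrinking_max_dist_never_adds_rows(self):
        genes = genes_of([("g1", "G1", "chr1", "+", 500_000, 520_000)])
        rng = np.random.default_rng(0)
        regions = diff_table(
            [
                (f"chr1:{int(s)}-{int(s) + 200}", "A-specific")
                for s in rng.integers(300_000, 700_000, size=50)
            ]
        )
        sig = sig_table([("g1", "A-up")])
        wide = da.link_regions_to_genes(regions, sig, genes, max_dist=100_000)
        narrow = da.link_regions_to_genes(regions, sig, genes, max_dist=30_000)
        assert set(narrow["region_id"]) <= set(wide["region_id"])


class TestSummarizeLinks:
    def test_printed_scale_percentages(self):
        """74 matched of 126 A-up genes -> 59%; 25 mismatched of 90 GF-up
        genes -> 28% under round-half-up."""
        sig_rows = [(f"a{i}", "A-up") for i in range(126)] + [
            (f"g{i}", "GF-up") for i in range(90)
        ]
        sig = sig_table(sig_rows)
        links = []
        for i in range(74):  # matched A genes
            links.append((f"chr1:{i}00-{i}50", "A-specific", f"a{i}", "A-up", 100, True))
        for i in range(25):  # GF genes with A-specific (mismatched) regions
            links.append((f"chr1:9{i}00-9{i}50", "A-specific", f"g{i}", "GF-up", 100, False))
        ltab = pd.DataFrame(
            links,
            columns=["region_id", "region_call", "gene_id", "gene_direction", "distance", "match"],
        )
        out = da.summarize_links(ltab, sig)
        assert out.loc["A-up", "n_genes_with_matched_region"] == 74
        assert out.loc["A-up", "pct_matched_genes"] == 59
        assert out.loc["GF-up", "n_genes_with_mismatched_region"] == 25
        assert out.loc["GF-up", "pct_mismatched_genes"] == 28

    def test_empty_links(self):
        sig = sig_table([("g1", "A-up")])
        empty = pd.DataFrame(
            columns=["region_id", "region_call", "gene_id", "gene_direction", "distance", "match"]
        )
        out = da.summarize_links(empty, sig)
        assert out.loc["A-up", "n_matched_links"] == 0
        assert out.loc["A-up", "pct_matched_genes"] == 0

    def test_depot_swap_exchanges_classes(self, sim_dataset):
        truth = sim_dataset.truth
        regions = diff_table(
            [
                (f"{r.chrom}:{r.start}-{r.end}",
                 "A-specific" if r.label == "A" else "GF-specific")
                for r in truth.peaks.itertuples()
                if r.label in ("A", "GF")
            ]
        )
        sig = sig_table(
            [
                (g.gene_id, "A-up" if g.label == "A" else "GF-up")
                for g in truth.genes.itertuples()
                if g.label != "none"
            ]
        )
        fwd = da.summarize_links(
            da.link_regions_to_genes(regions, sig, sim_dataset.genes), sig
        )
        flip_call = {"A-specific": "GF-specific", "GF-specific": "A-specific"}
        flip_dir = {"A-up": "GF-up", "GF-up": "A-up"}
        regions2 = regions.assign(call=regions["call"].map(flip_call))
        sig2 = sig.assign(direction=sig["direction"].map(flip_dir))
        rev = da.summarize_links(
            da.link_regions_to_genes(regions2, sig2, sim_dataset.genes), sig2
        )
        for col in fwd.columns:
            assert fwd.loc["A-up", col] == rev.loc["GF-up", col]
            assert fwd.loc["GF-up", col] == rev.loc["A-up", col]
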