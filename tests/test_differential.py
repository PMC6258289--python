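"""Depot-specific region calling: degenerate cases, planted effects,
label-swap antisymmetry, null calibration, and context annotation oracle."""

import numpy as np
import pandas as pd
import pytest

import depotatac as da


def sheet_4v4():
    rows = []
    for depot in ("A", "GF"):
        for subj in (1, 2):
            for rep in (1, 2):
                rows.append(
                    {"sample": f"{depot}_s{subj}_r{rep}", "depot": depot,
                     "subject": subj, "replicate": rep}
                )
    return pd.DataFrame(rows)


def nb_matrix(rng, n_regions, mean_a, mean_gf, dispersion=0.05):
    r = 1.0 / dispersion
    cols = {}
    for s in sheet_4v4()["sample"]:
        mean = mean_a if s.startswith("A") else mean_gf
        cols[s] = rng.negative_binomial(r, r / (r + mean), size=n_regions).astype(float)
    return pd.DataFrame(cols, index=[f"chr1:{i * 1000}-{i * 1000 + 500}" for i in range(n_regions)])


class TestTestDifferential:
    def test_identical_samples_give_p_one_and_no_calls(self):
        m = pd.DataFrame(
            {s: np.full(5, 2.0) for s in sheet_4v4()["sample"]},
            index=[f"chr1:{i}-{i + 10}" for i in range(0, 50, 10)],
        )
        out = da.test_differential(m, sheet_4v4())
        assert (out["p_value"] == 1.0).all()
        assert (out["call"] == "shared").all()
        assert (out["log2fc"] == 0).all()

    def test_planted_effect_called_a_specific(self):
        rng = np.random.default_rng(0)
        m = nb_matrix(rng, 1, mean_a=800.0, mean_gf=100.0)
        out = da.test_differential(m, sheet_4v4())
        assert out.loc[0, "call"] == "A-specific"
        assert out.loc[0, "log2fc"] > 0

    def test_depot_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        m = nb_matrix(rng, 50, mean_a=300.0, mean_gf=100.0)
        sheet = sheet_4v4()
        out = da.test_differential(m, sheet)
        swapped_sheet = sheet.copy()
        swapped_sheet["depot"] = swapped_sheet["depot"].map({"A": "GF", "GF": "A"})
        out_sw = da.test_differential(m, swapped_sheet)
        a = out.set_index("region_id")
        b = out_sw.set_index("region_id").loc[a.index]
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert np.allclose(a["p_value"], b["p_value"])
        assert set(a[a["call"] == "A-specific"].index) == set(b[b["call"] == "GF-specific"].index)
        assert set(a[a["call"] == "GF-specific"].index) == set(b[b["call"] == "A-specific"].index)

    def test_tightening_alpha_never_adds_calls(self):
        rng = np.random.default_rng(2)
        m = nb_matrix(rng, 100, mean_a=200.0, mean_gf=100.0)
        loose = da.test_differential(m, sheet_4v4(), alpha=0.05)
        tight = da.test_differential(m, sheet_4v4(), alpha=0.005)
        spec = lambda t: set(t[t["call"] != "shared"]["region_id"])
        assert spec(tight) <= spec(loose)

    def test_calls_partition_regions(self):
        rng = np.random.default_rng(3)
        m = nb_matrix(rng, 80, mean_a=150.0, mean_gf=100.0)
        out = da.test_differential(m, sheet_4v4())
        assert set(out["call"]) <= {"A-specific", "GF-specific", "shared"}
        assert len(out) == 80

    def test_null_calibration_over_seeds(self):
        """Specific-call fraction under the null stays at or below 2x alpha
        (averaged over 20 seeds)."""
        alpha = 0.005
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = nb_matrix(rng, 500, mean_a=100.0, mean_gf=100.0)
            out = da.test_differential(m, sheet_4v4(), alpha=alpha)
            rates.append((out["call"] != "shared").mean())
        assert np.mean(rates) <= 2 * alpha

    def test_single_sample_depot_rejected(self):
        sheet = sheet_4v4().iloc[[0, 4, 5, 6]]  # one A sample only
        m = pd.DataFrame(
            {s: np.ones(3) for s in sheet["sample"]},
            index=[f"chr1:{i}-{i + 5}" for i in range(0, 15, 5)],
        )
        with pytest.raises(ValueError):
            da.test_differential(m, sheet)


class TestSignalMatrix:
    def test_constant_region_value(self):
        cons = da.ConsensusPeakSet(
            [da.GenomicInterval("chr1", 0, 100)], [2], [("a", "b")], 2
        )
        track = da.CoverageTrack("s1", {"chr1": np.full(200, 1.5)}, 10)
        m = da.build_signal_matrix(cons, {"s1": track})
        assert m.loc["chr1:0-100", "s1"] == pytest.approx(1.5)

    def test_empty_track_all_zero(self):
        cons = da.ConsensusPeakSet(
            [da.GenomicInterval("chr1", 0, 100)], [2], [("a", "b")], 2
        )
        m = da.build_signal_matrix(cons, {"s1": da.CoverageTrack("s1", {}, 0)})
        assert (m["s1"] == 0).all()

    def test_matches_brute_force_means(self, sim_dataset):
        cons = da.build_consensus(list(sim_dataset.peak_calls.values()), 2)
        frags = sim_dataset.fragments["GF_s2_r1"]
        track = da.coverage_from_fragments(frags, 150)
        m = da.build_signal_matrix(cons, {"GF_s2_r1": track})
        for i in (0, len(cons) // 2, len(cons) - 1):
            iv = cons.intervals[i]
            arr = track.values.get(iv.chrom)
            expected = 0.0
            if arr is not None:
                vals = [arr[p] if p < arr.size else 0.0 for p in range(iv.start, iv.end)]
                expected = float(np.mean(vals))
            assert m.iloc[i, 0] == pytest.approx(expected)


class TestGenomicContext:
    def test_promoter_and_intergenic_examples(self):
        genes = da.GeneAnnotation(
            pd.DataFrame(
                [
                    {"gene_id": "g1", "gene_name": "G1", "chrom": "chr1",
                     "strand": "+", "start": 10_000, "end": 20_000}
                ]
            )
        )
        near_tss = da.PeakSet("p", "NA", [da.GenomicInterval("chr1", 9700, 9900)])
        assert da.annotate_genomic_context(near_tss, genes) == ["promoter-TSS"]
        far = da.PeakSet("p", "NA", [da.GenomicInterval("chr1", 70_000, 70_200)])
        assert da.annotate_genomic_context(far, genes) == ["intergenic"]

    def test_matches_brute_force_classification(self):
        rng = np.random.default_rng(8)
        genes = da.GeneAnnotation(
            pd.DataFrame(
                [
                    {"gene_id": f"g{i}", "gene_name": f"G{i}", "chrom": "chr1",
                     "strand": "+" if i % 2 else "-",
                     "start": int(s), "end": int(s) + 5000}
                    for i, s in enumerate(range(10_000, 100_000, 12_000))
                ]
            )
        )
        peaks = da.PeakSet(
            "p", "NA",
            [
                da.GenomicInterval("chr1", int(s), int(s) + 200)
                for s in rng.integers(0, 110_000, size=100)
            ],
        )
        got = da.annotate_genomic_context(peaks, genes, 1000, 100)
        for iv, cat in zip(peaks, got):
            mid = iv.midpoint
            exp = "intergenic"
            in_prom = in_tts = in_body = False
            for _, g in genes.df.iterrows():
                if g["strand"] == "+":
                    prom = (g["tss"] - 1000, g["tss"] + 100)
                else:
                    prom = (g["tss"] - 100, g["tss"] + 1000)
                if prom[0] <= mid <= prom[1]:
                    in_prom = True
                if g["tts"] - 100 <= mid <= g["tts"] + 100:
                    in_tts = True
                if g["start"] <= mid < g["end"]:
                    in_body = True
            if in_prom:
                exp = "promoter-TSS"
            elif in_tts:
                exp = "TTS"
            elif in_body:
                exp = "gene-body"
            assert cat == exp
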