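# depotatac

Integration of ATAC-seq chromatin accessibility with depot-specific gene
expression in human subcutaneous preadipocytes.

Fat stored in the lower body (gluteofemoral, **GF**) behaves differently from
abdominal (**A**) subcutaneous fat, and preadipocytes cultured from the two
depots keep a depot-of-origin transcriptional program. `depotatac` implements
the computational pipeline for asking *whether depot-specific gene expression
is mirrored by depot-specific open chromatin*: it takes per-sample ATAC-seq
peak calls and fragment coordinates from the two depots (2 subjects × 2
technical replicates each, 8 samples), per-subject RNA-seq differential
expression tables, and a gene annotation, and produces the depot-specific
open-chromatin regions, the cross-subject gene signature, promoter
accessibility classes, and the region-to-gene linkage summary.

## Method

1. **Consensus peaks** — a base belongs to the consensus iff peaks from ≥ 2
   distinct samples cover it; maximal runs form the consensus regions.
2. **Normalization** — fragments are extended to 150 bp from their 5′ end and
   piled into coverage; each sample's track is divided by its median "summit
   coverage" (mean coverage in the central 50-bp bin of each consensus peak),
   so the median summit coverage is exactly 1 after scaling.
3. **Depot-specific regions** — per region, a Welch two-sample *t*-test on
   log₂(normalized signal + 0.1) across the 4 A vs 4 GF sample columns;
   regions with raw *p* ≤ 0.005 are called A- or GF-specific by the sign of
   log₂FC = log₂((mean_A + 0.1)/(mean_GF + 0.1)).
4. **Gene signature** — a gene is depot-specific when *p* ≤ 0.05 in **every**
   subject's DE table with a consistent fold-change direction
   (A-up / GF-up).
5. **Promoter accessibility** — RPKM of depot-pooled fragments in TSS ± 250 bp
   windows; a promoter is "more open" in a depot when the RPKM ratio passes a
   1.5-fold cutoff.
6. **Region–gene linking** — a depot-specific region links to a signature
   gene when its midpoint lies within ± 100 kb of the TSS, clipped at the
   nearest neighboring gene; links are "matched" when region depot and gene
   direction agree. Percentages are integer round-half-up.
7. **qPCR validation arithmetic** — ChIP enrichment as percent of the input
   aliquot, 100 × 2^(Ct_input − Ct_IP); ΔCt relative expression normalized to
   PPIA; paired Wilcoxon / *t* comparisons across subjects.

A bundled generator (`depotatac.simulate`) produces depot-structured
synthetic datasets (negative-binomial peak counts, planted specific regions
and signature genes, ground-truth link table) so the whole pipeline is
testable without any sequencing data.

## Worked example

```bash
depotatac simulate --seed 1 --out scratch/demo
depotatac run --data-dir scratch/demo --out scratch/demo_out
```

prints (abridged):

```
Peaks: A=229  GF=227  shared: 224 (98% of A), 224 (99% of GF)
Consensus regions (>=2 samples): 228
Depot-specific regions: A=39 GF=11 (A:GF ratio 3.55)
Signature genes: A-up=14 GF-up=10 total=24
Per-subject DE counts (p <= alpha): {'subject1': 45, 'subject2': 29}
```

Reading: the two depots share almost all peaks (98–99%), as expected for the
same cell type; 39 regions are significantly more open in abdominal cells
versus 11 in GF (the generator plants a 40:8 asymmetry, which the caller
recovers); 24 genes are depot-specific in *both* subjects even though the
individual subjects have 45 and 29 significant genes. The link summary in
`report.json` then gives, per direction, how many signature genes carry a
depot-matched open region within the clipped ± 100 kb window.

Library use mirrors the CLI: `simulate_dataset` → `build_consensus` →
`normalize_track` → `test_differential` → `intersect_signatures` →
`link_regions_to_genes` → `summarize_links`, or everything at once via
`run_pipeline(PipelineConfig(...))`.

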