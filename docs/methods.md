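# Methods

## Coordinate model

All intervals are 0-based half-open (BED convention) on named chromosomes,
lexicographically ordered; GTF input (1-based inclusive) is converted on
read. No genome build is assumed and no sequence is ever required. The TSS
of a `+` gene is its span start; of a `-` gene, the last base of its span
(`end - 1`), so `tss < tts` on `+` and `tss > tts` on `-`.

## Coverage and normalization

Fragments are extended to a fixed length (default 150 bp) anchored at the
5′ end — directional when strand is present, left-anchored otherwise. An
`anchor="center"` option centers the extension on the fragment midpoint
instead, for data prepared with tag-centering tools. No Tn5 offset
correction (+4/−5) is applied. Coverage is a dense float64 per-base vector
per chromosome; total mass equals `extend_to × n_fragments` except where
extension is clipped at position 0 or a declared chromosome end.

The normalization scalar is the **per-sample median summit coverage**: for
each consensus peak, the mean per-base coverage in the 50-bp bin centered on
`floor((start+end)/2)` (peaks shorter than the bin use their full span; the
mean, not the sum, keeps edge clipping unbiased). The median is taken over
*all* consensus peaks of the sample, zeros included, and one median is
computed per sample rather than globally. Dividing by it makes the
recomputed median summit coverage exactly 1 (a tested fixed point) and makes
normalization scale-equivariant: multiplying a raw track by any k > 0 leaves
the normalized track unchanged. A zero median raises an error — such a
sample has no usable signal on the consensus.

## Consensus geometry

A genomic base belongs to the consensus iff peaks from at least
`min_samples` (default 2) **distinct** samples cover it; a sample's own
overlapping peaks are merged first so it counts once per base. Maximal runs
of qualifying bases form the consensus intervals (equivalent to
intersect-then-merge), with support = number of distinct samples
overlapping the interval. The rule is symmetric and order-independent, and
is verified against a per-base counting oracle. Consensus coverage is
monotone non-increasing in `min_samples`.

## Differential accessibility statistic

The depot comparison is a deliberately transparent statistic rather than a
moderated count model: per consensus region, a Welch (unequal-variance)
two-sample *t*-test on `log2(x + 0.1)` of the per-sample mean normalized
coverage, A columns vs GF columns. The pseudocount 0.1 stabilizes empty
regions; the decision threshold is the raw `p ≤ 0.005` with **no**
multiple-testing correction (a Benjamini–Hochberg q-value column is emitted
for reference but plays no role in calls). Technical replicates enter as
independent columns (4 per depot) by default — a fidelity choice matching
the study design this pipeline mirrors — with `collapse_replicates=True`
averaging them to per-subject means (2 vs 2). Degenerate rows with zero
variance in both groups get p = 1 when the group means agree (no evidence)
and p = 0 when they differ exactly.

Calls partition regions: A-specific (p ≤ α, log₂FC > 0), GF-specific
(p ≤ α, log₂FC < 0), shared otherwise. Label swapping negates every log₂FC,
preserves p, and exchanges the two call sets — a tested antisymmetry. Null
calibration is tested empirically: on negative-binomial null matrices
(mean 100, dispersion 0.05, 4 vs 4), the mean specific-call fraction over
20 seeds stays at or below 2α at α = 0.005.

## Expression signature

A gene enters the signature iff `p ≤ 0.05` (inclusive) in every subject's DE
table **and** its fold change has the same sign in every subject. The
direction-consistency requirement is not part of the nominal threshold rule
but is forced by the downstream A-up/GF-up labels: without it a gene up in A
for one subject and up in GF for the other would belong to both lists. Gene
universes are intersected when tables disagree (dropped genes are logged).
Published fold-change magnitudes are descriptive only, never filters.

## Promoter accessibility

Promoter windows are `[TSS − 250, TSS + 250)` in genomic coordinates —
symmetric, so strand does not affect them — clipped only at position 0.
RPKM = fragments overlapping the window (extended interval, ≥ 1 bp) divided
by window length in kb × total fragments in millions; fragments are pooled
across each depot's samples since the comparison is depot-level (a
per-sample mode exists). RPKM is invariant to duplicating the fragment set.
The class ratio is `(rpkm_A + 0.05) / (rpkm_GF + 0.05)` — the 0.05
pseudocount guards zero-RPKM promoters, on which the definition is otherwise
silent — with `more-open-A` iff ratio ≥ 1.5, `more-open-GF` iff
ratio ≤ 1/1.5, `no-difference` between. Classes are disjoint, exhaustive,
and antisymmetric under depot swap.

TSS tag-density profiles average normalized coverage at offsets
−flank..+flank (default 250, 1-bp resolution) and *are* strand-aware:
offsets run antisense for `-` genes so negative offsets always mean
gene-upstream; a strand-reversed annotation yields the mirrored profile.
The flank is a parameter (250 or 500 both render) because the two windows
are both in common use for this display.

## Region–gene linking

Each signature gene gets a linking window: up to ± 100 kb from the TSS,
clipped on each side at the nearest span boundary of **any** other annotated
gene (not just signature genes), each side independently; a neighbor whose
span covers the TSS collapses that side to the TSS base, which is always
retained. A depot-specific region links to the gene when its **midpoint**
falls in the window (midpoint chosen for determinism; `overlap_mode="any"`
uses ≥ 1 bp interval overlap instead). A region may link to several genes
and vice versa. A link is *matched* when region depot equals gene direction.
The summary reports, per direction class, distinct genes with ≥ 1 matched /
mismatched region, link rows, distinct regions, and percentages of genes.

Percentages everywhere are integer **round-half-up** of
`100 × count / total`. This choice reproduces standard two-sided rounding
(74/126 → 59, 25/90 → 28, 91022/112362 → 81, 91022/104957 → 87); for
14/90 (= 15.56) it yields 16 — a truncated 15 is *not* emulated, and the
report flags any percentage whose fractional part would make truncation and
rounding differ.

## qPCR arithmetic

ChIP enrichment: `100 × 2^(Ct_input − Ct_IP)`, a percent **of the input
aliquot itself** (here 5%); an `input_fraction` option shifts the input Ct
by `−log2(1/f)` for percent of total chromatin. Relative expression is ΔCt:
`2^(Ct_ref − Ct_target)` with PPIA the conventional reference. Replicate
wells are averaged to one Ct before statistics. Paired depot comparisons
offer both the exact Wilcoxon signed-rank (default, suited to n = 6) and
the paired *t*; IgG series are carried through as negative controls, not
subtracted. All-zero differences return p = 1, direction 0.

## Synthetic data generator

The generator emulates the study conditions end to end: 2 depots × 2
subjects × 2 technical replicates; 200 shared, 40 A-specific and 8
GF-specific 400-bp peaks (a 5:1 planted asymmetry echoing the strong
A-dominance of specific regions at genome scale); 80 genes (2–10 kb) of
which 14 are A-signature and 10 GF-signature, on 2 × 2 Mb chromosomes.
Elements are placed uniformly without overlap (validated feasible at
construction; an over-full configuration errors).

Counts: fragments per peak per sample are negative-binomial with dispersion
0.05 around a per-peak log-normal baseline (mean 100 fragments, log₂ SD 1);
depot-specific peaks are multiplied by 2^2.5 in their matching depot only; a
per-(subject, peak) normal(0, 0.25 log₂) shift shared across the subject's
samples mimics large between-donor differences; background fragments are
Poisson at 0.05/kb. Per-sample peak *calls* are re-derived from the sampled
counts (threshold 40 fragments, ± 20 bp edge jitter), so consensus building
faces genuine sample-to-sample variation rather than copied truth.

Expression: observed per-subject log₂FC = planted effect (± 2.0 for
signature genes, 0 otherwise) + normal(0, 0.5) noise; p is the two-sided
normal tail of observed/SD. Each subject additionally receives private DE
genes (20 and 5 by default), making the per-subject significant sets overlap
only partially, as in real donors. A fraction of signature genes receive a
depot-matched specific peak directly on the TSS (50% A / 15% GF) or nearby
within 5–80 kb (30% A / 10% GF), and 30% of GF genes receive a *mismatched*
A-specific peak nearby — reproducing the qualitative finding that A-specific
chromatin appears near GF genes but rarely vice versa.

Ground-truth links are computed from the final geometry and true labels
(any truth-specific peak whose midpoint falls in a truth-signature gene's
clipped window), so they are the noise-free value of exactly the quantity
the pipeline estimates; recovery tests require ≥ 90% region and gene recall
and matched-gene percentages within 10 points of this truth at the default
conditions.

What the generator does **not** model: read-level sequence, fragment-length
mixtures (mono/di-nucleosome), GC or mappability bias, spatially structured
background, correlated peak–gene placement beyond the planted links, or
Cuffdiff's specific p-value behavior. Passing tests therefore demonstrate
the pipeline's correctness and calibration under idealized count noise, not
robustness to alignment or library artifacts.

## Problem sizes and determinism

Default test and acceptance runs use the scaled-down conditions above
(≈ 250 peaks, 80 genes, ≈ 60 k fragments/sample), for which a full
simulate-and-run cycle takes a few seconds; all randomness flows from a
single integer seed through `numpy.random.default_rng`, and identical
configurations produce identical files. The published genome-scale tallies
(112,362 / 104,957 peaks, 7,160 / 780 specific regions, 126 / 90 signature
genes) derive from human sequencing data that was never deposited; they
enter the package only as *inputs* to the report arithmetic, whose derived
percentages and totals are recomputed and checked exactly.

## Known limitations

- The differential statistic is not DiffBind; agreement with DiffBind's
  moderated dispersion model is not claimed, only threshold-level behavior
  (raw p ≤ 0.005) with tested calibration.
- Treating technical replicates as independent columns inflates effective n;
  the collapse option is provided but is not the default, by design.
- Whether the original analysis used one normalization median per sample or
  a global one is not documented; per-sample is implemented.
- Linking-window anchoring uses the TSS only; anchoring at the TTS side of
  neighbor spans is covered via span boundaries, but no TTS-anchored window
  variant is offered.
- With only 10 GF-signature genes at default scale, one gene is 10
  percentage points; GF-side recovery metrics are correspondingly coarse.
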