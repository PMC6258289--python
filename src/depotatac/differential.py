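"""Depot-specific open-chromatin calling and genomic-context annotation.

The differential statistic is deliberately simple and transparent: per
consensus region, a Welch (unequal-variance) two-sample t-test on
log2(normalized signal + pseudocount) across the abdominal (A) and
gluteofemoral (GF) sample columns, with the decision threshold applied to the
raw p-value (default p <= 0.005, no multiple-testing correction; a
Benjamini-Hochberg column is emitted for reference). Technical replicates
are treated as independent columns by default, with an option to collapse
them to per-(depot, subject) means.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneAnnotation
from .consensus import ConsensusPeakSet
from .coverage import CoverageTrack
from .intervals import PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "build_signal_matrix",
    "test_differential",
    "annotate_genomic_context",
    "welch_log_t",
]


def build_signal_matrix(
    consensus: ConsensusPeakSet, tracks: dict[str, CoverageTrack]
) -> pd.DataFrame:
    """Regions x samples matrix of mean normalized coverage per region.

    ``tracks`` maps sample id -> normalized CoverageTrack. A sample missing a
    chromosome contributes 0 for regions on it (logged once per chromosome).
    """
    region_ids = consensus.region_ids()
    data = {}
    for sample_id, track in tracks.items():
        col = np.empty(len(consensus), dtype=np.float64)
        missing: set[str] = set()
        for i, iv in enumerate(consensus):
            if iv.chrom not in track.values:
                missing.add(iv.chrom)
            col[i] = track.mean_over(iv.chrom, iv.start, iv.end)
        for chrom in sorted(missing):
            logger.warning(
                "sample %s has no coverage on %s; regions there scored 0",
                sample_id, chrom,
            )
        data[sample_id] = col
    return pd.DataFrame(data, index=region_ids)


def welch_log_t(
    a: np.ndarray, b: np.ndarray, pseudocount: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test on log2(x + pseudocount).

    Returns (t, p). Degenerate rows (zero variance in both groups) get
    t = 0, p = 1 when the group means are equal, and p = 0 when they differ
    (infinite evidence under the model's scale estimate).
    """
    la = np.log2(np.asarray(a, dtype=np.float64) + pseudocount)
    lb = np.log2(np.asarray(b, dtype=np.float64) + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    t = np.asarray(t, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    bad = ~np.isfinite(p)
    if np.any(bad):
        eq = np.isclose(la[bad].mean(axis=1), lb[bad].mean(axis=1))
        p[bad] = np.where(eq, 1.0, 0.0)
        with np.errstate(invalid="ignore"):
            t[bad] = np.where(
                eq, 0.0, np.sign(la[bad].mean(axis=1) - lb[bad].mean(axis=1)) * np.inf
            )
    return t, p


def test_differential(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    alpha: float = 0.005,
    pseudocount: float = 0.1,
    collapse_replicates: bool = False,
) -> pd.DataFrame:
    """Call depot-specific regions from a signal matrix.

    ``sample_sheet`` needs columns ``sample`` (matching matrix columns),
    ``depot`` ('A'/'GF'), ``subject``, ``replicate``. Returns a table with
    mean_A, mean_GF, log2fc (A over GF), t, p_value, q_value and
    call in {'A-specific', 'GF-specific', 'shared'}, sorted by p ascending.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ss = sample_sheet.set_index("sample")
    unknown = [c for c in matrix.columns if c not in ss.index]
    if unknown:
        raise ValueError(f"samples missing from sample sheet: {unknown}")
    cols_a = [c for c in matrix.columns if ss.loc[c, "depot"] == "A"]
    cols_gf = [c for c in matrix.columns if ss.loc[c, "depot"] == "GF"]
    va = matrix[cols_a].to_numpy(dtype=np.float64)
    vgf = matrix[cols_gf].to_numpy(dtype=np.float64)
    if collapse_replicates:
        va = _collapse(va, [ss.loc[c, "subject"] for c in cols_a])
        vgf = _collapse(vgf, [ss.loc[c, "subject"] for c in cols_gf])
    if va.shape[1] < 2 or vgf.shape[1] < 2:
        raise ValueError("need >=2 sample columns per depot for a variance estimate")
    mean_a = va.mean(axis=1)
    mean_gf = vgf.mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_gf + pseudocount))
    t, p = welch_log_t(va, vgf, pseudocount)
    call = np.where(
        (p <= alpha) & (log2fc > 0),
        "A-specific",
        np.where((p <= alpha) & (log2fc < 0), "GF-specific", "shared"),
    )
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "region_id": matrix.index,
            "mean_A": mean_a,
            "mean_GF": mean_gf,
            "log2fc": log2fc,
            "t": t,
            "p_value": p,
            "q_value": q,
            "call": call,
        }
    )
    out["neg_log10_p"] = -np.log10(np.maximum(out["p_value"], 1e-300))
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def _collapse(values: np.ndarray, subjects: list) -> np.ndarray:
    uniq = sorted(set(subjects), key=str)
    cols = []
    for s in uniq:
        idx = [i for i, x in enumerate(subjects) if x == s]
        cols.append(values[:, idx].mean(axis=1))
    return np.column_stack(cols)


_CATEGORIES = ("promoter-TSS", "TTS", "gene-body", "intergenic")


def annotate_genomic_context(
    peaks: PeakSet,
    genes: GeneAnnotation,
    promoter_up: int = 1000,
    promoter_down: int = 100,
) -> list[str]:
    """Classify each peak by its midpoint with priority
    promoter-TSS > TTS > gene-body > intergenic.

    The promoter window is [TSS - promoter_up, TSS + promoter_down]
    strand-aware (upstream means 5' of the gene); the TTS window is symmetric
    +/- promoter_down; the gene body is the full gene span.
    """
    df = genes.df
    cats = []
    for iv in peaks:
        mid = iv.midpoint
        sub = df[df["chrom"] == iv.chrom]
        cat = "intergenic"
        if len(sub):
            tss = sub["tss"].to_numpy()
            tts = sub["tts"].to_numpy()
            plus = (sub["strand"] == "+").to_numpy()
            prom_lo = np.where(plus, tss - promoter_up, tss - promoter_down)
            prom_hi = np.where(plus, tss + promoter_down, tss + promoter_up)
            if np.any((mid >= prom_lo) & (mid <= prom_hi)):
                cat = "promoter-TSS"
            elif np.any((mid >= tts - promoter_down) & (mid <= tts + promoter_down)):
                cat = "TTS"
            elif np.any(
                (mid >= sub["start"].to_numpy()) & (mid < sub["end"].to_numpy())
            ):
                cat = "gene-body"
        cats.append(cat)
    return cats
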