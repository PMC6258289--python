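"""qPCR arithmetic for the validation arm: ChIP percent-of-input,
reference-normalized relative expression (delta-Ct), and paired depot
comparisons.

Percent of input follows the convention of expressing enrichment relative to
the reserved input aliquot itself (here a 5% aliquot): 100 * 2^(Ct_input -
Ct_IP), with an optional adjustment to percent of TOTAL input for users who
want it.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_input",
    "relative_expression",
    "paired_compare",
    "read_ct_table",
    "percent_input_table",
    "relative_expression_table",
]


def percent_input(ct_ip: float, ct_input: float, input_fraction: float | None = None) -> float:
    """ChIP enrichment as a percentage of the input aliquot.

    ``100 * 2^(ct_input - ct_ip)``. When ``input_fraction`` f is given the
    input Ct is first shifted by -log2(1/f) so the result is a percent of
    total chromatin instead of the aliquot.
    """
    if not (math.isfinite(ct_ip) and math.isfinite(ct_input)):
        raise ValueError("Ct values must be finite")
    if input_fraction is not None:
        if not 0 < input_fraction <= 1:
            raise ValueError("input_fraction must be in (0, 1]")
        ct_input = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (ct_input - ct_ip)


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Delta-Ct relative expression: ``2^(ct_reference - ct_target)``."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (ct_reference - ct_target)


def paired_compare(
    values_a, values_gf, method: str = "wilcoxon-signed-rank"
) -> tuple[float, int]:
    """Two-sided paired comparison of per-subject A vs GF measurements.

    Returns (p_value, direction) with direction the sign of the median
    per-subject difference (A - GF). Methods: 'wilcoxon-signed-rank'
    (exact when ties permit) or 'paired-t'. All-zero differences give
    (1.0, 0).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_gf, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and the same length")
    if a.size < 3:
        raise ValueError("need >=3 subject pairs")
    diff = a - b
    direction = int(np.sign(np.median(diff)))
    if np.all(diff == 0):
        return 1.0, 0
    if method == "wilcoxon-signed-rank":
        p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    elif method == "paired-t":
        p = float(stats.ttest_rel(a, b).pvalue)
    else:
        raise ValueError("method must be 'wilcoxon-signed-rank' or 'paired-t'")
    return p, direction


_CT_COLS = ["subject_id", "depot", "target", "assay", "ct"]


def read_ct_table(path_or_stream) -> pd.DataFrame:
    """Read a Ct table (TSV: subject_id, depot, target, assay, ct).

    Replicate wells (duplicated keys) are averaged to one Ct. Assays follow
    the convention 'IP:<antibody>', 'input' or 'expression'.
    """
    df = pd.read_csv(path_or_stream, sep="\t")
    missing = [c for c in _CT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    df = (
        df.groupby(["subject_id", "depot", "target", "assay"], as_index=False)["ct"]
        .mean()
    )
    return df


def percent_input_table(
    ct: pd.DataFrame, input_fraction: float | None = None
) -> pd.DataFrame:
    """Percent-of-input for every IP row against its matching input row.

    Matching is on (subject_id, depot, target); a missing input row is an
    error. IgG rows are carried through as the negative-control series.
    """
    ips = ct[ct["assay"].str.startswith("IP:")]
    inputs = ct[ct["assay"] == "input"].set_index(["subject_id", "depot", "target"])
    rows = []
    for _, r in ips.iterrows():
        key = (r["subject_id"], r["depot"], r["target"])
        if key not in inputs.index:
            raise ValueError(f"no input Ct for {key}")
        rows.append(
            {
                "subject_id": r["subject_id"],
                "depot": r["depot"],
                "target": r["target"],
                "antibody": r["assay"].split(":", 1)[1],
                "percent_input": percent_input(
                    r["ct"], float(inputs.loc[key, "ct"]), input_fraction
                ),
            }
        )
    return pd.DataFrame(rows)


def relative_expression_table(ct: pd.DataFrame, reference: str = "PPIA") -> pd.DataFrame:
    """Delta-Ct expression of every 'expression' target against the reference
    gene within the same (subject, depot)."""
    expr = ct[ct["assay"] == "expression"]
    refs = expr[expr["target"] == reference].set_index(["subject_id", "depot"])
    rows = []
    for _, r in expr[expr["target"] != reference].iterrows():
        key = (r["subject_id"], r["depot"])
        if key not in refs.index:
            raise ValueError(f"no {reference} reference Ct for {key}")
        rows.append(
            {
                "subject_id": r["subject_id"],
                "depot": r["depot"],
                "target": r["target"],
                "relative_expression": relative_expression(
                    r["ct"], float(refs.loc[key, "ct"])
                ),
            }
        )
    return pd.DataFrame(rows)
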