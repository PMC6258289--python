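"""Cross-subject depot-specific gene signatures.

A gene enters the signature iff it is significant (p <= alpha, default 0.05,
inclusive) in EVERY subject's differential-expression table AND its fold
change points the same way in every subject. Direction 'A-up' means higher
expression in abdominal preadipocytes, 'GF-up' higher in gluteofemoral.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_de_table", "intersect_signatures", "signature_counts"]

_DE_COLS = ["gene_id", "log2fc", "p_value"]


def read_de_table(path_or_stream, subject_id: str | None = None) -> pd.DataFrame:
    """Read a per-subject DE table (TSV with gene_id, log2fc, p_value)."""
    df = pd.read_csv(path_or_stream, sep="\t")
    missing = [c for c in _DE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if df["gene_id"].duplicated().any():
        raise ValueError("DE table has duplicate gene_id rows")
    if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
        raise ValueError("p_value outside [0, 1]")
    if subject_id is not None:
        df = df.copy()
        df["subject_id"] = subject_id
    return df


def intersect_signatures(
    tables: dict[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Signature = genes with p <= alpha and a consistent fold-change sign in
    all subjects.

    ``tables`` maps subject id -> DE table. Gene universes are restricted to
    their intersection (dropped genes are counted in a log message). Returns
    a frame indexed by gene_id with a ``direction`` column ('A-up'/'GF-up')
    and per-subject ``log2fc_<subject>`` / ``p_<subject>`` columns.
    """
    if len(tables) < 2:
        raise ValueError("need DE tables from >=2 subjects")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    subjects = list(tables)
    universes = [set(t["gene_id"]) for t in tables.values()]
    common = set.intersection(*universes)
    dropped = len(set.union(*universes)) - len(common)
    if dropped:
        logger.warning("gene universes disagree: %d genes dropped", dropped)
    wide = None
    for subj in subjects:
        t = tables[subj]
        t = t[t["gene_id"].isin(common)][_DE_COLS].rename(
            columns={"log2fc": f"log2fc_{subj}", "p_value": f"p_{subj}"}
        )
        wide = t if wide is None else wide.merge(t, on="gene_id")
    sig_all = pd.Series(True, index=wide.index)
    pos_all = pd.Series(True, index=wide.index)
    neg_all = pd.Series(True, index=wide.index)
    for subj in subjects:
        sig_all &= wide[f"p_{subj}"] <= alpha
        pos_all &= wide[f"log2fc_{subj}"] > 0
        neg_all &= wide[f"log2fc_{subj}"] < 0
    keep = sig_all & (pos_all | neg_all)
    out = wide[keep].copy()
    out["direction"] = "GF-up"
    out.loc[pos_all[keep], "direction"] = "A-up"
    out = out.sort_values("gene_id").set_index("gene_id", drop=False)
    return out


def signature_counts(signature: pd.DataFrame) -> tuple[int, int, int]:
    """(n_A_up, n_GF_up, n_total) tallies of a signature frame."""
    if len(signature) == 0:
        return 0, 0, 0
    n_a = int((signature["direction"] == "A-up").sum())
    n_gf = int((signature["direction"] == "GF-up").sum())
    return n_a, n_gf, n_a + n_gf
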