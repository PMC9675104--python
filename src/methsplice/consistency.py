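"""Multi-cancer aggregation of significant CpG-exon correlations.

A CpG-exon pair significant in two or more cancer types is a
"multi-cancer" pair. For each such pair the consistency score is the
fraction of its significant correlations sharing the majority sign
(range 0.5-1, 1 meaning every cancer agrees on direction), and pairs are
ranked by the mean absolute value of their significant correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "consistency_score",
    "majority_sign",
    "collect_pairs",
    "rank_pairs",
    "consistency_summary",
    "read_pairs_table",
]

PAIR_COLUMNS = [
    "cpg",
    "exon",
    "gene",
    "cancers",
    "correlations",
    "n_cancers",
    "consistency",
    "majority_sign",
    "sign_tie",
    "mean_abs_r",
]


def _signs(rs) -> np.ndarray:
    rs = np.asarray(rs, dtype=float)
    if rs.size < 2:
        raise ValueError("need correlations from >= 2 cancers")
    if np.any(rs == 0):
        raise ValueError("zero correlation has no sign")
    return np.sign(rs)


def consistency_score(rs) -> float:
    """max(#positive, #negative) / total over the pair's significant correlations."""
    s = _signs(rs)
    n_pos = int((s > 0).sum())
    return max(n_pos, s.size - n_pos) / s.size


def majority_sign(rs) -> tuple[str, bool]:
    """Sign of the majority group; count ties broken by larger summed |r|.

    Returns (sign, tie_flag).
    """
    rs = np.asarray(rs, dtype=float)
    s = _signs(rs)
    n_pos = int((s > 0).sum())
    n_neg = s.size - n_pos
    if n_pos != n_neg:
        return ("+" if n_pos > n_neg else "-"), False
    mass_pos = float(np.abs(rs[s > 0]).sum())
    mass_neg = float(np.abs(rs[s < 0]).sum())
    return ("+" if mass_pos >= mass_neg else "-"), True


def collect_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate significant exon records into multi-cancer pairs.

    Only rows flagged significant enter; pairs seen in a single cancer are
    dropped. Within one (cancer, cpg, exon) there is one record by
    construction of the screen.
    """
    if records.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    sig = records[records["significant"]] if "significant" in records else records
    rows = []
    for (cpg, exon), grp in sig.groupby(["cpg", "target"], sort=True):
        if grp["cancer"].nunique() < 2:
            continue
        grp = grp.sort_values("cancer")
        rs = grp["r"].to_numpy()
        sign, tie = majority_sign(rs)
        rows.append(
            (
                cpg,
                exon,
                grp["gene"].iloc[0],
                ";".join(grp["cancer"]),
                ";".join(f"{r:.6g}" for r in rs),
                int(len(grp)),
                consistency_score(rs),
                sign,
                tie,
                float(np.abs(rs).mean()),
            )
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def rank_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Sort descending by mean |r|; ties broken lexicographically by (cpg, exon)."""
    out = pairs.sort_values(
        ["mean_abs_r", "cpg", "exon"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    if len(out) != len(pairs):
        raise AssertionError("ranking must be a permutation")
    return out


def consistency_summary(pairs: pd.DataFrame) -> tuple[float, float]:
    """(fraction of pairs with score exactly 1, fraction with score > 0.7)."""
    if pairs.empty:
        raise ValueError("no multi-cancer pairs to summarize")
    scores = pairs["consistency"].to_numpy(dtype=float)
    return float((scores == 1.0).mean()), float((scores > 0.7).mean())


def read_pairs_table(path) -> pd.DataFrame:
    """Read a multi-cancer pair table written by the aggregation stage
    (or an equivalently structured external table)."""
    df = pd.read_csv(path, sep="\t", dtype={"cpg": str, "exon": str, "gene": str})
    missing = [c for c in ("cpg", "exon") if c not in df.columns]
    if missing:
        raise ValueError(f"pair table missing columns {missing}")
    return df
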