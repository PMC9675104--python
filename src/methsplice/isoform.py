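"""Direction-matched exon-vs-isoform correlation strength comparison.

If methylation of a CpG modulates inclusion of a single exon, the
CpG-exon correlation should be stronger than the CpG's correlation with
any isoform containing that exon, because the isoform signal averages
the affected exon with unaffected ones. For every significant CpG-exon
record we therefore pick, among isoforms that contain the exon and whose
CpG-isoform correlation is significant in the same cancer, the one with
the strongest correlation of the *same sign*, and summarize the
distribution of |r_exon| - |r_isoform|.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["candidate_isoforms", "select_matched", "build_diff_table", "diff_distribution"]

logger = logging.getLogger(__name__)

DIFF_COLUMNS = ["cancer", "gene", "cpg", "exon", "isoform", "r_exon", "r_isoform", "diff"]


def candidate_isoforms(exon_id, cpg_id, cancer, isoform_records, feature_map, gene=None):
    """Significant same-cancer CpG-isoform correlations for isoforms containing the exon."""
    recs = isoform_records
    if "significant" in recs:
        recs = recs[recs["significant"]]
    recs = recs[(recs["cancer"] == cancer) & (recs["cpg"] == cpg_id)]
    if gene is not None:
        recs = recs[recs["gene"] == gene]
    out = []
    for row in recs.itertuples(index=False):
        members = feature_map.isoform_exons.get(row.target, [])
        if exon_id in members:
            out.append((row.target, float(row.r)))
    return sorted(out)


def select_matched(r_exon: float, candidates):
    """Strongest same-sign candidate, or None when no candidate matches direction.

    Ties in |r| go to the lexicographically smallest isoform id.
    """
    if r_exon == 0:
        raise ValueError("exon correlation of exactly zero has no direction")
    same = [(iso, r) for iso, r in candidates if np.sign(r) == np.sign(r_exon)]
    if not same:
        return None
    best = max(sorted(same), key=lambda ir: (abs(ir[1]), ))
    ties = [iso for iso, r in same if abs(r) == abs(best[1])]
    if len(ties) > 1:
        logger.info("tie among isoforms %s; keeping %s", ties, min(ties))
        iso = min(ties)
        r = dict(same)[iso]
        return iso, r
    return best


def build_diff_table(exon_records: pd.DataFrame, isoform_records: pd.DataFrame, feature_map) -> pd.DataFrame:
    """One row per significant CpG-exon record; matched isoform and
    diff = |r_exon| - |r_isoform| where a direction-consistent significant
    isoform exists, NaN otherwise."""
    sig_exon = exon_records[exon_records["significant"]] if "significant" in exon_records else exon_records
    sig_iso = isoform_records[isoform_records["significant"]] if "significant" in isoform_records else isoform_records
    iso_by_key: dict = {}
    for row in sig_iso.itertuples(index=False):
        iso_by_key.setdefault((row.cancer, row.gene, row.cpg), []).append((row.target, float(row.r)))
    rows = []
    for row in sig_exon.itertuples(index=False):
        cands = [
            (iso, r)
            for iso, r in iso_by_key.get((row.cancer, row.gene, row.cpg), [])
            if row.target in feature_map.isoform_exons.get(iso, [])
        ]
        chosen = select_matched(float(row.r), sorted(cands)) if cands else None
        if chosen is None:
            rows.append((row.cancer, row.gene, row.cpg, row.target, None, float(row.r), np.nan, np.nan))
        else:
            iso, r_iso = chosen
            rows.append(
                (row.cancer, row.gene, row.cpg, row.target, iso, float(row.r), r_iso, abs(row.r) - abs(r_iso))
            )
    return pd.DataFrame(rows, columns=DIFF_COLUMNS)


def diff_distribution(diff_table: pd.DataFrame, bin_width: float = 0.05):
    """Fractions (diff > 0, diff > 0.1, diff < -0.1) over matched records,
    plus a fixed-width histogram over [-1, 1].

    Matched records are counted once per (cancer, pair); a collapsed
    per-pair tally (mean diff per unique CpG-exon pair over cancers) is
    returned alongside.
    """
    matched = diff_table.dropna(subset=["diff"])
    if matched.empty:
        raise ValueError("no matched CpG-exon/isoform records to summarize")
    diffs = matched["diff"].to_numpy(dtype=float)
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 10)
    counts, _ = np.histogram(np.clip(diffs, -1.0, 1.0 - 1e-12), bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})

    def fractions(d):
        return {
            "frac_gt_0": float((d > 0).mean()),
            "frac_gt_0.1": float((d > 0.1).mean()),
            "frac_lt_-0.1": float((d < -0.1).mean()),
            "n": int(d.size),
        }

    per_pair = matched.groupby(["cpg", "exon"])["diff"].mean().to_numpy()
    return {
        "per_record": fractions(diffs),
        "per_pair": fractions(per_pair),
        "histogram": hist,
    }
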