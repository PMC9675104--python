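"""Per-cancer CpG-target Pearson correlation screen.

For each cancer type and each gene, correlations are computed between the
beta values of every CpG assigned to the gene and the expression of every
exon (or isoform) of that gene, using only the gene's high-expression
cohort within that cancer. A gene/cancer combination is screened only
when the cohort holds at least ``min_cohort`` (default 10) patients;
missing beta values are removed pairwise and the floor applies to the
pairwise-complete count. Multiple testing is controlled per cancer type
and per target kind, by Benjamini-Hochberg by default (Bonferroni
available), and a record is significant when its adjusted p falls below
the threshold (default 0.05).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["pearson", "correlate_gene", "adjust_per_cancer", "run_screen", "RECORD_COLUMNS"]

logger = logging.getLogger(__name__)

MIN_COHORT = 10
RECORD_COLUMNS = ["cancer", "gene", "cpg", "target", "target_kind", "n", "r", "p"]
ADJUSTED_COLUMNS = RECORD_COLUMNS + ["p_adj", "significant"]


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p, after pairwise removal of missing values.

    Raises ``ValueError`` when fewer than 3 complete pairs remain or either
    vector is constant (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _p_from_r(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the t transform of r with n-2 degrees of freedom."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    denom = np.sqrt(np.maximum(1.0 - r * r, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df) / denom
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(t, df), 0.0)
    return np.minimum(p, 1.0)


def _pearson_block(x: np.ndarray, targets: np.ndarray):
    """Correlate one CpG vector against a block of target rows, pairwise-complete.

    Returns (r, n) arrays of length ``targets.shape[0]``; entries where either
    side is constant (or degenerate) come back as NaN.
    """
    valid = ~np.isnan(x) & ~np.isnan(targets)  # t x n
    n = valid.sum(axis=1).astype(float)
    xm = np.where(valid, x, 0.0)
    tm = np.where(valid, targets, 0.0)
    sx = xm.sum(axis=1)
    st = tm.sum(axis=1)
    sxx = (xm * xm).sum(axis=1)
    stt = (tm * tm).sum(axis=1)
    sxt = (xm * tm).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxt - sx * st
        vx = n * sxx - sx * sx
        vt = n * stt - st * st
        r = cov / np.sqrt(vx * vt)
    r = np.where((vx <= 0) | (vt <= 0) | (n < 3), np.nan, r)
    return np.clip(r, -1.0, 1.0), n.astype(int)


def correlate_gene(
    cancer: str,
    gene: str,
    cohort,
    feature_map,
    meth,
    expr,
    target_kind: str,
    min_cohort: int = MIN_COHORT,
) -> pd.DataFrame:
    """All CpG x target correlation records for one gene in one cancer cohort.

    ``cohort`` is the gene's high-expression sample list within the cancer;
    the whole gene is skipped (empty frame) when it is below ``min_cohort``.
    """
    if gene not in set(feature_map.genes):
        raise KeyError(f"gene {gene!r} absent from feature map")
    cohort = [s for s in cohort if s in meth.values.columns and s in expr.values.columns]
    if len(cohort) < min_cohort:
        logger.info("skip %s/%s: cohort %d < %d", cancer, gene, len(cohort), min_cohort)
        return pd.DataFrame(columns=RECORD_COLUMNS)

    cpgs = [c for c in feature_map.gene_cpgs.get(gene, []) if c in meth.values.index]
    if target_kind == "exon":
        targets = feature_map.gene_exons.get(gene, [])
    elif target_kind == "isoform":
        targets = feature_map.gene_isoforms.get(gene, [])
    else:
        raise ValueError(f"target_kind must be 'exon' or 'isoform', got {target_kind!r}")
    targets = [t for t in targets if t in expr.values.index]
    if not cpgs or not targets:
        return pd.DataFrame(columns=RECORD_COLUMNS)

    X = meth.values.loc[cpgs, cohort].to_numpy(dtype=float)
    T = expr.values.loc[targets, cohort].to_numpy(dtype=float)
    rows = []
    for i, cpg in enumerate(cpgs):
        r, n = _pearson_block(X[i], T)
        p = _p_from_r(np.nan_to_num(r), np.maximum(n, 3))
        for j, target in enumerate(targets):
            if n[j] < min_cohort or np.isnan(r[j]):
                continue
            rows.append((cancer, gene, cpg, target, target_kind, int(n[j]), float(r[j]), float(p[j])))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def adjust_per_cancer(records: pd.DataFrame, method: str = "bh", alpha: float = 0.05) -> pd.DataFrame:
    """Adjust p-values over one cancer's family of tests.

    The family is every record in the frame (all genes of that cancer, one
    target kind); all rows must share one cancer label.
    """
    if records.empty:
        return records.assign(p_adj=pd.Series(dtype=float), significant=pd.Series(dtype=bool))
    cancers = records["cancer"].unique()
    if len(cancers) != 1:
        raise ValueError(f"adjust_per_cancer expects one cancer, got {sorted(cancers)}")
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if sm_method is None:
        raise ValueError(f"method must be 'bh' or 'bonferroni', got {method!r}")
    _, p_adj, _, _ = multipletests(records["p"].to_numpy(), alpha=alpha, method=sm_method)
    out = records.copy()
    out["p_adj"] = p_adj
    out["significant"] = out["p_adj"] < alpha
    return out


def run_screen(
    sample_table,
    meth,
    expr,
    feature_map,
    cohorts: dict,
    target_kind: str,
    method: str = "bh",
    alpha: float = 0.05,
    min_cohort: int = MIN_COHORT,
    genes=None,
) -> tuple[pd.DataFrame, dict]:
    """Full per-cancer screen over all genes.

    ``cohorts`` maps gene -> global high-expression sample set (from the
    step-fit stratification); the per-cancer cohort is its intersection with
    that cancer's samples. Returns the adjusted record table and summary
    counts over the significant subset.
    """
    genes = list(genes) if genes is not None else sorted(set(feature_map.genes) & set(cohorts))
    pieces = []
    for cancer in sample_table.cancer_types:
        members = set(sample_table.samples_of(cancer))
        cancer_records = []
        for gene in genes:
            cohort = sorted(set(cohorts.get(gene, ())) & members)
            rec = correlate_gene(
                cancer, gene, cohort, feature_map, meth, expr, target_kind, min_cohort
            )
            if not rec.empty:
                cancer_records.append(rec)
        if cancer_records:
            pieces.append(adjust_per_cancer(pd.concat(cancer_records, ignore_index=True), method, alpha))
    if pieces:
        table = pd.concat(pieces, ignore_index=True)
    else:
        table = pd.DataFrame(columns=ADJUSTED_COLUMNS)
    sig = table[table["significant"]] if len(table) else table
    summary = {
        "target_kind": target_kind,
        "n_records": int(len(table)),
        "n_significant": int(len(sig)),
        "n_unique_cpgs": int(sig["cpg"].nunique()) if len(sig) else 0,
        "n_unique_targets": int(sig["target"].nunique()) if len(sig) else 0,
        "n_unique_genes": int(sig["gene"].nunique()) if len(sig) else 0,
    }
    return table, summary
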