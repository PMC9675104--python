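"""Per-CpG log-rank survival scan and overlap enrichment.

For each cancer type, each gene's high-expression cohort is split per CpG
into methylated vs unmethylated patients by a step fit on the CpG's beta
values (the same one-step least-squares machinery used to binarize gene
expression), and the two groups are compared with a one-degree-of-freedom
log-rank test. P-values are Benjamini-Hochberg adjusted per cancer.

The enrichment question: are CpGs whose methylation correlates with exon
expression over-represented among survival-associated CpGs? Under
independence the expected overlap is (overall survival-hit rate) x
(number of exon-correlated units); fold enrichment is observed/expected.
Counting units are (cancer, CpG) pairs, with unique-CpG counts also
reported since the two collapse differently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .stepminer import fit_step

__all__ = [
    "binarize_methylation",
    "logrank",
    "survival_scan",
    "overlap_enrichment",
    "enrichment_from_counts",
    "fold_enrichment",
    "stratify_by_cpg_panel",
    "EnrichmentResult",
    "PanelStratification",
]

logger = logging.getLogger(__name__)

SCAN_COLUMNS = ["cancer", "gene", "cpg", "n_methylated", "n_unmethylated", "chi2", "p"]


def binarize_methylation(betas) -> np.ndarray | None:
    """Methylated/unmethylated labels from a step fit on one CpG's beta values.

    Returns a boolean array (True = methylated, beta above the fitted
    threshold) or None when the fit is degenerate (constant betas).
    """
    b = np.asarray(betas, dtype=float)
    fit = fit_step(b)
    if fit.degenerate:
        return None
    return b > fit.threshold


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """One-degree-of-freedom log-rank statistic and p for two groups.

    With zero events in both groups the curves are trivially identical and
    (0.0, 1.0) is returned.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        logger.info("log-rank with zero events; returning (0, 1)")
        return 0.0, 1.0

    t = np.concatenate([times_a, times_b])
    e = np.concatenate([events_a, events_b]).astype(float)
    g = np.concatenate([np.ones(times_a.size), np.zeros(times_b.size)])
    order = np.argsort(t, kind="mergesort")
    t, e, g = t[order], e[order], g[order]

    _, first = np.unique(t, return_index=True)
    n_at_risk = t.size - first  # sorted ascending, so everyone from `first` on is at risk
    na_at_risk = np.cumsum(g[::-1])[::-1][first]
    d_total = np.add.reduceat(e, first)
    d_a = np.add.reduceat(e * g, first)

    use = d_total > 0
    n, na, d, da = n_at_risk[use], na_at_risk[use], d_total[use], d_a[use]
    frac = na / n
    observed_minus_expected = float((da - d * frac).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d * frac * (1.0 - frac) * (n - d) / (n - 1.0)
    variance = float(var_terms[n > 1].sum())
    if variance <= 0:
        return 0.0, 1.0
    chi2 = observed_minus_expected**2 / variance
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def survival_scan(
    sample_table,
    meth,
    clinical,
    cohorts: dict,
    feature_map,
    min_cohort: int = 10,
    min_group: int = 1,
    alpha: float = 0.05,
    genes=None,
) -> pd.DataFrame:
    """Log-rank scan over every (cancer, gene, CpG) with an adequate cohort.

    The cohort is the gene's high-expression samples in the cancer that have
    clinical follow-up; it must reach ``min_cohort`` after dropping samples
    with missing betas for the CpG. BH adjustment is applied per cancer.
    """
    genes = list(genes) if genes is not None else sorted(set(feature_map.genes) & set(cohorts))
    clin_idx = clinical.table.set_index("sample_id")
    pieces = []
    for cancer in sample_table.cancer_types:
        members = set(sample_table.samples_of(cancer))
        rows = []
        for gene in genes:
            cohort = sorted(
                set(cohorts.get(gene, ()))
                & members
                & set(meth.values.columns)
                & set(clin_idx.index)
            )
            if len(cohort) < min_cohort:
                logger.info("skip %s/%s: survival cohort %d < %d", cancer, gene, len(cohort), min_cohort)
                continue
            cpgs = [c for c in feature_map.gene_cpgs.get(gene, []) if c in meth.values.index]
            if not cpgs:
                continue
            betas = meth.values.loc[cpgs, cohort].to_numpy(dtype=float)
            times = clin_idx.loc[cohort, "time"].to_numpy(dtype=float)
            events = clin_idx.loc[cohort, "event"].to_numpy(dtype=int)
            for i, cpg in enumerate(cpgs):
                b = betas[i]
                ok = ~np.isnan(b)
                if ok.sum() < min_cohort:
                    continue
                labels = binarize_methylation(b[ok])
                if labels is None:
                    logger.info("skip %s/%s/%s: degenerate beta step fit", cancer, gene, cpg)
                    continue
                n_m, n_u = int(labels.sum()), int((~labels).sum())
                if min(n_m, n_u) < min_group:
                    continue
                chi2, p = logrank(
                    times[ok][labels], events[ok][labels], times[ok][~labels], events[ok][~labels]
                )
                rows.append((cancer, gene, cpg, n_m, n_u, chi2, p))
        if rows:
            df = pd.DataFrame(rows, columns=SCAN_COLUMNS)
            _, fdr, _, _ = multipletests(df["p"].to_numpy(), alpha=alpha, method="fdr_bh")
            df["fdr"] = fdr
            df["significant"] = df["fdr"] < alpha
            pieces.append(df)
    if pieces:
        return pd.concat(pieces, ignore_index=True)
    return pd.DataFrame(columns=SCAN_COLUMNS + ["fdr", "significant"])


@dataclass(frozen=True)
class EnrichmentResult:
    n_cpg_total: int
    n_cancers: int
    n_sig_survival: int
    rate: float
    n_exon_correlated: int
    expected_overlap: float
    observed_overlap: int
    fold: float
    # unique-CpG view of the same overlap (units above are (cancer, CpG) pairs)
    n_exon_correlated_unique: int | None = None
    n_sig_survival_unique: int | None = None
    observed_overlap_unique: int | None = None


def fold_enrichment(observed: float, expected: float) -> float:
    """observed / expected; infinite (with a log note) when expected is 0."""
    if expected == 0:
        if observed > 0:
            logger.warning("zero expected overlap with observed %s; fold infinite", observed)
            return float("inf")
        return 0.0
    return observed / expected


def enrichment_from_counts(
    n_sig_survival: int,
    n_cpg_total: int,
    n_cancers: int,
    n_exon_correlated: int,
    observed_overlap: int,
) -> EnrichmentResult:
    """Enrichment arithmetic from bare counts.

    rate = survival hits / (platform CpGs x cancers); expected overlap under
    independence = rate x exon-correlated units; fold = observed / expected.
    """
    if min(n_sig_survival, n_cpg_total, n_cancers, n_exon_correlated, observed_overlap) < 0:
        raise ValueError("counts must be non-negative")
    rate = n_sig_survival / (n_cpg_total * n_cancers)
    expected = rate * n_exon_correlated
    return EnrichmentResult(
        n_cpg_total=n_cpg_total,
        n_cancers=n_cancers,
        n_sig_survival=n_sig_survival,
        rate=rate,
        n_exon_correlated=n_exon_correlated,
        expected_overlap=expected,
        observed_overlap=observed_overlap,
        fold=fold_enrichment(observed_overlap, expected),
    )


def overlap_enrichment(exon_units, survival_units, n_cpg_total: int, n_cancers: int) -> EnrichmentResult:
    """Enrichment between exon-correlated and survival-associated CpG sets.

    ``exon_units`` and ``survival_units`` are sets of (cancer, cpg) tuples.
    """
    exon_units = set(exon_units)
    survival_units = set(survival_units)
    observed = len(exon_units & survival_units)
    base = enrichment_from_counts(
        len(survival_units), n_cpg_total, n_cancers, len(exon_units), observed
    )
    exon_cpgs = {c for _, c in exon_units}
    surv_cpgs = {c for _, c in survival_units}
    return EnrichmentResult(
        **{
            **base.__dict__,
            "n_exon_correlated_unique": len(exon_cpgs),
            "n_sig_survival_unique": len(surv_cpgs),
            "observed_overlap_unique": len(exon_cpgs & surv_cpgs),
        }
    )


@dataclass
class PanelStratification:
    labels: pd.Series  # sample -> 1 or 2
    chi2: float
    p: float
    km_curves: pd.DataFrame  # columns group, time, survival


def stratify_by_cpg_panel(panel_betas: pd.DataFrame, clinical, k: int = 2) -> PanelStratification:
    """Two-group patient stratification from a small survival-related CpG panel.

    Patients are clustered on their beta profiles over the panel
    (average-linkage hierarchical clustering, Euclidean distance, cut at
    ``k``); survival of the two groups is compared by log-rank and
    Kaplan-Meier curves are returned as coordinate tables.
    """
    if panel_betas.shape[0] < 2:
        raise ValueError("panel needs >= 2 CpGs")
    profiles = panel_betas.T  # samples x cpgs
    clin = clinical.lookup(profiles.index)
    profiles = profiles.loc[clin.index]
    if len(profiles) < 10:
        raise ValueError(f"cohort of {len(profiles)} < 10 after clinical join")
    X = profiles.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("all patient methylation profiles identical; cannot cluster")
    Z = linkage(X, method="average", metric="euclidean")
    labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=profiles.index)
    g1 = labels.index[labels == 1]
    g2 = labels.index[labels != 1]
    chi2, p = logrank(
        clin.loc[g1, "time"], clin.loc[g1, "event"], clin.loc[g2, "time"], clin.loc[g2, "event"]
    )
    curves = []
    for name, members in (("group1", g1), ("group2", g2)):
        kmf = KaplanMeierFitter()
        kmf.fit(clin.loc[members, "time"], clin.loc[members, "event"])
        sf = kmf.survival_function_
        for t, s in zip(sf.index, sf.iloc[:, 0]):
            curves.append((name, float(t), float(s)))
    return PanelStratification(
        labels=labels,
        chi2=chi2,
        p=p,
        km_curves=pd.DataFrame(curves, columns=["group", "time", "survival"]),
    )
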