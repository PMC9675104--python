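"""One-step (two-level) least-squares fit for expression binarization.

Expression of a gene over a large cohort is typically bimodal: a silent
mode near zero and an expressed mode well above it. Sorting the values
and fitting a single-step function — a low segment of length ``k`` at its
mean, a high segment of length ``n - k`` at its mean — by least squares
places the step in the gap between the modes. The midpoint of the two
segment means is then a global binarization threshold, and samples above
it form the gene's high-expression cohort.

The fit is exact: every split ``k`` in ``[1, n-1]`` is scored via prefix
sums (O(n) after sorting) and the minimum-SSE split is returned, ties
going to the smallest ``k``. When no split improves on the flat
single-mean fit (constant data), the fit is flagged degenerate and the
gene is excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StepFit", "fit_step", "binarize", "stratify_gene", "stratify_matrix"]

HIGH, LOW = "high", "low"


@dataclass(frozen=True)
class StepFit:
    split_index: int  # number of values in the low segment (sorted order)
    low_mean: float
    high_mean: float
    threshold: float
    sse: float
    degenerate: bool


def fit_step(values) -> StepFit:
    """Least-squares one-step fit to ``values`` (sorted internally).

    Returns the split minimizing the total squared error of the two
    segment-mean fit; ``threshold`` is the midpoint of the two means.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 values to fit a step, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in step fit input")

    csum = np.cumsum(x)
    total, total_sq = csum[-1], float(np.dot(x, x))
    ks = np.arange(1, n)
    low_sum = csum[:-1]
    high_sum = total - low_sum
    # SSE_k = sum(x^2) - sum_low^2/k - sum_high^2/(n-k)
    sse = total_sq - low_sum**2 / ks - high_sum**2 / (n - ks)
    # ties (including float-noise ties from the prefix-sum form) -> smallest k
    tie_tol = 1e-12 * max(1.0, total_sq)
    best = int(np.flatnonzero(sse <= sse.min() + tie_tol)[0])
    k = int(ks[best])
    low_mean = float(low_sum[best] / k)
    high_mean = float(high_sum[best] / (n - k))
    best_sse = float(max(sse[best], 0.0))
    flat_sse = total_sq - total**2 / n

    degenerate = best_sse >= flat_sse - 1e-12 * max(1.0, abs(flat_sse))
    if degenerate:
        mean = float(total / n)
        return StepFit(0, mean, mean, mean, float(max(flat_sse, 0.0)), True)
    return StepFit(k, low_mean, high_mean, (low_mean + high_mean) / 2.0, best_sse, False)


def binarize(values, fit: StepFit) -> np.ndarray:
    """Boolean high-expression labels; values exactly at the threshold are low."""
    x = np.asarray(values, dtype=float)
    if fit.degenerate:
        return np.zeros(x.shape, dtype=bool)
    return x > fit.threshold


def stratify_gene(values: pd.Series) -> tuple[StepFit, pd.Series]:
    """Fit one global threshold for a gene over all samples (all cancers pooled)
    and label each sample high/low."""
    fit = fit_step(values.to_numpy())
    labels = pd.Series(
        np.where(binarize(values.to_numpy(), fit), HIGH, LOW),
        index=values.index,
        name=values.name,
    )
    return fit, labels


def stratify_matrix(gene_expr) -> tuple[pd.DataFrame, dict]:
    """Stratify every gene of an expression matrix.

    Returns a long table (gene_id, sample_id, label, threshold) and a dict
    gene -> StepFit. Degenerate genes are labeled all-low and carry a NaN
    threshold in the table.
    """
    rows = []
    fits: dict[str, StepFit] = {}
    for gene in gene_expr.feature_ids:
        fit, labels = stratify_gene(gene_expr.values.loc[gene])
        fits[gene] = fit
        thr = np.nan if fit.degenerate else fit.threshold
        for sample, lab in labels.items():
            rows.append((gene, sample, lab, thr))
    table = pd.DataFrame(rows, columns=["gene_id", "sample_id", "label", "threshold"])
    return table, fits


def cohorts_from_labels(label_table: pd.DataFrame) -> dict:
    """gene -> set of high-expression samples, from a stratify_matrix table."""
    high = label_table[label_table["label"] == HIGH]
    out: dict[str, set] = {g: set() for g in label_table["gene_id"].unique()}
    for gene, grp in high.groupby("gene_id"):
        out[gene] = set(grp["sample_id"])
    return out
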