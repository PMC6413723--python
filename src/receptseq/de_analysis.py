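"""Differential-expression calling between two conditions.

A gene is called up-regulated when its fold change (condition B over A)
strictly exceeds ``fc_cutoff`` and its p-value is strictly below
``p_cutoff``; down-regulated when the reciprocal fold change does.  The
per-gene test is a two-sided Welch t-test on log2(x+1) replicate values —
a conservative, assumption-light choice for FPKM-like abundances at n=3
per condition.  Also provides the clustering order used for heatmaps
(1 - Pearson correlation distance, average linkage / UPGMA).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

__all__ = ["fold_change", "welch_t", "call_de", "cluster_order"]

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 0.5  # pseudo-abundance stabilizing zero condition means


def fold_change(mean_a: float, mean_b: float, epsilon: float = DEFAULT_EPSILON):
    """Fold change of condition B over A with a pseudo-abundance epsilon.

    Returns ``(fold_change, log2fc)`` where
    ``fold_change = (mean_b + epsilon) / (mean_a + epsilon)``.
    Antisymmetric under swapping the conditions (log2fc negates).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if mean_a < 0 or mean_b < 0:
        raise ValueError("condition means must be non-negative")
    fc = (mean_b + epsilon) / (mean_a + epsilon)
    return fc, float(np.log2(fc))


def welch_t(group_a, group_b) -> float:
    """Two-sided Welch t-test p-value (Satterthwaite df).

    Both groups need >= 2 values.  Degenerate inputs follow a documented
    convention: two constant, equal groups give p = 1; two constant,
    unequal groups give p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        logger.debug("both groups constant; p=%s by convention", p)
        return p
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def call_de(
    matrix: ExpressionMatrix,
    fc_cutoff: float = 2.0,
    p_cutoff: float = 0.05,
    epsilon: float = DEFAULT_EPSILON,
    adjust: str = "none",
    alpha: float | None = None,
) -> pd.DataFrame:
    """Call per-gene differential expression between the two conditions.

    Returns a DE table with one row per gene: condition means, fold change
    (B over A), ratio magnitude (larger over smaller), log2fc, p-value and
    direction in {up, down, unchanged}.  ``adjust="bh"`` applies
    Benjamini-Hochberg across genes and thresholds the adjusted values at
    ``alpha`` (default: ``p_cutoff``) instead of the raw p-values.  Genes
    with all-zero abundance in both conditions are reported as unchanged
    with p = 1 rather than dropped, keeping gene universes aligned.
    """
    cond_a, cond_b = matrix.conditions
    va = matrix.values[matrix.samples_of(cond_a)].to_numpy(dtype=float)
    vb = matrix.values[matrix.samples_of(cond_b)].to_numpy(dtype=float)
    if va.shape[1] < 2 or vb.shape[1] < 2:
        raise ValueError("each condition needs >= 2 samples")

    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)
    fc = (mean_b + epsilon) / (mean_a + epsilon)
    log2fc = np.log2(fc)
    ratio_mag = np.maximum(fc, 1.0 / fc)

    la = np.log2(va + 1.0)
    lb = np.log2(vb + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pvals = stats.ttest_ind(la, lb, axis=1, equal_var=False).pvalue
    # degenerate rows: both groups constant -> convention p=1 (equal) / 0 (unequal)
    const = (la.var(axis=1, ddof=1) == 0) & (lb.var(axis=1, ddof=1) == 0)
    pvals = np.where(const, np.where(la.mean(axis=1) == lb.mean(axis=1), 1.0, 0.0), pvals)
    allzero = (mean_a == 0) & (mean_b == 0)
    pvals = np.where(allzero, 1.0, pvals)

    if adjust == "bh":
        thresh_p = multipletests(pvals, method="fdr_bh")[1]
        cut = p_cutoff if alpha is None else alpha
    elif adjust == "none":
        thresh_p = pvals
        cut = p_cutoff
    else:
        raise ValueError("adjust must be 'none' or 'bh'")

    sig = thresh_p < cut
    up = sig & (fc > fc_cutoff) & ~allzero
    down = sig & (1.0 / fc > fc_cutoff) & ~allzero
    direction = np.where(up, "up", np.where(down, "down", "unchanged"))

    table = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "ratio_magnitude": ratio_mag,
            "log2fc": log2fc,
            "p_value": pvals,
            "direction": direction,
        }
    )
    if adjust == "bh":
        table["q_value"] = thresh_p
    return table


def cluster_order(de_values: pd.DataFrame):
    """Heatmap leaf orders by UPGMA on 1 - Pearson correlation distance.

    ``de_values`` holds DE-gene rows x sample columns.  Zero-variance rows
    are dropped with a logged warning (the correlation distance is undefined
    for them).  Returns ``(gene_order, sample_order)`` as lists of labels;
    deterministic given input order.
    """
    mat = de_values.to_numpy(dtype=float)
    variances = mat.var(axis=1)
    keep = variances > 0
    if not keep.all():
        dropped = list(de_values.index[~keep])
        logger.warning("dropping %d zero-variance gene(s): %s", len(dropped), dropped)
    de_values = de_values.loc[keep]
    if len(de_values) < 2:
        raise ValueError("need >= 2 genes with nonzero variance to cluster")

    gene_order = _upgma_leaves(de_values.to_numpy(dtype=float))
    genes = [de_values.index[i] for i in gene_order]

    cols = de_values.to_numpy(dtype=float).T
    if cols.shape[0] >= 2 and (cols.var(axis=1) > 0).all():
        sample_order = _upgma_leaves(cols)
        samples = [de_values.columns[i] for i in sample_order]
    else:
        samples = list(de_values.columns)
    return genes, samples


def _upgma_leaves(rows: np.ndarray) -> list[int]:
    d = pdist(rows, metric="correlation")  # 1 - Pearson r
    d = np.clip(d, 0.0, None)  # guard tiny negative rounding
    z = linkage(d, method="average")
    return [int(i) for i in leaves_list(z)]
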