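"""Hypergeometric over-representation testing with Benjamini-Hochberg FDR.

The upper-tail hypergeometric p-value is the probability of observing at
least k annotated genes in a query of size n drawn from a background of N
genes of which K carry the annotation.  Used both for GO-style gene-set
enrichment (via GMT annotations) and, through the tfbs module, for
transcription-factor binding-site enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetAnnotation

__all__ = ["hypergeom_upper", "bh_fdr", "enrich_sets"]

DEFAULT_TERM_SIZE_RANGE = (3, 2000)


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"invalid hypergeometric bounds: N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_sets(
    query: set[str],
    background: set[str],
    annotation: GeneSetAnnotation,
    fdr_cutoff: float = 0.05,
    term_size_range: tuple[int, int] = DEFAULT_TERM_SIZE_RANGE,
) -> pd.DataFrame:
    """Over-representation of annotation terms in a query gene set.

    Term members are intersected with the background first; terms are
    tested only when the intersected size lies in ``term_size_range`` and
    the query overlap is >= 1.  BH adjustment runs across all tested terms;
    the ``significant`` column flags fdr < ``fdr_cutoff``.  Output is
    sorted by ascending p-value.
    """
    if not query:
        raise ValueError("empty query set")
    if not background:
        raise ValueError("empty background set")
    stray = query - background
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:5]}")

    N = len(background)
    n = len(query)
    lo, hi = term_size_range
    rows = []
    for term_id, (term_name, members) in annotation.terms.items():
        in_bg = set(members) & background
        K = len(in_bg)
        if not lo <= K <= hi:
            continue
        k = len(in_bg & query)
        if k < 1:
            continue
        rows.append((term_id, term_name, N, K, n, k, hypergeom_upper(N, K, n, k)))

    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "N", "K", "n", "k", "p_value"]
    )
    if len(table):
        table["fdr"] = bh_fdr(table["p_value"].to_numpy())
        table["significant"] = table["fdr"] < fdr_cutoff
        table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table
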