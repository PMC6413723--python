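"""qRT-PCR relative quantification (2^-ddCt) and RNA-seq concordance.

Ct values are normalized to a reference gene (Rpl7 in the motivating
experiment) per sample; the fold change of condition B over A is
``2**(-ddCt)``.  Concordance between platforms is the Pearson correlation
of paired log2 fold changes with the exact t-based two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ddct_fold_change", "concordance", "concordance_from_r", "ConcordanceResult"]

DEFAULT_REFERENCE_GENE = "Rpl7"


@dataclass
class ConcordanceResult:
    n: int
    r: float
    p_value: float
    per_gene: pd.DataFrame  # gene_id, log2fc_rnaseq, log2fc_qpcr


def _validate_ct(ct: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    required = {"sample_id", "condition", "gene_id", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    vals = ct["ct"].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("Ct values must be finite")
    if ((vals <= 0) | (vals >= 45)).any():
        raise ValueError("Ct values must lie in (0, 45) cycles")
    if ct["condition"].nunique() != 2:
        raise ValueError("Ct table must contain exactly two conditions")
    # technical replicates within a sample are averaged on the Ct scale
    return (
        ct.groupby(["sample_id", "condition", "gene_id"], sort=False, as_index=False)["ct"]
        .mean()
    )


def ddct_fold_change(
    ct: pd.DataFrame,
    gene: str,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
) -> float:
    """Fold change of ``gene`` (condition B over A) by the 2^-ddCt method.

    dCt = Ct_gene - Ct_ref per sample; ddCt = mean dCt(B) - mean dCt(A);
    fold change = 2**(-ddCt).  Condition order follows first appearance in
    the table.  A sample measuring the gene but missing the reference is an
    error naming the sample.
    """
    ct = _validate_ct(ct, reference_gene)
    conds = list(dict.fromkeys(ct["condition"]))
    ref = ct[ct["gene_id"] == reference_gene].set_index("sample_id")["ct"]
    tgt = ct[ct["gene_id"] == gene]
    if tgt.empty:
        raise ValueError(f"gene {gene!r} not present in Ct table")

    dct_by_cond: dict[str, list[float]] = {c: [] for c in conds}
    for _, row in tgt.iterrows():
        sample = row["sample_id"]
        if sample not in ref.index:
            raise ValueError(f"reference gene missing in sample {sample!r}")
        dct_by_cond[row["condition"]].append(row["ct"] - ref[sample])
    for c in conds:
        if not dct_by_cond[c]:
            raise ValueError(f"gene {gene!r} not measured in condition {c!r}")
    ddct = float(np.mean(dct_by_cond[conds[1]]) - np.mean(dct_by_cond[conds[0]]))
    return float(2.0 ** (-ddct))


def concordance_from_r(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation from (r, n) alone.

    Uses the exact null distribution: t = r*sqrt(n-2)/sqrt(1-r^2) on n-2
    degrees of freedom.  For |r| = 1 the smallest positive float is
    returned rather than 0.
    """
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if not -1 <= r <= 1:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return float(np.nextafter(0.0, 1.0))
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def concordance(fc_rnaseq: dict[str, float], fc_qpcr: dict[str, float]) -> ConcordanceResult:
    """Pearson concordance of log2 fold changes across shared genes.

    Both inputs map gene -> fold change (> 0).  Requires >= 3 shared genes
    and nonzero variance in both log2 vectors.
    """
    shared = [g for g in fc_rnaseq if g in fc_qpcr]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    x = np.array([fc_rnaseq[g] for g in shared], dtype=float)
    y = np.array([fc_qpcr[g] for g in shared], dtype=float)
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("fold changes must be > 0")
    lx, ly = np.log2(x), np.log2(y)
    if lx.var() == 0 or ly.var() == 0:
        raise ValueError("zero variance in a fold-change vector")
    r = float(np.corrcoef(lx, ly)[0, 1])
    p = concordance_from_r(r, len(shared))
    per_gene = pd.DataFrame(
        {"gene_id": shared, "log2fc_rnaseq": lx, "log2fc_qpcr": ly}
    )
    return ConcordanceResult(n=len(shared), r=r, p_value=p, per_gene=per_gene)
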