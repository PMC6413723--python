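"""Cross-species comparison of DE gene lists through an ortholog map.

Mouse and human DE tables (already filtered to DE-called genes) are joined
through a strictly one-to-one ortholog table; shared pairs are classified
into four concordance categories from the signs of their log2 fold
changes: consistently down, consistently up, mouse-down/human-up and
mouse-up/human-down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["overlap", "classify", "OverlapResult", "CATEGORIES"]

CATEGORIES = (
    "consistent_down",
    "consistent_up",
    "mouse_down_human_up",
    "mouse_up_human_down",
)


@dataclass
class OverlapResult:
    shared: pd.DataFrame          # mouse_gene, human_gene, mouse_log2fc, human_log2fc
    mouse_only: list[str]
    human_only: list[str]


def overlap(
    mouse_de: pd.DataFrame,
    human_de: pd.DataFrame,
    orthologs: pd.DataFrame,
) -> OverlapResult:
    """Split DE genes into shared ortholog pairs and species-exclusive sets.

    The ortholog map must be one-to-one; many-to-many rows are rejected
    with the offending genes listed.  ``|mouse DE| = |shared| + |mouse_only|``
    and likewise for human.
    """
    for col, df, label in (
        ("mouse_gene", orthologs, "mouse"),
        ("human_gene", orthologs, "human"),
    ):
        dup = df.loc[df[col].duplicated(), col]
        if len(dup):
            raise ValueError(
                f"ortholog map is not one-to-one on the {label} side: {sorted(set(dup))[:10]}"
            )
    for df, label in ((mouse_de, "mouse"), (human_de, "human")):
        if df["gene_id"].duplicated().any():
            raise ValueError(f"duplicate gene ids in {label} DE table")

    m2h = dict(zip(orthologs["mouse_gene"], orthologs["human_gene"]))
    mouse_fc = dict(zip(mouse_de["gene_id"], mouse_de["log2fc"]))
    human_fc = dict(zip(human_de["gene_id"], human_de["log2fc"]))

    rows = []
    for mg in mouse_de["gene_id"]:
        hg = m2h.get(mg)
        if hg is not None and hg in human_fc:
            rows.append((mg, hg, mouse_fc[mg], human_fc[hg]))
    shared = pd.DataFrame(
        rows, columns=["mouse_gene", "human_gene", "mouse_log2fc", "human_log2fc"]
    )
    shared_m = set(shared["mouse_gene"])
    shared_h = set(shared["human_gene"])
    mouse_only = [g for g in mouse_de["gene_id"] if g not in shared_m]
    human_only = [g for g in human_de["gene_id"] if g not in shared_h]
    return OverlapResult(shared=shared, mouse_only=mouse_only, human_only=human_only)


def classify(shared: pd.DataFrame) -> tuple[dict[str, int], pd.DataFrame]:
    """Four-way concordance classification of shared ortholog pairs.

    Direction comes from the sign of the already-DE-called log2fc; a zero
    log2fc is an error (direction undefined).  Returns the category counts
    (always partitioning the shared set) and the per-pair table with a
    ``category`` column.
    """
    m = shared["mouse_log2fc"].to_numpy(dtype=float)
    h = shared["human_log2fc"].to_numpy(dtype=float)
    if (m == 0).any() or (h == 0).any():
        bad = shared.loc[(m == 0) | (h == 0), "mouse_gene"].tolist()
        raise ValueError(f"zero log2fc (direction undefined) for: {bad[:10]}")
    category = np.where(
        (m < 0) & (h < 0),
        "consistent_down",
        np.where(
            (m > 0) & (h > 0),
            "consistent_up",
            np.where((m < 0) & (h > 0), "mouse_down_human_up", "mouse_up_human_down"),
        ),
    )
    table = shared.copy()
    table["category"] = category
    counts = {c: int((category == c).sum()) for c in CATEGORIES}
    return counts, table
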