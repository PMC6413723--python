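"""Connectivity-map scoring of drug reference profiles against a DE signature.

Each drug is a ranked list of the gene universe (position 1 = most
up-regulated by the drug).  For a query gene set occupying ascending
positions V(1..t) in a list of length n, the KS enrichment score is

    a  = max_j ( j/t - V(j)/n )
    b  = max_j ( V(j)/n - (j-1)/t )
    es = a  if a > b  else  -b

i.e. the signed maximum deviation of the query's cumulative rank
distribution from uniform.  The connectivity score combines the up- and
down-set statistics: zero when both have the same sign, otherwise
ks_up - ks_down, so a drug that pushes the up signature down-list and the
down signature up-list scores negative (signature reversal).  Permutation
p-values draw random disjoint query-set pairs of matched sizes; scaled
scores divide negative and positive scores by their own absolute maxima
across the queried collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ks_enrichment",
    "ks_from_positions",
    "connectivity_score",
    "permutation_p",
    "rank_drugs",
    "ConnectivityResult",
]

logger = logging.getLogger(__name__)


@dataclass
class ConnectivityResult:
    drug_id: str
    ks_up: float
    ks_down: float
    score: float
    scaled_score: float
    perm_p: float


def ks_enrichment(n: int, positions) -> float:
    """KS enrichment score of a query set at 1-based ``positions`` in a
    ranked list of length ``n``.  Positions need not be pre-sorted."""
    v = np.sort(np.asarray(positions, dtype=float))
    t = v.size
    if t == 0:
        raise ValueError("empty query set")
    if v[0] < 1 or v[-1] > n or np.unique(v).size != t:
        raise ValueError("positions must be distinct integers in 1..n")
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a > b else -b


def ks_from_positions(v_sorted: np.ndarray, n: int) -> np.ndarray:
    """Row-wise KS scores for a matrix of ascending positions (n_rows x t)."""
    t = v_sorted.shape[1]
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - v_sorted / n, axis=1)
    b = np.max(v_sorted / n - (j - 1) / t, axis=1)
    return np.where(a > b, a, -b)


def connectivity_score(ks_up: float, ks_down: float) -> float:
    """Same-sign rule: zero if both KS statistics share a sign, else the
    difference ks_up - ks_down.  A zero KS counts as opposite-direction
    (the rule uses a strict product > 0), keeping the score defined."""
    if not (-1 <= ks_up <= 1 and -1 <= ks_down <= 1):
        raise ValueError("KS statistics must lie in [-1, 1]")
    if ks_up * ks_down > 0:
        return 0.0
    return ks_up - ks_down


def _perm_scores(n: int, t_up: int, t_down: int, n_perm: int, rng) -> np.ndarray:
    """Null connectivity scores from random disjoint (up, down) position sets."""
    # random disjoint sets of matched sizes: first t_up + t_down entries of a
    # random permutation of 1..n per draw
    keys = rng.random((n_perm, n))
    idx = np.argsort(keys, axis=1)[:, : t_up + t_down]
    up_pos = np.sort(idx[:, :t_up] + 1, axis=1).astype(float)
    down_pos = np.sort(idx[:, t_up:] + 1, axis=1).astype(float)
    ks_u = ks_from_positions(up_pos, n)
    ks_d = ks_from_positions(down_pos, n)
    scores = np.where(ks_u * ks_d > 0, 0.0, ks_u - ks_d)
    return scores


def permutation_p(
    n: int,
    t_up: int,
    t_down: int,
    observed: float,
    n_perm: int = 1000,
    seed: int = 0,
    null_scores: np.ndarray | None = None,
) -> float:
    """Add-one permutation p-value for a connectivity score.

    ``perm_p = (1 + #{|score_perm| >= |observed|}) / (n_perm + 1)``; the
    null draws random disjoint query pairs of the observed sizes, which is
    exchangeable with shuffling the profile itself.  A precomputed
    ``null_scores`` vector (same n, t_up, t_down) may be supplied.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if t_up + t_down > n:
        raise ValueError("query sets larger than the profile")
    if null_scores is None:
        rng = np.random.default_rng(seed)
        null_scores = _perm_scores(n, t_up, t_down, n_perm, rng)
    exceed = int(np.sum(np.abs(null_scores) >= abs(observed)))
    return (1 + exceed) / (len(null_scores) + 1)


def _positions_of(profile_genes: pd.Series, query: set[str]) -> np.ndarray:
    mask = profile_genes.isin(query).to_numpy()
    return np.flatnonzero(mask) + 1


def rank_drugs(
    profiles: pd.DataFrame,
    up: set[str],
    down: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every drug profile against the (up, down) DE signature.

    ``profiles`` is a long table (drug_id, rank, gene_id).  Query genes
    absent from a profile's universe are dropped for that profile with a
    logged count.  Output rows are sorted by ascending permutation p, ties
    broken by ascending score (most reversing first).  Scaled scores
    normalize negative and positive scores separately by their own absolute
    maxima across the collection; the raw score is always reported.

    The permutation null distribution depends only on (profile length,
    query sizes), so it is computed once per distinct triple and shared
    across profiles — an exact reuse, not an approximation.
    """
    if up & down:
        raise ValueError("up and down query sets must be disjoint")
    if not up or not down:
        raise ValueError("both query sets must be non-empty")

    null_cache: dict[tuple[int, int, int], np.ndarray] = {}
    rows = []
    for drug, grp in profiles.groupby("drug_id", sort=False):
        ranked = grp.sort_values("rank")["gene_id"].reset_index(drop=True)
        n = len(ranked)
        universe = set(ranked)
        up_here = up & universe
        down_here = down & universe
        dropped = (len(up) - len(up_here)) + (len(down) - len(down_here))
        if dropped:
            logger.info("profile %s: dropped %d query gene(s) absent from universe", drug, dropped)
        if not up_here or not down_here:
            raise ValueError(f"profile {drug!r}: a query set has no genes in the universe")

        ks_u = ks_enrichment(n, _positions_of(ranked, up_here))
        ks_d = ks_enrichment(n, _positions_of(ranked, down_here))
        score = connectivity_score(ks_u, ks_d)

        key = (n, len(up_here), len(down_here))
        if key not in null_cache:
            rng = np.random.default_rng([int(seed), n, len(up_here), len(down_here)])
            null_cache[key] = _perm_scores(n, key[1], key[2], n_perm, rng)
        p = permutation_p(n, key[1], key[2], score, n_perm=n_perm, null_scores=null_cache[key])
        rows.append((drug, ks_u, ks_d, score, p))

    table = pd.DataFrame(rows, columns=["drug_id", "ks_up", "ks_down", "score", "perm_p"])
    neg_max = table.loc[table["score"] < 0, "score"].abs().max()
    pos_max = table.loc[table["score"] > 0, "score"].max()
    scaled = np.zeros(len(table))
    neg = table["score"] < 0
    pos = table["score"] > 0
    if neg.any():
        scaled[neg.to_numpy()] = table.loc[neg, "score"] / neg_max
    if pos.any():
        scaled[pos.to_numpy()] = table.loc[pos, "score"] / pos_max
    table["scaled_score"] = scaled
    return (
        table.sort_values(["perm_p", "score"], kind="stable").reset_index(drop=True)
    )
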