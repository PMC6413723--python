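"""PWM promoter scanning and transcription-factor binding-site enrichment.

Motif matrices are converted to log2-odds against a background base model
(uniform 0.25 by default, pseudocount 0.01 per cell before column
normalization).  Every window on both strands is scored and min-max
normalized to a relative score in [0, 1]:

    rel = (S - S_min) / (S_max - S_min)

where S_min/S_max are the minimum/maximum attainable window scores.  Hits
are windows with rel >= cutoff (0.9 in the motivating analysis).  TF
enrichment is the upper-tail hypergeometric test on the number of genes
whose promoter carries at least one hit, run separately for up- and
down-regulated gene sets against the background; TFs at raw p < alpha
(0.01) are reported, with an optional BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import bh_fdr, hypergeom_upper
from .io_formats import PWM, PromoterSet

__all__ = ["ScoredPWM", "score_pwm", "scan_promoter", "scan_set", "tf_enrichment"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_UNIFORM = np.full(4, 0.25)


@dataclass
class ScoredPWM:
    """A PWM prepared for scanning: log2-odds plus attainable score range."""

    pwm: PWM
    log_odds: np.ndarray       # 4 x L
    s_min: float               # sum of column minima
    s_max: float               # sum of column maxima
    background: np.ndarray
    pseudocount: float

    @property
    def tf_name(self) -> str:
        return self.pwm.tf_name

    @property
    def length(self) -> int:
        return self.pwm.length


def score_pwm(
    pwm: PWM,
    background=None,
    pseudocount: float = 0.01,
) -> ScoredPWM:
    """Convert counts to log2-odds and precompute the score range.

    The pseudocount is added to every cell before column normalization;
    ``log_odds[b, i] = log2(freq[b, i] / background[b])``.
    """
    bg = _UNIFORM if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies summing to 1")
    counts = pwm.matrix + pseudocount
    freq = counts / counts.sum(axis=0, keepdims=True)
    lo = np.log2(freq / bg[:, None])
    s_min = float(lo.min(axis=0).sum())
    s_max = float(lo.max(axis=0).sum())
    if not s_max > s_min:
        raise ValueError(f"PWM {pwm.tf_name!r} is uninformative (s_max == s_min)")
    return ScoredPWM(
        pwm=pwm, log_odds=lo, s_min=s_min, s_max=s_max, background=bg, pseudocount=pseudocount
    )


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int8)


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Raw log-odds score of every window; NaN where the window contains N."""
    L = lo.shape[1]
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)  # n_win x L
    padded = np.vstack([lo, np.full((1, L), np.nan)])  # row 4 = N
    per_pos = padded[win, np.arange(L)]
    return per_pos.sum(axis=1)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
    return comp[codes][::-1]


def scan_promoter(
    seq: str,
    spwm: ScoredPWM,
    cutoff: float = 0.9,
    strand: str = "both",
    gene_id: str = "",
) -> pd.DataFrame:
    """Scan one promoter; return hits with rel score >= cutoff.

    Positions are 1-based starts on the forward strand of the supplied
    sequence, for hits on either strand.  Windows containing N are skipped.
    """
    if strand not in ("both", "forward"):
        raise ValueError("strand must be 'both' or 'forward'")
    L = spwm.length
    if len(seq) < L:
        return _empty_hits()
    codes = _encode(seq)
    span = spwm.s_max - spwm.s_min
    rows = []
    fwd = (_window_scores(codes, spwm.log_odds) - spwm.s_min) / span
    for pos in np.flatnonzero(fwd >= cutoff):
        rows.append((gene_id, spwm.tf_name, int(pos) + 1, "+", float(fwd[pos])))
    if strand == "both":
        n = codes.size
        rev = (_window_scores(_revcomp_codes(codes), spwm.log_odds) - spwm.s_min) / span
        for pos in np.flatnonzero(rev >= cutoff):
            # window [pos, pos+L) on the reverse strand starts at forward
            # coordinate n - L - pos (0-based)
            rows.append((gene_id, spwm.tf_name, n - L - int(pos) + 1, "-", float(rev[pos])))
    hits = pd.DataFrame(rows, columns=_HIT_COLUMNS)
    return hits.sort_values(["position", "strand"], kind="stable").reset_index(drop=True)


_HIT_COLUMNS = ["gene_id", "tf_name", "position", "strand", "rel_score"]


def _empty_hits() -> pd.DataFrame:
    return pd.DataFrame(columns=_HIT_COLUMNS)


def _batch_scores(codes2d: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Window scores for a stack of equal-length sequences (m x n_win)."""
    L = lo.shape[1]
    win = np.lib.stride_tricks.sliding_window_view(codes2d, L, axis=1)
    padded = np.vstack([lo, np.full((1, L), np.nan)])
    return padded[win, np.arange(L)].sum(axis=2)


def scan_set(
    promoters: PromoterSet,
    spwms: list[ScoredPWM],
    cutoff: float = 0.9,
    strand: str = "both",
) -> pd.DataFrame:
    """Scan every promoter with every PWM; concatenated hit table.

    Equal-length promoters are scored in one vectorized batch per PWM.
    """
    ids = promoters.gene_ids
    by_len: dict[int, list[str]] = {}
    for gid in ids:
        by_len.setdefault(len(promoters[gid]), []).append(gid)

    out: dict[str, list] = {c: [] for c in _HIT_COLUMNS}
    for seq_len, group in by_len.items():
        codes2d = np.stack([_encode(promoters[g]) for g in group])
        if strand == "both":
            rc = np.stack([_revcomp_codes(codes2d[i]) for i in range(len(group))])
        for spwm in spwms:
            L = spwm.length
            if seq_len < L:
                continue
            span = spwm.s_max - spwm.s_min
            with np.errstate(invalid="ignore"):
                rel = (_batch_scores(codes2d, spwm.log_odds) - spwm.s_min) / span
                gi, pos = np.nonzero(rel >= cutoff)
            out["gene_id"] += [group[i] for i in gi]
            out["tf_name"] += [spwm.tf_name] * len(gi)
            out["position"] += (pos + 1).tolist()
            out["strand"] += ["+"] * len(gi)
            out["rel_score"] += rel[gi, pos].tolist()
            if strand == "both":
                with np.errstate(invalid="ignore"):
                    relr = (_batch_scores(rc, spwm.log_odds) - spwm.s_min) / span
                    gi, pos = np.nonzero(relr >= cutoff)
                out["gene_id"] += [group[i] for i in gi]
                out["tf_name"] += [spwm.tf_name] * len(gi)
                out["position"] += (seq_len - L - pos + 1).tolist()
                out["strand"] += ["-"] * len(gi)
                out["rel_score"] += relr[gi, pos].tolist()
    return pd.DataFrame(out)


def tf_enrichment(
    up_genes: set[str],
    down_genes: set[str],
    background_genes: set[str],
    promoters: PromoterSet,
    spwms: list[ScoredPWM],
    cutoff: float = 0.9,
    alpha: float = 0.01,
    strand: str = "both",
    adjust_bh: bool = False,
    hits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Hypergeometric TFBS enrichment, separately per DE direction.

    A gene counts once per TF if its promoter has any hit (presence /
    absence, regardless of multiplicity).  For each TF and direction set:
    N = |background|, K = background genes with a site, n = |set|,
    k = set genes with a site.  A TF with no sites anywhere has p = 1 and
    is never flagged.  Precomputed ``hits`` (from :func:`scan_set` over the
    same promoters/PWMs/cutoff) may be passed to avoid re-scanning.
    """
    for name, s in (("up", up_genes), ("down", down_genes)):
        stray = s - background_genes
        if stray:
            raise ValueError(f"{name} genes outside background: {sorted(stray)[:5]}")
    missing = [g for g in background_genes if g not in promoters]
    if missing:
        raise ValueError(f"no promoter for background gene {missing[0]!r}")

    if hits is None:
        bg_promoters = PromoterSet({g: promoters[g] for g in sorted(background_genes)})
        hits = scan_set(bg_promoters, spwms, cutoff=cutoff, strand=strand)

    N = len(background_genes)
    rows = []
    for spwm in spwms:
        tf = spwm.tf_name
        with_site = (
            set(hits.loc[hits["tf_name"] == tf, "gene_id"]) & background_genes
        )
        K = len(with_site)
        for direction, gene_set in (("up", up_genes), ("down", down_genes)):
            n = len(gene_set)
            k = len(with_site & gene_set)
            p = 1.0 if K == 0 else hypergeom_upper(N, K, n, min(k, K))
            rows.append((tf, direction, N, K, n, k, p))

    table = pd.DataFrame(
        rows, columns=["tf_name", "direction", "N", "K", "n", "k", "p_value"]
    )
    if adjust_bh:
        for direction in ("up", "down"):
            mask = table["direction"] == direction
            table.loc[mask, "fdr"] = bh_fdr(table.loc[mask, "p_value"].to_numpy())
        table["enriched"] = (table["fdr"] < alpha) & (table["K"] > 0)
    else:
        table["enriched"] = (table["p_value"] < alpha) & (table["K"] > 0)
    return table.sort_values(["direction", "p_value"], kind="stable").reset_index(drop=True)
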