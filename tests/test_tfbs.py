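import itertools

import numpy as np
import pandas as pd
import pytest

from receptseq import enrichment, synthetic, tfbs
from receptseq.io_formats import PWM, PromoterSet

BASES = "ACGT"


def _revcomp(s):
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------- score_pwm

def test_score_pwm_uniform_column_gives_zero_log_odds():
    pwm = PWM("flat", np.full((4, 4), 3.0))
    with pytest.raises(ValueError, match="uninformative"):
        tfbs.score_pwm(pwm)  # min == max: nothing to scan for
    # one informative column next to flat ones: flat columns stay ~0
    mat = np.full((4, 5), 3.0)
    mat[:, 0] = [12.0, 0.0, 0.0, 0.0]
    spwm = tfbs.score_pwm(PWM("onecol", mat))
    np.testing.assert_allclose(spwm.log_odds[:, 1:], 0.0, atol=1e-6)


def test_score_pwm_consensus_limit_log2_four():
    mat = np.zeros((4, 4))
    mat[0] = 1000.0  # all-A consensus columns
    spwm = tfbs.score_pwm(PWM("allA", mat), pseudocount=1e-9)
    np.testing.assert_allclose(spwm.log_odds[0], 2.0, atol=1e-6)


def test_score_pwm_background_validation(simple_pwm):
    with pytest.raises(ValueError, match="background"):
        tfbs.score_pwm(simple_pwm, background=[0.3, 0.3, 0.3, 0.3])


@pytest.mark.parametrize("seed", [0, 1])
def test_score_range_matches_exhaustive_windows(seed):
    rng = np.random.default_rng(seed)
    pwm = PWM("rand", rng.integers(1, 15, size=(4, 5)).astype(float))
    spwm = tfbs.score_pwm(pwm)
    scores = []
    for word in itertools.product(range(4), repeat=5):
        scores.append(sum(spwm.log_odds[b, i] for i, b in enumerate(word)))
    assert spwm.s_min == pytest.approx(min(scores), rel=1e-12)
    assert spwm.s_max == pytest.approx(max(scores), rel=1e-12)


# ------------------------------------------------------------- scan_promoter

def test_scan_consensus_hit_rel_one(simple_pwm):
    spwm = tfbs.score_pwm(simple_pwm)
    seq = "T" * 20 + simple_pwm.consensus() + "T" * 20
    hits = tfbs.scan_promoter(seq, spwm, cutoff=0.9, gene_id="g")
    top = hits.loc[hits["rel_score"].idxmax()]
    assert top["position"] == 21 and top["strand"] == "+"
    assert top["rel_score"] == pytest.approx(1.0)


def test_scan_reverse_complement_strand_and_coordinate(simple_pwm):
    spwm = tfbs.score_pwm(simple_pwm)
    seq = "T" * 20 + _revcomp(simple_pwm.consensus()) + "T" * 20
    hits = tfbs.scan_promoter(seq, spwm, cutoff=0.99, gene_id="g")
    top = hits.loc[hits["rel_score"].idxmax()]
    assert top["strand"] == "-" and top["position"] == 21
    fwd_only = tfbs.scan_promoter(seq, spwm, cutoff=0.99, strand="forward")
    assert len(fwd_only) == 0


def test_scan_windows_with_n_skipped(simple_pwm):
    spwm = tfbs.score_pwm(simple_pwm)
    consensus = simple_pwm.consensus()
    seq = consensus[:3] + "N" + consensus[4:]
    assert len(tfbs.scan_promoter(seq, spwm, cutoff=0.0)) == 0


def test_scan_strand_symmetry(simple_pwm):
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list(BASES), size=300))
    spwm = tfbs.score_pwm(simple_pwm)
    fwd = tfbs.scan_promoter(seq, spwm, cutoff=0.8, gene_id="g")
    rev = tfbs.scan_promoter(_revcomp(seq), spwm, cutoff=0.8, gene_id="g")
    # mirrored positions with flipped strands, same scores
    L = simple_pwm.length
    mirrored = sorted(
        (len(seq) - L - (p - 1) + 1, {"+": "-", "-": "+"}[s], round(r, 9))
        for p, s, r in zip(rev["position"], rev["strand"], rev["rel_score"])
    )
    original = sorted(
        (p, s, round(r, 9))
        for p, s, r in zip(fwd["position"], fwd["strand"], fwd["rel_score"])
    )
    assert mirrored == original


def test_rel_scores_bounded_and_argmax_unique(simple_pwm):
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list(BASES), size=500))
    spwm = tfbs.score_pwm(simple_pwm)
    hits = tfbs.scan_promoter(seq, spwm, cutoff=0.0)
    assert ((hits["rel_score"] >= 0) & (hits["rel_score"] <= 1)).all()
    perfect = hits[np.isclose(hits["rel_score"], 1.0)]
    cons = simple_pwm.consensus()
    for _, h in perfect.iterrows():
        window = seq[h["position"] - 1 : h["position"] - 1 + spwm.length]
        assert window == cons or window == _revcomp(cons)


def test_null_hit_probability_bounded():
    """An informative 8-mer at cutoff 0.9 hits few 1 kb random promoters."""
    rng = np.random.default_rng(12)
    mat = np.ones((4, 8))
    mat[rng.integers(0, 4, size=8), np.arange(8)] = 20.0
    spwm = tfbs.score_pwm(PWM("tight", mat))
    promoters = synthetic.gen_promoters(200, length=1000, seed=12)
    hits = tfbs.scan_set(promoters, [spwm], cutoff=0.9)
    frac = hits["gene_id"].nunique() / 200
    assert frac < 0.5


# ------------------------------------------------------------- tf_enrichment

def test_tf_enrichment_planted_motif_recovered(simple_pwm):
    genes = [f"p{i:03d}" for i in range(1, 301)]
    up = set(genes[:50])
    targets = set(genes[:40])  # 80% of the up set
    promoters = synthetic.gen_promoters(
        300, length=1000, pwm=simple_pwm, target_genes=targets,
        sites_per_target=2, seed=21, genes=genes, consensus=True,
    )
    spwm = tfbs.score_pwm(simple_pwm)
    table = tfbs.tf_enrichment(up, set(genes[50:80]), set(genes), promoters, [spwm])
    row = table.set_index(["tf_name", "direction"]).loc[("TF_TEST", "up")]
    assert row["p_value"] < 0.01 and row["enriched"]


def test_tf_enrichment_composes_with_hypergeom(simple_pwm):
    genes = [f"p{i:02d}" for i in range(1, 61)]
    promoters = synthetic.gen_promoters(
        60, length=500, pwm=simple_pwm, target_genes=set(genes[:10]),
        sites_per_target=1, seed=3, genes=genes, consensus=True,
    )
    spwm = tfbs.score_pwm(simple_pwm)
    table = tfbs.tf_enrichment(
        set(genes[:15]), set(genes[15:30]), set(genes), promoters, [spwm]
    )
    for _, row in table.iterrows():
        expected = (
            1.0 if row["K"] == 0
            else enrichment.hypergeom_upper(row["N"], row["K"], row["n"], row["k"])
        )
        assert row["p_value"] == pytest.approx(expected, rel=1e-12)


def test_tf_enrichment_zero_site_tf_never_reported(simple_pwm):
    promoters = PromoterSet({f"g{i}": "AC" * 25 for i in range(10)})
    mat = np.ones((4, 6))
    mat[3] = 30.0  # all-T consensus: no ACAC... window (either strand) nears 0.9
    spwm = tfbs.score_pwm(PWM("absent", mat))
    table = tfbs.tf_enrichment(
        {"g0", "g1"}, {"g2"}, {f"g{i}" for i in range(10)}, promoters, [spwm]
    )
    assert (table["p_value"] == 1.0).all()
    assert not table["enriched"].any()


def test_tf_enrichment_missing_promoter_named(simple_pwm):
    promoters = PromoterSet({"g0": "ACGT" * 30})
    with pytest.raises(ValueError, match="g1"):
        tfbs.tf_enrichment(
            {"g0"}, set(), {"g0", "g1"}, promoters, [tfbs.score_pwm(simple_pwm)]
        )
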