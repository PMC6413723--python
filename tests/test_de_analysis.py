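import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from receptseq import de_analysis as de
from receptseq.io_formats import ExpressionMatrix
from receptseq.synthetic import SynthSpec, gen_expression


# -------------------------------------------------------------- fold_change

def test_fold_change_hand_arithmetic():
    fc, l2 = de.fold_change(10, 40, epsilon=0.5)
    assert fc == pytest.approx(40.5 / 10.5)
    assert l2 == pytest.approx(np.log2(40.5 / 10.5))


@pytest.mark.parametrize("x", [0.0, 1.0, 123.4])
def test_fold_change_identity_and_degenerate(x):
    fc, l2 = de.fold_change(x, x, epsilon=0.5)
    assert fc == 1.0 and l2 == 0.0


def test_fold_change_antisymmetry_and_errors():
    _, l2 = de.fold_change(3, 17, epsilon=0.5)
    _, l2_swap = de.fold_change(17, 3, epsilon=0.5)
    assert l2 == pytest.approx(-l2_swap)
    with pytest.raises(ValueError):
        de.fold_change(-1, 5, epsilon=0.5)
    with pytest.raises(ValueError):
        de.fold_change(1, 5, epsilon=0)


# ------------------------------------------------------------------ welch_t

def test_welch_t_matches_direct_formula():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    # independent evaluation: Welch t and Satterthwaite df computed by hand
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(va / 3 + vb / 3)
    df = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
    assert t == pytest.approx(-3.6742, abs=1e-4)
    assert df == pytest.approx(4.0)
    expected = 2 * stats.t.sf(abs(t), df)
    assert de.welch_t(a, b) == pytest.approx(expected, rel=1e-12)
    assert de.welch_t(a, b) == pytest.approx(0.02131, abs=2e-5)


def test_welch_t_symmetry_and_conventions():
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=5), rng.normal(1, 1, size=5)
    assert de.welch_t(a, b) == de.welch_t(b, a)
    g = [2.0, 2.0, 2.0]
    assert de.welch_t(g, g) == 1.0
    assert de.welch_t(g, [3.0, 3.0, 3.0]) == 0.0
    with pytest.raises(ValueError):
        de.welch_t([1.0], [1.0, 2.0])


# ------------------------------------------------------------------ call_de

def _matrix(rows: dict[str, tuple[list, list]]) -> ExpressionMatrix:
    samples = ["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"]
    vals = pd.DataFrame(
        {g: list(a) + list(b) for g, (a, b) in rows.items()}, index=samples
    ).T
    return ExpressionMatrix(vals, pd.Series(["A"] * 3 + ["B"] * 3, index=samples))


def test_call_de_cutoffs_strict():
    m = _matrix(
        {
            # fc = (7.5+0.5)/(1.5+0.5) = 4 > 2, constant groups -> p=0: up
            "up": ([1.5] * 3, [7.5] * 3),
            # fc = (3.5+0.5)/(1.5+0.5) = 2.0 exactly: unchanged under strict >
            "edge": ([1.5] * 3, [3.5] * 3),
            # reciprocal fc 4: down
            "down": ([7.5] * 3, [1.5] * 3),
            "flat": ([5.0, 5.1, 4.9], [5.0, 5.1, 4.9]),
        }
    )
    table = de.call_de(m).set_index("gene_id")
    assert table.loc["up", "direction"] == "up"
    assert table.loc["edge", "fold_change"] == pytest.approx(2.0)
    assert table.loc["edge", "direction"] == "unchanged"
    assert table.loc["down", "direction"] == "down"
    assert table.loc["flat", "direction"] == "unchanged"


def test_call_de_all_zero_gene_kept_unchanged():
    m = _matrix({"z": ([0.0] * 3, [0.0] * 3), "x": ([1, 2, 3], [9, 10, 11])})
    row = de.call_de(m).set_index("gene_id").loc["z"]
    assert row["direction"] == "unchanged" and row["p_value"] == 1.0
    assert row["fold_change"] == 1.0


def test_call_de_label_swap_symmetry():
    matrix, _ = gen_expression(SynthSpec(seed=5, n_genes=200, n_up=30, n_down=30))
    fwd = de.call_de(matrix)
    swapped = ExpressionMatrix(
        matrix.values[matrix.samples_of("day4") + matrix.samples_of("day3")],
        matrix.condition_of_sample,
    )
    rev = de.call_de(swapped)
    assert set(fwd.loc[fwd["direction"] == "up", "gene_id"]) == set(
        rev.loc[rev["direction"] == "down", "gene_id"]
    )
    np.testing.assert_allclose(fwd["p_value"], rev["p_value"], rtol=1e-10)


def test_call_de_counts_conserved_and_monotone():
    matrix, _ = gen_expression(SynthSpec(seed=6, n_genes=300, n_up=40, n_down=40))
    strict = de.call_de(matrix, fc_cutoff=2.0, p_cutoff=0.05)
    assert strict["direction"].value_counts().sum() == 300
    for fc_cut, p_cut in [(1.5, 0.05), (2.0, 0.2), (1.5, 0.2)]:
        relaxed = de.call_de(matrix, fc_cutoff=fc_cut, p_cutoff=p_cut)
        assert set(strict.loc[strict["direction"] != "unchanged", "gene_id"]) <= set(
            relaxed.loc[relaxed["direction"] != "unchanged", "gene_id"]
        )


def test_call_de_bh_variant_is_more_conservative():
    matrix, _ = gen_expression(SynthSpec(seed=7, n_genes=300, n_up=40, n_down=40))
    raw = de.call_de(matrix, adjust="none")
    bh = de.call_de(matrix, adjust="bh", alpha=0.01)
    assert (bh["direction"] != "unchanged").sum() <= (raw["direction"] != "unchanged").sum()
    assert (bh["q_value"] >= raw["p_value"] - 1e-15).all()


# ------------------------------------------------------------- cluster_order

def brute_force_upgma(d: np.ndarray):
    """Independent UPGMA recursion on a dense distance matrix.

    Returns merge heights in merge order (average inter-cluster distance).
    """
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
            if best is None or dist < best[0] - 1e-12:
                best = (dist, i, j)
        dist, i, j = best
        heights.append(dist)
        clusters[i] = clusters[i] + clusters.pop(j)
    return heights


def test_cluster_order_matches_brute_force_upgma():
    rng = np.random.default_rng(11)
    rows = rng.normal(size=(6, 8))
    df = pd.DataFrame(rows, index=[f"g{i}" for i in range(6)])
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(rows, metric="correlation"))
    expected = brute_force_upgma(d)
    z = linkage(pdist(rows, metric="correlation"), method="average")
    np.testing.assert_allclose(sorted(z[:, 2]), sorted(expected), rtol=1e-10)
    order, _ = de.cluster_order(df)
    assert sorted(order) == sorted(df.index)


def test_cluster_order_identical_rows_adjacent_and_negation_last():
    base = np.array([1.0, 2.0, 3.0, 4.0])
    df = pd.DataFrame(
        {"s1": base, "s2": base * 2, "s3": -base, "s4": [4.0, 1.0, 3.0, 2.0]}
    ).T
    df.index = ["a", "a_copy", "neg", "mid"]
    order, _ = de.cluster_order(df)
    ia, ib = order.index("a"), order.index("a_copy")
    assert abs(ia - ib) == 1  # distance 0, merged first -> adjacent leaves


def test_cluster_order_drops_zero_variance_and_errors():
    df = pd.DataFrame(
        {"g1": [1.0, 2.0, 3.0], "g2": [5.0, 5.0, 5.0], "g3": [3.0, 1.0, 2.0]}
    ).T
    order, _ = de.cluster_order(df)
    assert "g2" not in order and len(order) == 2
    flat = pd.DataFrame({"g1": [1.0, 1.0], "g2": [2.0, 2.0]}).T
    with pytest.raises(ValueError):
        de.cluster_order(flat)
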