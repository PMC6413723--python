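"""Seeded generators for synthetic pipeline inputs.

Each generator is a pure function of its arguments (including the seed):
the same call yields bitwise-identical output.  Per-component random
sub-streams are derived from the bundle seed with fixed offsets, so that a
change in the number of draws made by one component cannot perturb another.

The generators plant known structure (DE direction labels, motif instances,
high-degree nodes, a signature-reversing drug, concordance categories, fold
changes) that the consuming analysis modules are expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, InteractionNetwork, PromoterSet, PWM

__all__ = [
    "SynthSpec",
    "gen_expression",
    "gen_promoters",
    "gen_network",
    "gen_drug_profiles",
    "gen_species_pair",
    "gen_ct_values",
]

_BASES = np.array(["A", "C", "G", "T"])

# fixed offsets deriving per-component sub-streams from one bundle seed
_STREAM = {
    "expression": 11,
    "promoters": 23,
    "network": 37,
    "profiles": 53,
    "species": 71,
    "ct": 89,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[component]])


@dataclass
class SynthSpec:
    """Design of a synthetic two-condition expression experiment.

    ``log2_effect`` is the planted |log2 fold change| of DE genes;
    ``noise_sd`` is per-sample Gaussian noise on the log2 scale.
    """

    seed: int
    n_genes: int = 1000
    n_up: int = 316
    n_down: int = 225
    log2_effect: float = 2.0
    reps_per_condition: int = 3
    noise_sd: float = 0.25
    conditions: tuple[str, str] = ("day3", "day4")

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down must not exceed n_genes")
        if self.reps_per_condition < 2:
            raise ValueError("reps_per_condition must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def gene_ids(n: int, prefix: str = "g") -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def gen_expression(spec: SynthSpec) -> tuple[ExpressionMatrix, pd.Series]:
    """Simulate a two-condition expression matrix with planted DE genes.

    Baseline log2 means are uniform in [3, 10]; the first ``n_up`` genes are
    shifted by +log2_effect and the next ``n_down`` by -log2_effect in
    condition B.  Observed abundance is ``2**(mean + N(0, noise_sd))`` per
    sample.  Returns the matrix and per-gene truth labels
    (``up``/``down``/``unchanged``, describing condition B vs A).
    """
    rng = _rng(spec.seed, "expression")
    genes = gene_ids(spec.n_genes)
    base = rng.uniform(3.0, 10.0, size=spec.n_genes)
    shift = np.zeros(spec.n_genes)
    shift[: spec.n_up] = spec.log2_effect
    shift[spec.n_up : spec.n_up + spec.n_down] = -spec.log2_effect

    r = spec.reps_per_condition
    cond_a, cond_b = spec.conditions
    samples = [f"{cond_a}_r{i + 1}" for i in range(r)] + [f"{cond_b}_r{i + 1}" for i in range(r)]
    means = np.concatenate(
        [np.tile(base[:, None], (1, r)), np.tile((base + shift)[:, None], (1, r))], axis=1
    )
    noise = rng.normal(0.0, spec.noise_sd, size=means.shape)
    values = np.exp2(means + noise)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        condition_of_sample=pd.Series([cond_a] * r + [cond_b] * r, index=samples),
    )
    truth = pd.Series("unchanged", index=genes, name="direction")
    truth.iloc[: spec.n_up] = "up"
    truth.iloc[spec.n_up : spec.n_up + spec.n_down] = "down"
    truth.attrs["seed"] = spec.seed
    matrix.values.attrs["seed"] = spec.seed
    return matrix, truth


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def gen_promoters(
    n_genes: int,
    length: int = 1000,
    pwm: PWM | None = None,
    target_genes: set[str] | None = None,
    sites_per_target: int = 1,
    seed: int = 0,
    consensus: bool = False,
    genes: list[str] | None = None,
) -> PromoterSet:
    """Generate promoters with i.i.d. uniform background and planted motifs.

    Each target gene's promoter receives ``sites_per_target`` non-overlapping
    motif instances at random positions on a random strand.  Instances are
    sampled base-by-base from the PWM column frequencies, or are the exact
    consensus when ``consensus=True`` (for tests requiring relative score 1).
    """
    rng = _rng(seed, "promoters")
    ids = genes if genes is not None else gene_ids(n_genes, prefix="p")
    if len(ids) != n_genes:
        raise ValueError("genes list length must equal n_genes")
    targets = set(target_genes or ())
    unknown = targets - set(ids)
    if unknown:
        raise ValueError(f"target genes not in generated set: {sorted(unknown)}")
    if targets and pwm is None:
        raise ValueError("a PWM is required to plant motif instances")
    if pwm is not None and pwm.length > length:
        raise ValueError("PWM longer than promoter")

    seqs: dict[str, str] = {}
    for gid in ids:
        chars = _BASES[rng.integers(0, 4, size=length)]
        if gid in targets:
            L = pwm.length
            placed: list[int] = []
            for _ in range(sites_per_target):
                pos = _place_nonoverlapping(rng, length, L, placed)
                placed.append(pos)
                inst = _sample_instance(rng, pwm, consensus)
                if rng.integers(0, 2) == 1:
                    inst = _revcomp(inst)
                chars[pos : pos + L] = list(inst)
        seqs[gid] = "".join(chars)
    return PromoterSet(seqs)


def _place_nonoverlapping(rng, length: int, L: int, placed: list[int]) -> int:
    for _ in range(1000):
        pos = int(rng.integers(0, length - L + 1))
        if all(pos + L <= q or q + L <= pos for q in placed):
            return pos
    raise ValueError("could not place motif instances without overlap")


def _sample_instance(rng, pwm: PWM, consensus: bool) -> str:
    if consensus:
        return pwm.consensus()
    freq = pwm.frequencies()
    idx = [rng.choice(4, p=freq[:, i]) for i in range(pwm.length)]
    return "".join(_BASES[i] for i in idx)


def gen_network(n_nodes: int, m_attach: int, seed: int = 0) -> InteractionNetwork:
    """Scale-free interaction network by preferential attachment.

    Each new node attaches to ``m_attach`` existing nodes with probability
    proportional to current degree, giving ``m_attach * (n_nodes - m_attach)``
    edges and a heavy-tailed degree distribution.  Combined scores are drawn
    uniform in [0.4, 1.0].
    """
    if not n_nodes > m_attach >= 1:
        raise ValueError("need n_nodes > m_attach >= 1")
    rng = _rng(seed, "network")
    g = nx.barabasi_albert_graph(n_nodes, m_attach, seed=int(rng.integers(2**31)))
    names = gene_ids(n_nodes, prefix="n")
    rows = []
    for a, b in sorted(g.edges()):
        rows.append((names[a], names[b], rng.uniform(0.4, 1.0)))
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "combined_score"])
    return InteractionNetwork(df)


def gen_drug_profiles(
    n_drugs: int,
    n_genes: int,
    up_set: set[str],
    down_set: set[str],
    reverser_id: str,
    effect: float,
    seed: int = 0,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Ranked reference profiles with one planted signature-reversing drug.

    Non-reverser drugs rank the gene universe by i.i.d. uniform scores
    (position 1 = most up-regulated by the drug).  The reverser's scores for
    ``up_set`` genes are lowered and for ``down_set`` genes raised by
    ``effect``, displacing them by about ``effect * n_genes`` ranks; at
    ``effect = 1`` the separation is total.  Returns a long table with
    columns ``drug_id``, ``rank``, ``gene_id``.
    """
    if not 0 < effect <= 1:
        raise ValueError("effect must lie in (0, 1]")
    if up_set & down_set:
        raise ValueError("up_set and down_set must be disjoint")
    rng = _rng(seed, "profiles")
    ids = genes if genes is not None else gene_ids(n_genes)
    if len(ids) != n_genes:
        raise ValueError("genes list length must equal n_genes")
    universe = set(ids)
    if not (up_set <= universe and down_set <= universe):
        raise ValueError("query sets must be subsets of the gene universe")
    gene_arr = np.array(ids)
    up_mask = np.isin(gene_arr, sorted(up_set))
    down_mask = np.isin(gene_arr, sorted(down_set))

    drug_names = [f"drug{j + 1:03d}" for j in range(n_drugs)]
    if reverser_id not in drug_names:
        drug_names[0] = reverser_id

    frames = []
    for drug in drug_names:
        scores = rng.uniform(0.0, 1.0, size=n_genes)
        if drug == reverser_id:
            scores = scores.copy()
            scores[up_mask] -= effect
            scores[down_mask] += effect
        order = np.argsort(-scores, kind="stable")
        frames.append(
            pd.DataFrame(
                {
                    "drug_id": drug,
                    "rank": np.arange(1, n_genes + 1),
                    "gene_id": gene_arr[order],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_species_pair(
    n_shared: int,
    n_consistent_down: int,
    n_consistent_up: int,
    n_mdown_hup: int,
    n_mup_hdown: int,
    n_mouse_only: int,
    n_human_only: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired mouse/human DE tables with planted concordance categories.

    ``n_shared`` must equal the sum of the four category counts.  Returns
    (mouse DE table, human DE table, one-to-one ortholog map); log2fc signs
    encode the planted category, magnitudes are uniform in [1.1, 6] so every
    row clears a 2-fold cutoff.
    """
    cats = (n_consistent_down, n_consistent_up, n_mdown_hup, n_mup_hdown)
    if n_shared != sum(cats):
        raise ValueError(
            f"n_shared ({n_shared}) must equal the sum of the four category counts ({sum(cats)})"
        )
    rng = _rng(seed, "species")

    n_mouse = n_shared + n_mouse_only
    n_human = n_shared + n_human_only
    mouse_genes = gene_ids(n_mouse, prefix="m")
    human_genes = gene_ids(n_human, prefix="h")

    signs_m = np.concatenate(
        [
            -np.ones(n_consistent_down),
            np.ones(n_consistent_up),
            -np.ones(n_mdown_hup),
            np.ones(n_mup_hdown),
            rng.choice([-1.0, 1.0], size=n_mouse_only),
        ]
    )
    signs_h = np.concatenate(
        [
            -np.ones(n_consistent_down),
            np.ones(n_consistent_up),
            np.ones(n_mdown_hup),
            -np.ones(n_mup_hdown),
            rng.choice([-1.0, 1.0], size=n_human_only),
        ]
    )
    mag_m = rng.uniform(1.1, 6.0, size=n_mouse)
    mag_h = rng.uniform(1.1, 6.0, size=n_human)

    mouse = pd.DataFrame(
        {
            "gene_id": mouse_genes,
            "log2fc": signs_m * mag_m,
            "p_value": rng.uniform(1e-8, 0.04, size=n_mouse),
        }
    )
    human = pd.DataFrame(
        {
            "gene_id": human_genes,
            "log2fc": signs_h * mag_h,
            "p_value": rng.uniform(1e-8, 0.04, size=n_human),
        }
    )
    orthologs = pd.DataFrame(
        {
            "mouse_gene": mouse_genes[:n_shared],
            "human_gene": human_genes[:n_shared],
        }
    )
    return mouse, human, orthologs


def gen_ct_values(
    fold_changes: dict[str, float],
    ref_gene: str = "Rpl7",
    base_ct: float = 15.0,
    noise_sd: float = 0.0,
    reps_per_condition: int = 3,
    seed: int = 0,
    conditions: tuple[str, str] = ("day3", "day4"),
) -> pd.DataFrame:
    """qPCR Ct table consistent with given per-gene fold changes (B over A).

    The reference gene has constant Ct ``base_ct`` in every sample; each
    target gene's condition-B Ct equals its condition-A Ct minus
    log2(fold_change), plus N(0, noise_sd) per well.
    """
    for g, fc in fold_changes.items():
        if not fc > 0:
            raise ValueError(f"fold change for {g!r} must be > 0, got {fc}")
    if ref_gene in fold_changes:
        raise ValueError("reference gene cannot carry a planted fold change")
    rng = _rng(seed, "ct")
    cond_a, cond_b = conditions
    genes = list(fold_changes)
    baseline = {g: rng.uniform(18.0, 30.0) for g in genes}

    rows = []
    for cond in (cond_a, cond_b):
        for i in range(reps_per_condition):
            sample = f"{cond}_s{i + 1}"
            rows.append((sample, cond, ref_gene, base_ct))
            for g in genes:
                ct = baseline[g]
                if cond == cond_b:
                    ct -= np.log2(fold_changes[g])
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                rows.append((sample, cond, g, ct))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene_id", "ct"])
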