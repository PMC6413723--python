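"""One-call synthetic fixture bundle mirroring the motivating study design.

``generate_bundle`` writes every input the pipeline consumes into a
directory: a 1000-gene, 3 vs 3 expression table with 316 up / 225 down
planted DE genes at |log2FC| = 2 and log2-scale noise SD 0.25; 1-kb
promoters with a planted TF motif in most planted-up genes; a small PWM
library; a 289-node scale-free edge list; 50 ranked drug profiles with one
planted signature reverser; paired mouse/human DE tables with the
115 = 25 + 50 + 20 + 20 shared-gene split plus 1994 human-only genes; and
a 10-gene qPCR Ct table consistent with the realized RNA-seq fold changes.
All randomness derives from one bundle seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .io_formats import PWM, write_fasta, write_gmt, write_pwm_library, write_table, GeneSetAnnotation

__all__ = ["generate_bundle", "default_pwm_library", "PLANTED_TF"]

PLANTED_TF = "TF_PLANTED"


def default_pwm_library(seed: int, n_background_tfs: int = 7) -> list[PWM]:
    """A small PWM library: one informative 8-mer planted TF plus
    seeded random background factors."""
    rng = np.random.default_rng([int(seed), 101])
    # strongly informative planted motif: dominant base 20, others 1
    L = 8
    dominant = rng.integers(0, 4, size=L)
    mat = np.ones((4, L))
    mat[dominant, np.arange(L)] = 20.0
    pwms = [PWM(tf_name=PLANTED_TF, matrix=mat)]
    for i in range(n_background_tfs):
        Lb = int(rng.integers(6, 10))
        counts = rng.integers(0, 12, size=(4, Lb)).astype(float)
        counts[rng.integers(0, 4, size=Lb), np.arange(Lb)] += 8.0
        pwms.append(PWM(tf_name=f"TF_BG{i + 1}", matrix=counts))
    return pwms


def generate_bundle(seed: int, out_dir, n_genes: int = 1000) -> dict:
    """Write the full synthetic input bundle; returns a manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = synthetic.SynthSpec(seed=seed, n_genes=n_genes)

    matrix, truth = synthetic.gen_expression(spec)
    write_table(matrix, out / "expression.tsv", "expression")
    up_genes = list(truth.index[truth == "up"])
    down_genes = list(truth.index[truth == "down"])

    # promoters: plant the motif (2 sites) in 80% of planted-up genes
    pwms = default_pwm_library(seed)
    n_target = int(0.8 * len(up_genes))
    targets = set(up_genes[:n_target])
    promoters = synthetic.gen_promoters(
        n_genes=n_genes,
        length=1000,
        pwm=pwms[0],
        target_genes=targets,
        sites_per_target=2,
        seed=seed,
        genes=list(truth.index),
    )
    write_fasta(promoters, out / "promoters.fasta")
    write_pwm_library(pwms, out / "pwms.txt")

    # gene-set annotation: one term per planted direction plus random terms
    rng = np.random.default_rng([int(seed), 103])
    all_genes = list(truth.index)
    terms = {
        "SET_UP": ("planted up-regulated genes", up_genes),
        "SET_DOWN": ("planted down-regulated genes", down_genes),
    }
    for i in range(8):
        size = int(rng.integers(20, 120))
        terms[f"SET_RND{i + 1}"] = (
            "random background set",
            list(rng.choice(all_genes, size=size, replace=False)),
        )
    write_gmt(GeneSetAnnotation(terms), out / "annotation.gmt")

    net = synthetic.gen_network(289, 2, seed=seed)
    write_table(net, out / "edges.tsv", "edges")

    profiles = synthetic.gen_drug_profiles(
        n_drugs=50,
        n_genes=n_genes,
        up_set=set(up_genes),
        down_set=set(down_genes),
        reverser_id="drug_reverser",
        effect=0.8,
        seed=seed,
        genes=all_genes,
    )
    write_table(profiles, out / "profiles.tsv", "ranked_profile")

    # cross-species pair: shared mouse genes are planted DE genes so the
    # pipeline's own DE calls recover the designed Venn split
    mouse_de, human_de, orthologs = synthetic.gen_species_pair(
        115, 25, 50, 20, 20, 0, 1994, seed=seed
    )
    mouse_ids = down_genes[:25] + up_genes[:50] + down_genes[25:45] + up_genes[50:70]
    rename = dict(zip(mouse_de["gene_id"], mouse_ids))
    mouse_de = mouse_de.assign(gene_id=[rename[g] for g in mouse_de["gene_id"]])
    orthologs = orthologs.assign(
        mouse_gene=[rename[g] for g in orthologs["mouse_gene"]]
    )
    write_table(mouse_de, out / "mouse_de.tsv", "de_table")
    write_table(human_de, out / "human_de.tsv", "de_table")
    write_table(orthologs, out / "orthologs.tsv", "ortholog_map")

    # qPCR: 10 planted genes, Ct values consistent with realized RNA-seq FC
    qpcr_genes = up_genes[:5] + down_genes[:5]
    eps = 0.5
    cond_a, cond_b = matrix.conditions
    ma = matrix.values[matrix.samples_of(cond_a)].mean(axis=1)
    mb = matrix.values[matrix.samples_of(cond_b)].mean(axis=1)
    fc = {g: float((mb[g] + eps) / (ma[g] + eps)) for g in qpcr_genes}
    ct = synthetic.gen_ct_values(fc, ref_gene="Rpl7", noise_sd=0.1, seed=seed)
    write_table(ct, out / "ct.tsv", "ct_values")

    truth_payload = {
        "seed": seed,
        "direction": truth.to_dict(),
        "planted_tf": PLANTED_TF,
        "tf_target_genes": sorted(targets),
        "reverser": "drug_reverser",
        "qpcr_fold_changes": fc,
        "species_counts": {
            "shared": 115,
            "consistent_down": 25,
            "consistent_up": 50,
            "mouse_down_human_up": 20,
            "mouse_up_human_down": 20,
            "human_only": 1994,
        },
    }
    (out / "truth.json").write_text(json.dumps(truth_payload, indent=2))
    return truth_payload
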