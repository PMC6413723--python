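# Methods

`receptseq` re-implements, as a tested library, the analysis chain commonly
applied to two-condition bulk RNA-seq studies of uterine receptivity (mouse
day-3 pre-receptive vs day-4 receptive uterus): differential-expression (DE)
calling, qRT-PCR validation, gene-set and transcription-factor binding-site
(TFBS) enrichment, interaction-network hub detection, connectivity-map (CMap)
drug scoring, and a cross-species comparison against a human DE table. This
note records the models, the defaults, and the choices made where the design
was genuinely open.

## Differential expression

Input is a gene-level abundance matrix (FPKM-like, non-negative) with two
conditions of at least two replicates each. For each gene:

- **Fold change** (condition B over A): `FC = (mean_B + ε) / (mean_A + ε)`
  with pseudo-abundance `ε = 0.5` (configurable) stabilizing zero means. The
  reciprocal ratio is reported alongside as `ratio_magnitude`.
- **p-value**: two-sided Welch t-test on `log2(x + 1)` replicate values with
  Satterthwaite degrees of freedom. The upstream tool chain that produced the
  original abundances does not document a reproducible per-gene test, so the
  package adopts Welch-on-log2 as a conservative, assumption-light standard
  for n = 3 vs 3 designs. Degenerate rows follow a logged convention: two
  constant equal groups give p = 1, constant unequal groups p = 0; all-zero
  genes are reported as `unchanged` with p = 1 rather than dropped, keeping
  the gene universe aligned across downstream modules.
- **Direction**: `up` iff `FC > fc_cutoff` **and** `p < p_cutoff` (strict
  inequalities); `down` by the reciprocal criterion; otherwise `unchanged`.
  Defaults `fc_cutoff = 2`, `p_cutoff = 0.05` on raw p-values. An
  `adjust="bh"` variant thresholds Benjamini–Hochberg q-values instead (the
  FDR < 0.01 convention some heatmap/volcano figures use); raw-p at 0.05 is
  the default because it is the stated selection rule of the motivating
  experimental design.

Heatmap ordering uses agglomerative clustering with distance
`d = 1 − Pearson r` and average linkage (UPGMA), via SciPy's `linkage`;
zero-variance rows are dropped with a warning. A brute-force UPGMA recursion
serves as the oracle in tests.

## qRT-PCR concordance

Relative quantification is the 2^−ΔΔCt method: per sample,
`ΔCt = Ct_gene − Ct_ref` (reference gene `Rpl7` by default; technical
replicate wells are averaged on the Ct scale first); `ΔΔCt` is the difference
of condition means and `FC = 2^−ΔΔCt`. Platform concordance is the Pearson
correlation of paired **log2** fold changes — fold changes in such validation
panels span ~70-fold, so a raw-scale correlation would be leverage-dominated —
with the exact two-sided p from `t = r·√(n−2)/√(1−r²)` on n−2 df. The p-value
depends on (r, n) only, so it is scale-free regardless of that choice.

## Set enrichment

Over-representation of an annotation term is the upper-tail hypergeometric
probability `P(X ≥ k)` for k query hits among n query genes, from a background
of N genes of which K carry the term (SciPy's `hypergeom.sf`, oracle-tested
against exhaustive enumeration for N ≤ 12). Terms are tested when their
background-intersected size lies in [3, 2000] and the query overlap is ≥ 1;
Benjamini–Hochberg adjustment runs across tested terms with significance at
FDR < 0.05. BH is used because the motivating analyses report only "FDR";
it is the field default. Depletion testing is out of scope.

## TFBS scanning and enrichment

Count matrices become log2-odds with pseudocount 0.01 added per cell before
column normalization, against a uniform 0.25 background (both configurable;
the scanning tool the field historically used does not document its
background). Every window on **both** strands is scored and min-max
normalized: `rel = (S − S_min)/(S_max − S_min)` where `S_min`/`S_max` are the
attainable window-score extrema, so `rel = 1` exactly for per-column-argmax
(consensus) windows. Hits require `rel ≥ 0.9`; windows containing `N` are
skipped; coordinates are 1-based forward-strand starts. The min-max
convention is adopted because the alternative (likelihood-ratio
normalization) is not pinned down by any public description of the original
scanner.

TF enrichment is the same hypergeometric machinery with gene-level
presence/absence (a gene counts once per TF regardless of hit multiplicity),
run separately for up- and down-regulated sets against the full background.
TFs at raw p < 0.01 are reported per direction — no cross-TF correction, to
match the stated criterion of the motivating analysis — with an optional BH
flag. A TF with no sites anywhere has p = 1 by convention.

## Network hubs

Edges below the combined-score threshold (default 0.4, unit scale; a
`string999` loader flag divides raw STRING exports by 999) are removed;
"minimum score 0.4" is read as **inclusive** (≥). Degrees are unweighted.
Hubs are nodes with degree strictly greater than mean + 2·SD, using the
sample SD (n−1) — the conservative default where the original tooling is
silent. The scale-free check fits a least-squares line to
`log10 P(D ≥ d)` vs `log10 d` over observed degrees (a survival-function fit
avoids binning artifacts on small networks); it is descriptive only and never
gates hub calls.

## CMap connectivity

For a query set at ascending positions `V(1..t)` in a ranked list of length
n, the KS enrichment score is

    a = max_j ( j/t − V(j)/n ),   b = max_j ( V(j)/n − (j−1)/t ),
    es = a if a > b else −b.

The connectivity score is 0 when `ks_up · ks_down > 0` (same direction) and
`ks_up − ks_down` otherwise; a zero KS counts as opposite-direction so the
score is defined everywhere. Scaled scores divide negative and positive
scores by their own absolute maxima across the queried collection; the raw
score is always reported alongside. Permutation p-values draw `n_perm`
(default 1000) random disjoint query-set pairs of matched sizes and use the
add-one estimator `(1 + #{|s*| ≥ |s|})/(n_perm + 1)` — equivalent under
exchangeability to shuffling the profile, and cheaper. Because the null
depends only on (n, t_up, t_down), `rank_drugs` computes it once per distinct
triple and shares it across profiles (an exact reuse). Drugs are ranked by
ascending permutation p, ties broken by ascending score (most reversing
first).

Note a structural property of the same-sign rule: roughly half of all null
draws score exactly 0, so null permutation p-values carry an atom at 1. They
are uniform below that atom and globally valid (never anti-conservative),
which is what the calibration test asserts; a plain uniformity check would be
wrong by construction.

## Cross-species comparison

Mouse and human DE tables (already filtered to DE-called genes) are joined
through a strictly one-to-one ortholog map — many-to-many rows are rejected
rather than silently multiplying counts. Shared pairs are classified by the
signs of their log2 fold changes into consistently-down, consistently-up,
mouse-down/human-up and mouse-up/human-down; the four counts always partition
the shared set. Direction comes from the sign of the already-called log2FC,
not from re-thresholding, keeping the module independent of species-specific
cutoffs.

## Synthetic data

Generators in `receptseq.synthetic` are pure functions of their arguments
including the seed (bitwise reproducible); per-component sub-streams derive
from the bundle seed by fixed offsets so one component's draw count cannot
perturb another. Defaults mirror the motivating study design:

- **Expression**: 1000 genes, 2 conditions × 3 replicates; baseline log2
  means uniform in [3, 10]; 316 up / 225 down planted genes shifted by
  ±2 log2 units in condition B; per-sample log-normal noise with SD 0.25 on
  the log2 scale. Log-normal rather than negative-binomial because the
  pipeline consumes FPKM-like abundances, not raw counts.
- **Promoters**: 1 kb, i.i.d. uniform background; motif instances sampled
  from PWM column frequencies (consensus on request) planted non-overlapping
  on random strands — by default 2 sites in 80% of planted-up genes.
- **Network**: preferential-attachment growth (289 nodes, m = 2 → 574
  edges), scores uniform in [0.4, 1].
- **Drug profiles**: 50 drugs over the expression universe; uniform random
  scores, with the planted reverser's up-set scores lowered and down-set
  scores raised by `effect = 0.8` (rank displacement ≈ effect × n; total
  separation at effect 1).
- **Species pair**: the 115 = 25 + 50 + 20 + 20 shared split plus 1994
  human-only genes; |log2FC| uniform in [1.1, 6] so every row clears a
  2-fold cutoff.
- **Ct values**: reference gene constant at Ct 15; target baselines uniform
  in [18, 30]; condition-B Ct lowered by log2(FC) plus per-well noise
  (SD 0.1 cycles in the bundle).

The generators deliberately omit library-size effects, batch effects, count
noise, dropout, GC bias and correlated genes. Passing recovery tests
therefore demonstrates that each algorithm recovers the structure it models
under its own assumptions — not that those assumptions hold in any real
uterus dataset.

## Problem sizes and numerics

Recovery simulations use 1000 genes, 50 drug profiles, 1000 permutations and
10 seeds; null-calibration checks use 200 replicates — sizes at which the
binomial noise on the asserted rates is well inside the asserted margins.
Oracle equivalences are exhaustive at small n (hypergeometric N ≤ 12, KS
placements n ≤ 12, UPGMA ≤ 8 rows). Ties in clustering and ranking are
broken by first-occurrence order so outputs are byte-reproducible under a
fixed seed; correlation distances are clipped at 0 against rounding;
hypergeometric tails come from SciPy's stable survival function.

## Known limitations

- The per-gene DE test is a stand-in chosen by this package; results will
  differ from pipelines using count-based models (DESeq2, edgeR) on the same
  data.
- PWM relative scores use the min-max convention; scanners using
  likelihood-ratio normalization will call different borderline hits at the
  same nominal cutoff.
- The permutation null treats profiles as exchangeable rankings; correlated
  reference profiles would make the p-values optimistic.
- Ortholog handling is strictly one-to-one by design; paralog expansions
  must be resolved upstream.
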