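# Methods

## Model and assumptions

`dimorphnet` compares gene regulatory networks between two sample strata
(female and male subjects, per tissue) of a case-only cohort. The core
premise is that strata can share expression *levels* yet differ in
co-expression structure, and that differential co-expression — read
through a motif prior and TF–TF interactions — is evidence of
differential co-*regulation*.

### Network inference

A single network is inferred by message passing over three inputs: a
binary motif prior W⁰ (TF×gene), a TF–TF interaction matrix P⁰ with unit
diagonal, and a gene–gene Pearson co-expression matrix C⁰. All three are
first brought onto a common scale with

  N(M) = (Z_rows(M) + Z_cols(M)) / √2,

using sample (n−1) standard deviations; a zero-variance row or column
contributes 0 and the surviving component enters scaled by 1/√2.
Each iteration then computes, with T(·,·) the continuous Tanimoto
similarity S_ij = d_ij / √(‖X_i‖² + ‖Y_j‖² − |d_ij|), d = XY:

1. responsibility R = T(P, W) and availability A = T(W, C);
2. W ← (1−α) W + α (R + A)/2;
3. P ← (1−α) P + α T(W, Wᵀ) and C ← (1−α) C + α T(Wᵀ, W), where the
   diagonals of the Tanimoto self-similarities are refilled with
   (row sd of off-diagonal entries) × dimension × exp(2αt) at iteration
   t — without this the self-similarity diagonal dominates and freezes
   the co-regulation estimates.

The loop stops when the mean absolute change of W falls below `tol` or
at `max_iter`, in which case the network is returned flagged
unconverged (warning, not an exception). Defaults α = 0.1, tol = 1e-3,
max_iter = 200. The final W is the edge-score matrix, in Z-score-like
units; scores are returned untruncated (negative scores mean "less
support than expected", and downstream filters handle sign).

There is no internal randomness: identical inputs give bit-identical
networks, and permuting gene order permutes the score columns
identically.

### Ensembles and edge comparison

Each sex×tissue ensemble contains one network per jack-knife replicate:
`reps` (default 100) independent draws of k = 10 subjects without
replacement within a replicate (subjects may recur across replicates).
Fixing k equalizes the information content of every network and
regularizes the 1:2 female/male imbalance. Covariate-matched mode draws
the female replicate at random and pairs each female with the unused
male of identical GOLD stage nearest in standardized (age, pack-years)
Euclidean distance, greedily; it requires the male group to cover the
female stage composition replicate-wise.

Edges are compared with an unpaired pooled-variance t-test across the
two ensembles' score columns, BH-corrected over all TF×gene pairs. The
sex-specific edge caller requires |mean difference| ≥ 0.25,
FDR < 1e-5, and a mean score > 0 in at least one ensemble. On the
synthetic studies shipped here these defaults select 1–5% of all
possible edges — a plausible regulatory network density — and
`calibrate_edge_thresholds` walks a difference-cutoff grid to re-target
that band on other data.

An important caveat inherited from the design: networks within an
ensemble share subjects, so the per-edge t-test treats positively
dependent replicates as independent and its significances should be
read as a rank-ordering, not literal error rates. The gene-label and
sex-label permutation controls (below) exist to quantify this.

### Differential targeting

Per network, a gene's in-degree is the sum of its incoming edge scores
and a TF's out-degree the sum of its outgoing scores; in-degree totals
equal out-degree totals per network by construction. Gene-by-network
degree tables (and per-TF gene-by-network edge-weight tables) feed the
same enrichment engine as expression tables:

- rank metric: signal-to-noise (μ_A − μ_B)/(s_A + s_B) with each s
  floored at 0.2·|μ| (0.2 when μ = 0); ties broken by gene id for
  determinism;
- enrichment score: weighted KS running sum (weight p = 1): hits add
  |metric|ᵖ normalized by the total hit mass, misses subtract
  1/(N − N_hits); ES is the extreme of the running sum;
- null: gene-set permutation — `n_perm` random same-size sets scored on
  the fixed ranked list; when the universe is small enough that all
  C(N, k) subsets fit within `n_perm`, the null is enumerated exactly;
- NES = ES / mean same-sign null magnitude; nominal p = same-sign null
  tail; FDR = sign-stratified NES-ratio, floored at 1/(n_perm+1) when
  converted to the signed score;
- signed score: −log₁₀(FDR) for female-enriched sets (positive),
  +log₁₀(FDR) for male-enriched (negative).

Default set-size window 15–500 (the conventional GSEA defaults),
relaxed in the per-TF profiles where panels are small.

### Cross-tissue discordance and the core subnetwork

For each TF, GSEA on its gene-by-network table gives a signed profile
over a fixed gene-set panel per tissue (default: the 5 most
female-enriched plus 5 most male-enriched sets from the gene-level
in-degree comparison; configurable). Per-TF Spearman ρ (average ranks
for ties) between the two tissues' profiles flags TFs with ρ < −0.4 as
discordant — regulators whose sex-specific targeting reverses between
compartments. Constant profiles have undefined ρ (NaN, excluded, with a
warning). The core subnetwork keeps exactly the sex-specific edges from
discordant TFs into genes of the panel, per tissue.

## Motif prior

Promoters are the [−750, +250) window around the TSS in transcription
orientation (BED taken 0-based half-open; minus-strand windows are
reflected and reverse-complemented). Window scores are
log₂ P(S|M)/P(S|B); an N base contributes 0. A 1e-3 pseudocount is
applied to PWM probabilities only where a zero would give −∞, so clean
probability matrices score exactly by their printed values. The log
base is irrelevant to site calls because the null is calibrated in the
same base: the threshold is the empirical (1 − p) quantile of 10⁶
background-window scores (p = 1e-5 by default; fewer than 1e5 samples is
an error, fewer than 1e6 a warning), drawn i.i.d. from background
frequencies or uniformly from a supplied background sequence. A site is
called when its score strictly exceeds the threshold; both strands are
scanned and any passing site makes the binary TF→gene prior edge, so
overlap/strand deduplication is moot downstream. Note the granularity
limit of an empirical null: a motif whose consensus word has background
probability above p (e.g. any length-8 motif under a uniform background,
0.25⁸ ≈ 1.5e-5 > 1e-5) cannot clear the threshold; the shipped fixtures
therefore use length-10 motifs.

TFs encoded on sex chromosomes are retained as regulators even when sex
chromosome genes are excluded as targets: their binding sites in
autosomal promoters still carry regulatory information.

## Expression statistics and QC

All per-gene tests are covariate-free, deliberately matching the
network stage (which cannot model covariates directly): pooled-variance
unpaired t for differential expression, variance-ratio F with two-sided
p = 2·min(tail, 1−tail) for differential variability, BH step-up for
FDR (NaN p-values propagate). The sex check runs a PCA on the marker
(Y-chromosome-like) gene submatrix, splits samples by exact
one-dimensional 2-means on PC1, and flags samples whose recorded sex
differs from their cluster's majority; the intended workflow removes
flagged subjects before analysis. Tests run per tissue.

## The synthetic-data generator

`generate_cohort` emulates the statistical structure of a two-tissue
COPD case cohort on a log-intensity scale: per-gene baselines
N(7, 1); i.i.d. N(0, σ²) noise with σ = 1 by default; 42 female and 84
male subjects with both tissues; 24 bimodal marker genes (female ≈ 4,
male ≈ 8, sd 0.5) following each subject's *true* sex so that planted
mislabels (recorded-sex flips) are detectable; covariates with the
direction of imbalance seen in such cohorts (females younger, fewer
pack-years; GOLD distribution shared) at qualitative magnitudes only.
Planted effects:

- `de_shifts`: mean shifts added to female samples (differential
  expression);
- `dv_factors`: noise-sd multipliers in females (differential
  variance — a factor of 2 gives the variance ratio 4 regime);
- modules: each planted module fixes a sex, tissue, TF set, gene set
  and coupling; in the designated stratum each module TF gets a latent
  activity ~ N(0,1) per sample and each module gene receives
  coupling × Σ activities. Because activities have zero mean, modules
  create differential co-expression with *no* differential expression —
  exactly the regime the network comparison targets. With one TF at
  coupling 1, within-stratum module correlation is 0.5; stronger
  couplings push it toward 1.

`generate_regulatory_truth` produces a Bernoulli motif prior (planted
TF→gene pairs forced present), a symmetric Bernoulli TF–TF matrix with
unit diagonal, and a gene-set collection containing each module's set
plus size-matched decoys sampled without replacement, making enrichment
specificity testable. `generate_promoter_fixtures` writes i.i.d.
background promoters with PWM consensus words planted at recorded
offsets/strands inside the promoter window.

What the generator does *not* emulate: probe-level microarray
artifacts, batch effects, count noise, correlated baseline structure
beyond the planted modules, and realistic effect-size spectra — real
cohorts have diffuse, weak signal where the generator plants one strong
module. Passing recovery tests therefore demonstrates the machinery
identifies the structure it models, not that effect sizes in real
cohorts are detectable at these sample sizes.

## Problem sizes and numerical choices

The shipped experiments run at desk scale, chosen so the full suite
completes in minutes: 300–1000 genes, 10–50 TFs, 8–20 networks per
ensemble for pipeline experiments; the full 130-TF prior and
100-network ensembles are exercised at reduced gene counts. Edge scores
are float64 throughout; Tanimoto denominators of exactly zero (possible
only when the dot product is zero) yield similarity 0; constant rows in
clustering get correlation 0 (distance 1) with a warning; identical
ensembles give t = 0, p = 1 per edge by the zero-variance convention.

## Known limitations

- **Ensemble pseudo-replication.** Jack-knife networks share subjects;
  per-edge and per-degree significances are anticonservative and should
  be ranked, not believed literally.
- **Permutation-control leakage.** A *single* global sex-label
  permutation retains both a hypergeometric residual of true-sex
  composition between the permuted groups and an uneven split of
  subject-specific module activities. Both residuals are constant
  across all replicates of the permuted ensembles, and the set-level
  enrichment statistic aggregates the resulting coherent shift over an
  entire planted module — so with a strong planted module the permuted
  control can still flag that module as differentially targeted, even
  when the permutation is balanced by construction. The edge-count
  comparison is far less sensitive to this and the gene-label
  permutation control does not suffer from it (it destroys the
  prior↔expression correspondence outright). In real cohorts with
  diffuse signal the sex-permutation control behaves as intended; with
  concentrated synthetic signal, interpret it via edge counts.
- **PANDA variant.** Published message-passing implementations differ
  in normalization and diagonal details; this package fixes one
  variant. Single-network edge scores differ across variants; whether
  ensemble-level *differential* conclusions are robust to the variant
  is a worthwhile robustness experiment, not an assumption made here.
- The covariate-matched sampler is greedy (stage-exact, nearest
  age/pack-years) and requires the larger group to cover the smaller
  group's stage composition in every replicate.
- Promoter scanning covers the fixed window only; no genome-wide
  scanning, motif clustering, or TF-family disambiguation.
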