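# dimorphnet

Sex-specific gene regulatory network ensembles for case-only cohort
transcriptomics.

Many diseases — chronic obstructive pulmonary disease (COPD) prominently —
progress differently in men and women while showing almost no autosomal
differential *expression* between the sexes. `dimorphnet` implements the
network-level alternative: infer an *ensemble* of message-passing
regulatory networks per sex and tissue from jack-knifed subject subsets,
then test where the two ensembles disagree — at individual TF→gene edges,
at per-gene "targeting" (in-degree), and at the level of functionally
related gene sets. It is aimed at computational biologists comparing
regulatory network structure between sample strata (sexes, tissues,
disease grades) when per-gene differential expression is uninformative.

## The method

1. **Motif prior.** Promoter windows ([−750, +250) bp around each TSS)
   are scanned with TF position weight matrices. A window S scores
   log₂ P(S|M)/P(S|B) against background B; significance is calibrated
   empirically from 10⁶ background windows and sites with p < 10⁻⁵
   become edges of the binary TF×gene prior W⁰.
2. **Message passing.** Starting from W⁰, a TF–TF interaction network P
   and a gene–gene co-expression network C, each iteration computes a
   *responsibility* R = T(P, W) and an *availability* A = T(W, C)
   (T = continuous Tanimoto similarity) and updates
   W ← (1−α)W + α(R+A)/2, with P and C re-estimated from W.
   The converged W holds an edge score Z⁽ⁿ⁾ᵢⱼ for every TF i and gene j.
3. **Jack-knife ensembles.** For each sex × tissue group, 100 random
   10-subject subsets (optionally covariate-matched across sexes on GOLD
   stage, age and pack-years) each yield one network, so every edge has a
   score *distribution* per ensemble.
4. **Differential edges.** Per edge: unpaired pooled t-test between the
   two ensembles' score distributions, BH-corrected. Sex-specific edges
   satisfy |Δmean| ≥ 0.25, FDR < 10⁻⁵, and mean score > 0 in at least
   one ensemble.
5. **Differential targeting.** Gene in-degrees (and TF out-degrees) per
   network form gene-by-network tables; a from-scratch weighted-KS GSEA
   with gene-set permutation scores each gene set, reported as signed
   −log₁₀(FDR) (positive = female-enriched).
6. **Disease-specific regulators.** Per-TF signed-significance profiles
   over a panel of gene sets are compared between tissues by Spearman ρ;
   TFs with ρ < −0.4 reverse their sex-specific targeting between
   compartments. Their sex-specific edges into the panel's genes form
   the core subnetwork.

A first-class synthetic-data module generates cohorts with the exact
statistical structure this analysis assumes — bimodal Y-marker genes,
near-null autosomal differential expression, differentially *variable*
genes, and sex/tissue-restricted co-regulation modules driven by latent
TF activities — so the full pipeline is testable without any download.

## Worked example

```python
import pandas as pd
import dimorphnet as dn

# a 42 F / 84 M sputum cohort with one female-only co-regulation module
cohort, truth = dn.simulate_study(
    seed=1, n_genes=300, n_tfs=15, n_female=42, n_male=84,
    tissues=("sputum",), module_specs=(("F", "sputum", 4, 40, 1.0),),
    n_decoy_sets=10)
expr = cohort.expression_by_tissue["sputum"].drop(index=cohort.marker_genes)

ens_f, ens_m, edges = dn.sex_comparison(
    expr, cohort.metadata, truth.motif_prior, truth.ppi,
    tissue="sputum", reps=15, k=10, seed=1)
sub_f, sub_m = dn.select_sex_specific_edges(edges)
print(f"female-specific edges: {len(sub_f.edges)}  "
      f"male-specific edges: {len(sub_m.edges)}  of {len(edges)} total")

deg = pd.concat([dn.degree_table(ens_f, "gene_in").values,
                 dn.degree_table(ens_m, "gene_in").values], axis=1)
deg.columns = range(deg.shape[1])
res = dn.gsea(deg, ["F"] * 15 + ["M"] * 15, truth.gene_sets,
              n_perm=1000, seed=1, min_size=10)
print(res[["set", "size", "nes", "fdr_q", "signed_score"]].head(3))
```

Output:

```
female-specific edges: 174  male-specific edges: 20  of 4500 total
              set  size      nes    fdr_q  signed_score
MODULE_0_F_SPUTUM    40 3.283531 0.000000      3.000434
        DECOY_001    40 1.404186 0.147368      0.831596
        DECOY_004    40 1.470657 0.153509      0.813867
```

The planted female module dominates the female-specific edge calls
(174 vs 20; ~4% of all possible edges, inside the expected 1–5% network
density band) and tops the in-degree enrichment at the FDR floor with a
strongly positive (female) signed score, while size-matched decoy sets
stay near zero.

A `dimorphnet` command-line tool wraps the stages for shell use
(`simulate`, `motif-scan`, `build-ensembles`, `diff-edges`, `gsea`); run
`dimorphnet --help`.

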