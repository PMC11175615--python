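# placentome

Analysis pipeline for placental-layer transcriptomics of mother–fetus
cohorts from two populations living at high altitude: which layers of the
placenta diverge in expression between a long-adapted population and recent
migrants, how much of that divergence is specific to male-newborn
placentas, and whether the diverged genes are enriched for targets of
natural selection.

The pipeline covers four analyses, each usable as a library module and
driven end-to-end by the numbered scripts under `analysis/`:

1. **Maternal/fetal origin deconvolution** (`placentome.deconv`). A
   placental sample is a mix of fetal and maternal RNA. At a *fetal-specific*
   SNP — fetus heterozygous A/B, mother homozygous A/A — reads carrying B
   must be fetal, and a het fetus emits B at rate 1/2 per fetal read. The
   pooled allelic ratio over a random tag subset of informative SNPs,
   R = ΣB / (ΣA + ΣB), therefore has expectation f/2 for fetal fraction f;
   averaging R over five tag-subset replicates and inverting gives f̂ =
   clip(2·R_f, 0, 1) (with an R_f/(R_f+R_m) variant available).
2. **Sex-stratified differential expression** (`placentome.de`). Per layer,
   gene counts are modelled NB(s_j·q_gj, α_g) with log link, log q = β₀ +
   β_pop·x + covariates (fetal sex + maternal age combined; maternal age
   only within a sex stratum), median-of-ratios size factors s_j, gene-wise
   Pearson-moment dispersions α_g, and a Wald test of β_pop referred to
   t(n−p); DEGs at Benjamini–Hochberg adjusted p < 0.05 per layer × stratum.
3. **Co-expression modules and trait association** (`placentome.coexpr`).
   WGCNA-style: unsigned adjacency |cor|^β with β from the scale-free
   topology fit, topological overlap, average-linkage clustering with a
   static height cut, eigengene (first PC) summaries, Pearson association
   with population and 11 newborn traits (BW, BPD, FL, GT, PW, PLV, AG,
   AFMD, AFI, FH, FUH). A module is a significantly differential module
   (SDM) when population p < 0.05 and some trait p < 0.05/Meff, where Meff
   is the effective number of independent traits from the trait correlation
   spectrum; hub genes need kME > 0.2, |trait r| > 0.8 and top-3
   intra-module connectivity.
4. **Panel enrichment** (`placentome.enrich`). Permutation test of a
   selection-nominated gene panel against DEG sets: 10,000 draws of
   panel-sized random sets from the expressed universe, empirical
   p = #(overlap ≥ observed)/n_perm, reported as "< 1/n_perm" when no draw
   reaches the observed overlap, with the exact hypergeometric tail as the
   closed-form cross-check.

Because the real cohort is not redistributable, the package ships a
first-class synthetic-cohort generator (`placentome.simulate`) that
reproduces the study design — 69 mother–fetus pairs (35 natives: 16 male /
19 female newborns; 34 migrants: 21 / 13) × 7 placental layers (UC, AN, CN,
CP, VF, VI, VM), layer-specific fetal fractions (UC/VF fully fetal, CN
mostly maternal), a 17,284-gene universe with a strongly male-biased
population-effect architecture, planted co-expression modules driving the
newborn traits, and a 192-gene panel — with full ground truth for recovery
testing.

## Worked example

```sh
python analysis/01_simulate_cohort.py     # writes results/cohort/
python analysis/02_origin_deconvolution.py
python analysis/03_differential_expression.py
python analysis/05_panel_enrichment.py
```

prints (seed 1):

```
       mean_fetal_fraction  mean_abs_error   n
layer
AN                  0.9605          0.0239  69
CN                  0.3089          0.0261  69
...
UC                  0.9858          0.0275  69
overall mean |error| vs truth: 0.0235; 0 samples skipped

combined: 1011 distinct DEGs (5.8% of universe), one-layer share 72.4%, ...
    male: 974 distinct DEGs (5.6% of universe), ...
  female: 416 distinct DEGs (2.4% of universe), ...
male planted-effect recall: 0.93 (536/579)

combined: overlap 20 ... -> empirical p 0.0095 (hypergeometric 0.00903)
    male: overlap 25 ... -> empirical p 0.0002 (hypergeometric 8.27e-05)
  female: overlap 5  ... -> empirical p 0.4947 (hypergeometric 0.495)
```

Reading this: the deconvolution recovers each layer's true mixing fraction
to ~0.02 (chorion correctly identified as maternal-dominant at ~0.31 fetal);
the male stratum yields ~2.3× the female DEG count under the generator's
10× male-biased architecture; and only the male DEG set is enriched for the
planted selection panel — the qualitative pattern the analysis is designed
to detect. `analysis/04_coexpression_modules.py` then identifies SDMs and
hub genes per network, with the planted birth-weight module recovered as a
key module.

The same stages are available as a CLI (`placentome simulate|deconv|de|
modules|enrich|run`) and as one call, `placentome.run_pipeline(config)`,
which writes a single deterministic JSON report.

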