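# igsurv

Associations between intratumorally produced immunoglobulin isotypes and
overall survival in driver-mutation-defined tumor subgroups, from bulk
RNA-seq.

Tumor-infiltrating B cells and plasma cells leave a quantifiable trace in
bulk tumor RNA-seq: the expression of the immunoglobulin heavy-chain
constant-region genes. `igsurv` implements the analysis that links the
*composition* of that trace — which antibody isotype dominates, how focused
(clonal) the underlying B-cell repertoire is, and which IGHV–IGHJ segments
it uses — to patient survival within genetically defined subgroups of a
tumor cohort (mutant/wild-type status of driver genes such as *KRAS*,
*TP53*, *STK11*, *EGFR*, PD-L1-high/low, and transcriptional subtypes).
It is aimed at computational immunologists working with cohorts in the
TCGA mold: a gene-level expression table, a clinical table, somatic
mutation calls, and per-sample CDR3 clonotype tables (MiXCR/VDJtools-style
output).

## The quantities at the core

* **Total antibody expression**
  `IGH = IGHA1 + IGHA2 + IGHG1 + IGHG2 + IGHG3 + IGHG4 + IGHM + IGHD + IGHE`
  (TPM), `IgA = IGHA1 + IGHA2`; isotype proportions such as `IGHG1/IGH`,
  and plasma-to-B-cell ratios such as `IGH/MS4A1` (CD20).
* **Repertoire clonality** of an isotype's CDR3 repertoire, after
  downsampling to 500 reads (multivariate hypergeometric; samples with
  ≤ 500 isotype reads are excluded):
  `clonality = 1 − H / ln S`, with `H = −Σ pᵢ ln pᵢ` the Shannon–Wiener
  index over the `S` clonotypes — 0 for a perfectly even repertoire, 1 for
  a single dominant clone.
* **Survival stratification**: every metric is dichotomized at the median
  within each subgroup; groups are compared with Kaplan–Meier curves, the
  log-rank test (Bonferroni-adjusted across the 12-subgroup screen), and a
  Cox proportional-hazards fit on the high/low indicator (high = 1, so
  HR < 1 means the high group survives longer), optionally adjusted for
  stage, gender, smoking, age, and leukocyte infiltration
  (log₂ CD45 TPM + 1).
* **V–J usage signature**: per-sample read frequencies over
  (IGHV family × IGHJ gene) features (IGHV3-11 and IGHV3-13 both count as
  IGHV3), decomposed by PCA and contrasted between long- and
  short-surviving patients.
* **Synthetic cohorts**: a generator that draws clinical records, driver
  genotypes, isotype composition (Dirichlet × log-normal), mutation burden
  coupled to `IGHG1/IGH` through a Gaussian copula, survival with planted
  hazard ratios, and power-law clonotype repertoires — so every stage of
  the pipeline can be validated against known ground truth.

## Worked example

Simulate a 442-patient cohort with the default planted effects (hazard
ratio 0.36 for `IGHG1/IGH`-high patients within the *KRAS*-mutant stratum,
Spearman ρ = 0.48 between `IGHG1/IGH` and mutation burden), then run the
full analysis:

```bash
igsurv simulate --seed 1 --out cohort/
igsurv run --expression cohort/expression.tsv --clinical cohort/clinical.tsv \
    --mutations cohort/mutations.tsv --clonotypes cohort/clonotypes \
    --out report/ --seed 3
```

`report/survival.tsv` then contains one row per subgroup × metric; the
(KRASmut, IGHG1_over_IGH) row from this exact run reads

```
n_high=62  n_low=63  hazard_ratio=0.3488  adjusted_p=0.0001
```

i.e. the planted protective effect is recovered (HR ≈ 0.35 vs the planted
0.36; HR < 1 = the IGHG1-high half of the KRAS-mutant stratum dies at
roughly a third the rate of the low half), and
`report/burden_correlation.tsv` reports a cohort-wide Spearman
ρ = 0.4665 against the planted 0.48. `report/clonality.tsv` holds the
per-sample downsampled IgG1/IgA clonality values (cohort mean ≈ 0.55 under
the default clone-size skew), and `report/signature.tsv` the V–J usage
loadings and the long-vs-short-survival frequency contrast per feature.

The same stages are available as library calls (`igsurv.simulate`,
`igsurv.isotypes`, `igsurv.repertoire`, `igsurv.survival`,
`igsurv.pipeline`) for use in notebooks.

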