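# scsig

Rare-cell gene-signature enrichment for droplet scRNA-seq, and
signature-index survival stratification for bulk cohorts.

Tumors that look homogeneous in bulk can hide small subpopulations of cells
running a different transcriptional program — for example, rare
Wnt-signature-active cells inside otherwise Wnt-naive medulloblastoma.
`scsig` implements the computational pipeline for finding such cells and for
asking whether the same signature predicts patient outcome in bulk
expression cohorts:

1. **Cell calling** — separate cell-containing droplets from ambient-RNA
   barcodes at the inflection point ("knee") of the sorted barcode
   read-count curve.
2. **Quality control** — drop cells with >30% mitochondrial UMIs, likely
   multiplets whose log library size exceeds 2 MADs above the median, cells
   detecting <500 genes, and genes detected in <5 cells; then
   log-normalize, `ln(1 + c_gi / C_i · 10⁴)`, and center each gene across
   all cells ("relative expression").
3. **Module scoring** — for a gene set *R*, the per-cell score is

   `score(i) = mean_{g∈R} z_gi − mean_{g∈ctrl(R)} z_gi`

   where the control pool draws, for every signature gene, 100 genes from
   the same expression bin (all genes binned into 25 equal-frequency bins of
   mean log-normalized expression). Expression-matched controls remove the
   depth component that a raw average of `z` would carry. A rank-based
   single-sample enrichment scorer (ssGSEA, weighted running sum with
   `rank^0.25` weights) is available as an alternative.
4. **Empirical null and classification** — 100 random gene sets of the same
   size are scored on every cell; the pooled scores define the 5% cutoff
   (empirical 95th percentile). A cell is *enriched* only if its observed
   score strictly surpasses that threshold. Per-sample enrichment
   proportions summarize how common the signature-active state is.
5. **Survival stratification** — per patient, the signature index
   `(Σ_{g∈R} x_g)/n_R` (mean log2 expression of the signature's
   same-direction genes) splits the cohort into High (top ⌈n/3⌉) and Low
   tertile groups, compared by Kaplan–Meier curves, the log-rank
   (Mantel–Cox) test, and univariate/multivariate Cox proportional-hazards
   fits (index + age + metastatic status + subgroup; Efron tie handling).

A seeded synthetic-data module generates droplet barcode pools,
negative-binomial UMI matrices with a planted signature-high subpopulation,
and proportional-hazards survival cohorts, so the whole pipeline is testable
without any download.

## Worked example

Simulate 1000 cells with a 5% planted subpopulation whose 50 signature
genes are up-shifted by `exp(1.5) ≈ 4.5`-fold, then classify cells against
the random-set null:

```sh
$ scsig simulate sc --n-cells 1000 --n-genes 1500 --seed 7 --out sim
wrote 1000 cells x 1500 genes to sim
$ scsig classify --matrix sim --gmt sim/planted_signature.gmt --seed 7 --out calls
classified 1000 cells
$ head -3 calls/enrichment_by_sample.tsv
sample_id	n_cells	n_enriched	proportion	signature
all	1000	67	0.067	PLANTED_SIGNATURE_UP
__total__	1000	67	0.067	PLANTED_SIGNATURE_UP
```

6.7% of cells surpass the 5% cutoff: the planted 5% plus the expected
handful of null-level false positives.

The bulk branch — here the simulated hazard doubles per SD of index, so the
High-index tertile dies faster:

```sh
$ scsig simulate cohort --n-patients 300 --seed 7 --out cohort
wrote 300 patients to cohort
$ scsig survive --expr cohort/expression.tsv --clinical cohort/clinical.tsv \
      --gmt cohort/signature.gmt --out surv
SIM_SIGNATURE_UP: logrank chi2=66.77 p=3.051e-16; medians High=13.5, Low=52.7
```

The full pipeline (`scsig run --config config.yaml`) chains
call-cells → qc → score → classify (and optionally the survival branch),
writing per-stage TSV/JSON artifacts and a manifest with the seed and config
hash needed to reproduce every output. The same functionality is available
as a library (`import scsig`).

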