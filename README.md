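# palnn

Detection of **potentially associated loci (PAL)** for binary traits from
neural-network feature attributions on genome-wide SNP genotypes.

The package implements a full simulation-to-significance pipeline:

1. **Synthetic genotypes** (`palnn.genotypes`) — ternary {-1, 0, 1} dosage
   matrices with block-wise LD from founder haplotype pools; VCF and PLINK
   `.traw`/`.raw` I/O; Pearson-r LD; PCA covariates.
2. **Phenotype simulation** (`palnn.phenosim`) — continuous phenotypes from
   dominant, recessive, two-way and three-way interaction effects (class
   sizes in a 5:5:4:6 ratio), Gaussian noise scaled to the genetic variance
   (factor *k*), and order-statistic binarization to a target case count.
3. **Classifier training** (`palnn.nnmodel`) — a three-layer feedforward
   network (input-mask dropout → affine → dropout → ReLU → affine → dropout
   → GELU → affine → sigmoid) trained with Adam + weight decay, case
   duplication / control halving for class balance, and per-batch Gaussian
   noise on inputs and labels.  Implemented directly on numpy (no GPU
   framework required); training is seed-reproducible on CPU and exposes
   exact input gradients.
4. **Attribution** (`palnn.attribution`) — saliency, integrated gradients
   (midpoint Riemann sum, zero baseline) and permutation importance;
   per-sample L1 normalization and averaging over case samples gives the
   mean attribution score (MAS) per model.
5. **PAL calling** (`palnn.palcall`) — multi-seed MAS matrices, percentile
   thresholds θ (strict 99.99 / relaxed 99.95), exceedance weights,
   AMAS = w·μ, PAL_AMAS / PAL_Common sets, cross-model LD clumping
   (|r| > 0.5 connected components) and >100 kb distance blocks.
6. **Significance** (`palnn.nullsig`) — half-normal null fitted on pooled
   MAS from permuted-label models, AIC/BIC tail-distribution comparison,
   and Monte-Carlo P-values via rank-matched half-normal resampling.
7. **Evaluation** (`palnn.evalbench`) — per-SNP logistic-regression GWAS
   baseline with PC covariates and Bonferroni threshold; ±100 kb TP/FP
   block labeling, precision/recall, and effect-type breakdown.

## CLI

```bash
palnn --stage all --seed 1 --out runs/demo            # full pipeline, defaults
palnn --config my_run.yaml --stage train              # one stage from a config
palnn --stage aggregate --theta relaxed --out runs/demo
```

Six scenario presets (noise scaling k ∈ {1,2,3} × {100, 1000} causal SNPs)
ship under `configs/`, e.g. `palnn --config configs/scenario_k2_n100.yaml`.

Stages: `simulate-genotypes`, `simulate-phenotype`, `train`, `attribute`,
`aggregate`, `null-fit`, `pvalues`, `gwas-lr`, `evaluate`, `all`.  Every
stage writes plain-text artifacts plus a `manifest.json` with per-stage
seeds and output hashes; all randomness derives from the master seed via a
per-stage hash, so reruns are idempotent.  Config keys are documented in
`palnn.pipeline.RunConfig`.

## Notes

- Genotypes must be complete; missing calls are rejected, not imputed.
- The full-scale architecture presets (290,522 → 290 → 29 → 1 with input
  mask p = 0.99; 20,714 → 82 → 8 → 1 with p = 0.50) are available as
  `nnmodel.GENOME_WIDE_PRESET` / `nnmodel.SMALL_PRESET`; for other input
  sizes hidden widths default to h1 = max(8, round(L/1000)),
  h2 = max(4, round(h1/10)).
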