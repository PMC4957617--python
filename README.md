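# mrpipe

A two-sample Mendelian randomization (MR) pipeline for biomarker–disease
analyses, built around the single-SNP Wald (ratio) instrumental-variable
estimator. The package covers the full analysis chain:

1. **`mrpipe.simulate`** — synthetic genotype → biomarker → outcome cohorts
   with known causal structure: Hardy-Weinberg genotype sampling with
   optional LD (Gaussian copula calibrated to target r²), additive per-allele
   biomarker effects (normal or log-normal biomarkers), confounders,
   logistic disease/grade/stage outcomes, exponential survival with optional
   non-additive genotype hazards, and multi-study consortia with
   between-study heterogeneity in the genotype–outcome log-OR.
2. **`mrpipe.qc`** — genotype QC: allele statistics, chi-square and exact
   Hardy-Weinberg tests, composite LD r² from dosages, VCF (GT/DS) and TSV
   dosage I/O.
3. **`mrpipe.instruments`** — instrument validation: per-(SNP, biomarker)
   exposure regressions with partial F and incremental R², the F ≥ 10
   strong/weak classification, Bonferroni-corrected confounder screens, and
   a pleiotropy matrix flagging SNPs strong for multiple biomarkers.
4. **`mrpipe.outcomes`** — per-SNP outcome models: logistic regression with
   cluster-robust sandwich SEs (risk plus case-only grade/stage contrasts)
   and Cox proportional-hazards survival under additive or genotypic coding,
   with a Schoenfeld-residual proportional-hazards check.
5. **`mrpipe.meta`** — inverse-variance fixed-effects pooling with Cochran
   Q/I², DerSimonian-Laird (or REML) random effects, and the model-selection
   rule: fixed effects unless the heterogeneity p ≤ 0.05.
6. **`mrpipe.wald`** — SD-scaled Wald ratio causal estimates with
   first-order delta (default), second-order delta, or Fieller intervals;
   summary-statistic allele harmonization with palindromic-SNP flagging.
7. **`mrpipe.pipeline` / `mrpipe.cli`** — a configured, seeded, logged
   end-to-end run with per-stage TSV/JSON outputs.

## CLI

```sh
# write a 5-study / 2,000-individual / 8-SNP demo consortium + config
mrpipe make-fixture --seed 0 --out demo

# run every stage (simulate, qc, validate, associate, meta, mr)
mrpipe run-all --config demo/config.yaml --out demo_run --seed 1
```

Individual verbs (`simulate`, `qc`, `validate`, `associate`, `meta`, `mr`)
run subsets of the pipeline against the same output directory; a stage whose
upstream output is missing exits nonzero with a dependency error. Outputs:
`qc.tsv`, `instruments.tsv`, `confounder_screen.tsv`, `associations.tsv`,
`meta.tsv`, `mr.json`, `summary.json` and `run.log`. Reruns with the same
config and seed are byte-identical.

## Library example

```python
import numpy as np
from mrpipe import wald_ratio

w = wald_ratio(
    beta_gx=94.78, se_gx=14.4,          # gene -> exposure, ng/mL per allele
    log_gy=np.log(1.05), se_gy=0.0243,  # gene -> outcome, log-OR per allele
    scale_sd=265.0,                     # exposure SD for scaling
)
print(w.estimate, (w.ci_low, w.ci_high))  # causal OR per SD with 95% CI
```
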