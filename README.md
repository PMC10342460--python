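# bariscore

Candidate-SNP association testing and unweighted genetic risk scores for
long-term weight response after bariatric surgery.

The package implements, end to end:

- **`bariscore.simulate`** — a synthetic-cohort generator: genotypes in
  Hardy–Weinberg proportions for a packaged 48-variant / 13-gene candidate
  panel, pre-surgery covariates with configurable marginals (sex, age, BMI,
  T2D, HTN, surgery type), and annual weight trajectories (years 0–8) with a
  nadir followed by partial regain. Genetic effects can be planted on the
  latent phenotypes for calibration and parameter-recovery experiments.
- **`bariscore.phenotypes`** — weight-response phenotype derivation: nadir
  weight (lowest postoperative value, earliest year on ties), %TWL, %EWL
  (ideal weight at BMI 25 kg/m²) and weight regain as a percent of maximum
  weight lost, at the nadir and at the end of follow-up (year 6, closest
  visit within a ±1-year window), plus the strict binary codings
  `%EWL_6y > 50` and `%WR > 20`. Excluded patients are flagged with a reason,
  never dropped silently.
- **`bariscore.association`** — per-SNP association under five inheritance
  models (codominant, dominant, recessive, over-dominant, log-additive), each
  adjusted for the six pre-surgery covariates; genetic-term p by likelihood-
  ratio test; best model by lowest AIC; per-SNP call-rate QC (0.95) and an
  exact Hardy–Weinberg test (`bariscore.hwe`, full conditional enumeration);
  risk-allele calling from the direction of the best-model contrast.
- **`bariscore.risk_score`** — unweighted phenotype-specific risk scores
  (2 points for the risk-allele homozygote, 1 for the heterozygote,
  0 otherwise), patient scoring, and categorization at the cohort's 75th
  percentile (high = strictly above the cutoff).
- **`bariscore.outcome`** — adjusted high-vs-low category effects (mean
  differences or odds ratios with 95% CIs) and pre-surgery profile
  comparisons (Welch's t-test / chi-square).
- **`bariscore.io` / `bariscore.cli`** — VCF v4.2 and a TSV genotype-matrix
  dialect, CSV covariates/trajectories, deterministic result tables, YAML
  run configuration.

## Command line

```sh
# full pipeline from one config: simulate -> phenotypes -> assoc -> score -> evaluate
bariscore all --config config.yaml --out-dir runs/demo

# or stage by stage
bariscore simulate --n 375 --seed 1 --out-dir cohort/
bariscore phenotypes --trajectories cohort/trajectories.csv \
    --covariates cohort/covariates.csv --out phenotypes.csv
bariscore assoc --genotypes cohort/genotypes.tsv --manifest cohort/manifest.tsv \
    --pheno-table phenotypes.csv --covariates cohort/covariates.csv --out-dir assoc/
bariscore score --genotypes cohort/genotypes.tsv --manifest cohort/manifest.tsv \
    --rs-def assoc/rs_definition_twl_6y.json --out scores.csv
bariscore evaluate --scores scores.csv --pheno-table phenotypes.csv \
    --covariates cohort/covariates.csv --out-dir evaluation/
```

Example YAML config:

```yaml
n_patients: 375
seed: 1
alpha: 0.05
effect_spec:
  - rsid: rs10423928
    target: twl_6y
    model: dominant
    beta: -5.0
```

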