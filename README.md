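# metageno

Chromosome-wise multi-task genomic risk prediction.

`metageno` implements a biologically structured SNP representation — allele
states (0/1/2, optional missing state) embedded through a single shared
matrix plus a per-SNP identity term, contextualized by single-head
self-attention *within each chromosome*, mean-pooled and stacked into a
22 × d chromosome-aware matrix — feeding a sequence backbone (transformer,
LSTM, GRU, CNN or TCN) with six jointly trained disease heads (IS, AF, CAD,
T2D, HT, HCL). Around the model it ships the full evaluation layer:

- **genodata** — PGS-Catalog-style scoring-file parsing, VCF genotype
  extraction (effect-allele dosages via cyvcf2), effect-allele alignment,
  chromosome grouping, plain-text VCF writing for round-trips.
- **simulate** — synthetic cohorts: Gaussian-copula LD blocks, liability
  threshold multi-disease labels with a shared latent factor, planted
  within-chromosome epistatic pairs, liability-correlated event ages,
  family-history flags. Canonical fixture factories
  (`make_null_spec`, `make_epistasis_spec`, `make_causal_chrom_spec`,
  `make_shared_factor_spec`) drive the test suite.
- **chromembed / model** — the embedding layer and backbones, built on a
  small in-repo reverse-mode autodiff engine (`metageno.autodiff`, float64
  numpy; no GPU frameworks required), with representation-ablation modes
  (`chromosome_wise`, `global_snp`, `independent_snp`, `one_hot`).
- **train_eval** — stratified 5-fold protocol with balanced training folds
  (controls downsampled to the IS case count; excluded controls join the
  fold's evaluation pool), Mann-Whitney AUROC with stratified bootstrap
  CIs, precision/recall/F1.
- **baselines** — the classic weighted-sum polygenic risk score.
- **riskstrat** — percentile normalization against a reference cohort,
  tertile and high-risk percentile bins with Cox hazard ratios (lifelines),
  Harrell's C-index, Kaplan-Meier cumulative incidence with Greenwood
  bands, and per-chromosome attention reports.

## CLI

```bash
# simulate a cohort -> VCF + phenotype table
metageno simulate --spec spec.yaml --n 5000 --out cohort

# weighted-sum PRS from a VCF and a scoring file
metageno prs --vcf cohort.vcf --panel panel.txt --tag IS --out scores.csv

# cross-validated training (config-driven)
metageno train --config cfg.yaml --out run/

# percentile stratification + bin-wise hazard ratios
metageno stratify --scores scores.csv --pheno cohort.pheno.tsv --scheme tertiles
```

A simulation spec is a YAML mirror of `simulate.ArchitectureSpec`
(see `tests/test_cli.py` for a minimal example).

## Acceptance

Acceptance for this artifact is property-based: attention and metric
oracles, gradient checks, null calibration, hazard-ratio recovery, the
nonlinearity advantage over a true-weight PRS, the multi-task benefit,
attention recovery of planted causal chromosomes, and the representation
ablation ordering. They run as `tests/test_acceptance.py` with frozen
seeds. The report generator

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs a deterministic end-to-end self-check and writes an empty JSON object:
no numeric headline targets are defined for offline recomputation, since
metrics of that kind require restricted-access biobank cohorts.
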