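# hapscan

Multimarker logistic-regression association testing for case-control
GWAS data, built around sliding windows of SNPs.

Single-SNP tests miss association signals carried by untyped variants
whose footprint is spread over several nearby markers or over a marker
*haplotype*. `hapscan` implements three window-level logistic models for
a binary phenotype Y over a window of m SNPs, together with everything
needed to run them on real, unphased genotype data:

* **main-effects** — `logit P(Y=1) = μ + Σ_j X_j β_j`, one term per SNP
  minor-allele count;
* **main+adj** — the main effects plus a statistical interaction
  `X_j · X_{j+1}` for each *included* adjacent SNP pair. A pair is
  included only when the rarest of its four 2-SNP haplotypes has at
  least 10 observations: near D' = 1 the interaction parameter is not
  (or barely) identifiable;
* **haplotype** — `logit P(Y=1) = Σ_k Z_k β_k` with Z_k the number of
  copies of haplotype category k carried; haplotypes seen fewer than
  10 times are pooled into one "rare" category.

For unphased genotypes, window haplotype frequencies are estimated with
an EM algorithm and the design matrix entries for the two higher-order
models are replaced by their expectations under the per-individual
phase posterior (*expectation-substitution*). Because inferred haplotype
frequencies are never exact, significance is assessed with the Rao score
test `S = Uᵀ(θ₀) J⁻(θ₀) U(θ₀)` — whose null χ² distribution is robust to
that misspecification, unlike the likelihood-ratio test — with nuisance
covariates (e.g. principal-component scores) profiled out through the
efficient Fisher information and a generalized inverse handling
collinear SNPs. The omnibus p-value tests all genetic terms jointly.

The package also provides:

* the QC battery that multimarker analyses need (missingness > 3 %,
  differential case/control missingness at p < 1e-4, SNP and
  window-haplotype Hardy–Weinberg tests, VIF-based LD pruning);
* a multinomial log-linear model of haplotype *frequencies*
  (`log(p_i/p_ref) = x_iᵀβ`) used to quantify how much adjacent
  interactions improve haplotype-frequency modelling (LR test and AIC);
* simulation machinery: a 20,000-haplotype 1 Mb European-demography
  coalescent panel (msprime, hotspot recombination map), case-control
  sampling with calibrated relative risks, empirical-null power
  estimation, and a two-population stratification model with the
  median-based inflation factor λ̂ = median(S) / median(χ²_df);
* a genome-scan driver (sliding windows, default width 6) and a CLI
  (`hapscan scan | qc | simulate-strat | simulate-power | hapfreq-study`).

## Worked example

Simulate one stratified case-control dataset (500 + 500 individuals from
two populations, 3 SNPs, no true genetic effect), EM-phase it, and run
the three omnibus score tests:

```python
from hapscan import (StratConfig, simulate_stratified, em_frequencies,
                     phase_posteriors, build_main_effects, build_main_adj,
                     build_haplotype, fit_null, score_test)

gm, pheno, pop = simulate_stratified(StratConfig(delta=0.08, mu=0.08), seed=1)
table = em_frequencies(gm.dosage)
post = phase_posteriors(gm.dosage, table)
null = fit_null(pheno.y)
for build in (build_main_effects, build_main_adj, build_haplotype):
    res = score_test(build(post), null)
    print(f"{res.model:10s} S = {res.statistic:6.2f}  df = {res.df}  p = {res.p:.4f}")
```

```
main       S =   1.30  df = 3  p = 0.7302
main+adj   S =   1.60  df = 5  p = 0.9009
haplotype  S =   2.41  df = 6  p = 0.8785
```

The EM recovers the seven underlying haplotype frequencies (e.g. 0.340
for the most common haplotype `100`, truth 0.38 in population 1 and 0.30
in population 2), the main+adj design adds both adjacent interactions
(df 5), and the haplotype design has seven categories (df 6). This
particular replicate shows no spurious association; over many replicates
the stratification shifts the whole statistic distribution upward, which
is what the inflation factor λ̂ summarises (`hapscan simulate-strat`).

Scanning real data:

```sh
hapscan qc   --vcf study.vcf --pheno pheno.txt --out qc.tsv
hapscan scan --vcf study.vcf --pheno pheno.txt --covar pcs.txt \
             --window 6 --out results.tsv
```

`results.tsv` has one row per window and model (`first_snp, pos, model,
stat, df, p, p_adjusted`), plus a JSON summary with per-model λ̂.

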