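# Methods

This note records the statistical models, the simulation designs, the
numerical choices, and the known limitations of `hapscan`. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Window models and coding conventions

All models are logistic regressions of a binary phenotype on genetic
covariates built from a window of m biallelic SNPs (default m = 6;
window widths of 5–6 are near-optimal for haplotype testing, and the
phasing machinery caps m at 8 so the 2^m haplotype space stays
enumerable). Alleles are coded 0/1 with 1 the *minor* allele in the
analysed sample; ties at frequency 0.5 keep the file's alternate allele.
Observation units are haplotype copies when phase is known (each copy
contributes one row) and individuals otherwise (rows are sums over the
two copies).

* **Main-effects**: intercept plus one dosage term per SNP. Unaffected
  by phase, since the dosage is observable.
* **Main+adj**: adds the product `X_j X_{j+1}` for each adjacent pair
  whose rarest 2-SNP haplotype count is ≥ 10 (`min_count`, the one
  tunable threshold shared across modules). Rationale: the interaction
  is the third identifiable parameter of the 2-SNP haplotype
  distribution; near complete LD it is estimated from almost no
  observations, and logistic asymptotics degrade below roughly ten
  observations per parameter. For an individual the product term is the
  expected number of *copies* carrying both minor alleles — not the
  product of the two dosages, which would confuse coupling (11/00) and
  repulsion (10/01) phase.
* **Haplotype**: one category per window haplotype with count ≥ 10,
  all rarer haplotypes pooled into a single "rare" category (formed
  whatever its pooled total). The model is parameterized as intercept
  plus h−1 indicators with the most frequent category (lexicographic
  tie-break) as reference — equivalent to the intercept-free h-category
  coding because the category dosages of an individual sum to 2, but
  with a well-defined df = h−1.

Monomorphic SNPs are dropped from main/adj terms (zero variance) but
retained in haplotype identity.

## Unphased data: EM phasing and expectation-substitution

Window haplotype frequencies are the multinomial MLE over unordered
haplotype pairs under Hardy–Weinberg random pairing, computed by EM on
the deduplicated genotype patterns. Initialization is the
product-of-marginals table — deterministic, and on exactly symmetric
data the symmetric stationary point is returned, which is what
expectation-substitution needs. Convergence: max absolute frequency
change < 1e-8 (the observed-data log-likelihood is checked to be
non-decreasing). Frequencies below 100× the tolerance are numerical
zeros — the EM approaches boundary zeros only linearly, and keeping that
dust would fabricate near-empty haplotype categories downstream.
Individuals with any missing genotype in a window are excluded from that
window: upstream QC caps per-SNP missingness at 3 %, so the loss is
small, while summing over missingness patterns would complicate the
E-step for little gain.

Phase posteriors are `P(pair | genotype) ∝ p_a p_b` (doubled for
heterozygous pairs) over compatible pairs; a genotype with zero
probability under the table falls back to a uniform posterior with a
warning. Every higher-order design entry is an expectation under these
posteriors (ES). ES is valid under the null because genotype alone then
determines the haplotype distribution.

## Score test

With null fit π̂ (intercept + optional covariates, via IRLS), tested
block G, null design M and W = diag(π̂(1−π̂)):

    U = Gᵀ(y − π̂),   J = GᵀWG − GᵀWM (MᵀWM)⁻¹ MᵀWG,   S = Uᵀ J⁺ U.

J is the efficient information (Schur complement), mathematically
identical to refitting the nuisance per window but much faster for
scans. J⁺ is the eigendecomposition pseudo-inverse with the standard
cutoff max(dim)·ε·λ_max; the reported df is the numerical rank, which
makes S invariant under invertible reparameterizations and robust to
SNPs fully determined by their neighbours. Because the binomial family
is exponential, the score covariance equals the Fisher information, so S
keeps its χ² null distribution even when the inferred haplotype
frequencies are wrong — the reason unphased analyses use the score test
while phased simulations may use the likelihood-ratio test. The LR path
reduces collinear designs by pivoted QR and falls back to the score test
on separation.

Single-SNP tests are 1-df logistic score tests (asymptotically the
Cochran–Armitage trend test; exactly N·corr²(g, y) without covariates),
which also gives the covariate-adjusted single-SNP test.

## Haplotype-frequency modelling

Observed window haplotypes are a categorical response with
log-likelihood Σ n_i log p_i and log-linear frequencies
`log(p_i/p_ref) = x_iᵀβ`, where x_i holds the haplotype's alleles (main
coding; exactly the independence model) and optionally the included
adjacent products. The fit is a Newton iteration on the softmax
parameterization after centring and reducing the design to a linearly
independent column set (the likelihood is then strictly concave;
statsmodels' Poisson GLM serves as an independent oracle in the tests).
Zero-count haplotypes are excluded from the response. Nested codings are
compared by LR (χ² with df = added independent interaction columns) and
by ΔAIC = LR − 2·df; sets with no includable interaction are flagged and
excluded from study denominators. The significance threshold for "the
interactions improve the fit" is α = 0.05.

## Synthetic data

**Coalescent panel.** `simulate_panel` draws 20,000 haplotype copies of
a 1 Mb segment with msprime under a single-deme European-calibrated
history (ancestral Ne 12,500; a brief bottleneck to 800 for 150
generations at 3,500 generations ago, inbreeding ≈ 0.085; size 7,700
until an expansion to 100,000 at 350 generations), mutation rate
1.5e-8 /bp/gen, and a seeded hotspot recombination map: ~2 kb hotspots
with mean spacing 50 kb carrying 80 % of a 1.3 cM/Mb sequence-averaged
map. The hotspot structure matters: it produces the block-like LD of
European data, in which some adjacent marker pairs are nearly
independent (straddling a hotspot) while others are in almost complete
LD — the regime that drives both the interaction-inclusion rule and the
spread of LR outcomes. Sites perfectly correlated with an earlier site
(equal or complementary columns) are removed; typical panels then hold
~10,000 sites of which ~500–900 have MAF ≥ 0.05. What the panel does
*not* emulate: real genetic maps and hotspot intensities vary along the
genome; mutation is treated as infinite-sites; there is no genotyping
error. Results on this panel therefore characterise the methods under
clean European-like LD, not artefact robustness.

**Case-control sampling.** Disease is assigned per haplotype copy
(baseline risk 0.1; relative risk `rr` for carriers of the causal
allele), and 1,500 case plus 1,500 control copies are sampled without
replacement. The causal allele is either a typed panel SNP at a target
MAF with six flanking common markers at the requested spacing (the
causal SNP excluded and central), or the indicator of the marker
haplotype whose frequency is closest to the target — the "recent
founder mutation" scheme in which the causal allele sits on exactly one
marker haplotype. `calibrate_rr` solves, by bisection on a non-central
χ² power curve, for the smallest rr giving 80 % power at α = 0.05 to
detect the causal SNP directly with a 1-df allelic test on the same
sample sizes (a 2-df genotype-test mode on HWE-paired copies is
provided; with haplotype copies as the observation unit the allelic
form is the natural default). Power is estimated against an *empirical*
null: each model's 5 % threshold is the 0.05 quantile of its p-values
over phenotype permutations on one fixed genotype sample, which forces
exact self-calibration at rr = 1.

**Stratification model.** Two populations, seven 3-SNP haplotypes.
Haplotypes (1,0,0) and (0,0,0) have frequencies 0.3 ± δ in population 1
and 0.3, 0.3 in population 2; the five background patterns — every
remaining pattern except (1,1,1), in lexicographic order — carry fixed
frequencies {0.05, 0.07, 0.08, 0.09, 0.11} in both populations. Only
SNP 1 is differentiated (by exactly δ per haplotype copy). Each
replicate draws 1,000 copies per population, pairs them randomly within
population into 500 + 500 individuals, and assigns case status with
probability 0.5 ± μ by population, so any association signal is pure
confounding. Inflation is summarised by λ̂ = median(S) / median(χ²_df)
per model at that model's *modal* df across replicates; replicates with
a different df (e.g. an extra rare category) are excluded and counted.
`balding_nichols_fst` converts the SNP-1 frequency gap into an F_ST
estimate (variance of the two subpopulation frequencies about their
mean over p̄(1−p̄)). The λ̂ values depend mildly on which background
patterns carry the SNP-1 minor allele; the lexicographic assignment
above is fixed as the package's reference condition.

## QC battery

Missingness > 3 % (strict inequality) excludes a SNP; differential
missingness is a 2×2 Pearson χ² of missing-vs-observed by case status,
flagged at p < 1e-4 (case-biased missingness can fabricate case-only
haplotypes); SNP HWE is the 1-df goodness-of-fit χ² with an exact-test
mode; window haplotype HWE treats the pooled categories as alleles of
one multi-allelic locus, comparing EM-expected pair counts to N p_i²
and 2N p_i p_j with df = h(h−1)/2 and cells of expected count < 5
pooled. Because the EM-expected pair counts are themselves computed
under random pairing, this test is mildly conservative — it cannot
over-reject, which is the property the suite asserts. LD pruning slides
a 50-SNP window in steps of 5 and repeatedly removes the SNP with the
highest variance-inflation factor (regression on the other window SNPs;
ties remove the later position) while any VIF exceeds 2, iterating to a
fixed point so pruning is idempotent and deterministic.

## Problem sizes used by the suite and acceptance script

Chosen to keep the full run in a few CPU-minutes while leaving the
stated tolerances at ≥ ~1.7 Monte-Carlo standard errors: stratification
λ̂ uses 5,000 replicates (8,000 for the μ = 0 calibration check, whose
±0.03 band is narrow relative to the MC error of a sample median); the
interaction-improvement study uses 1,000 marker sets of 1,500 rows per
spacing; type-I-error checks use 300–400 replicates against 0.05 ± 3 SE;
power orderings use 300 replicates with 300-permutation empirical
nulls. All random draws flow from explicit seeds.

## Known limitations

* ES assumes genotype-only information determines phase — exact under
  the null, approximate under strong alternatives; the score test keeps
  type-I error but power statements inherit the approximation.
* The EM phaser is single-window and HWE-based; long-range or
  population-aware phasers would sharpen posteriors, though the score
  test's robustness makes the tests insensitive to modest phasing error.
* The haplotype-HWE statistic is conservative by construction (above).
* λ̂ compares medians only; models with different df are not directly
  comparable beyond the median, and replicate-level df variation is
  handled by exclusion rather than mixture modelling.
* No family-based designs, no mixed-model/kinship correction, no
  imputation; principal-component scores are accepted as covariates but
  not computed here.
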