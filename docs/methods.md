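# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Animal model and single-step evaluation

Both evaluations solve Henderson's mixed-model equations for

y = Xb + Z₁a + Z₂c + e,

with fixed hatch-year and harvest-group effects (intercept plus dummy
columns; the first level of each factor is constrained to zero, and
collinear columns detected by pivoted QR are constrained out with a
warning), a ~ N(0, σ²ₐK), c ~ N(0, σ²꜀I) per full-sib family, and
e ~ N(0, σ²ₑI). The equations are assembled in variance-ratio form with
λₐ = σ²ₑ/σ²ₐ and λ꜀ = σ²ₑ/σ²꜀; σ²꜀ = 0 drops the family equations.

K⁻¹ is A⁻¹ for PBLUP, built by Henderson's rules with the exact
Mendelian-sampling variances dᵢ = ½ − ¼(F_s + F_d) from Meuwissen–Luo
inbreeding coefficients, so A⁻¹ is the exact inverse of the tabular A for
inbred pedigrees. For ssGBLUP, K⁻¹ = H⁻¹ adds (G⁻¹ − A₂₂⁻¹) into the
genotyped block of A⁻¹. A₂₂⁻¹ is always the dense inverse of the extracted
A block, never a subset of A⁻¹ (those differ whenever genotyped animals
have non-genotyped relatives; a regression test enforces the distinction).

G is VanRaden's matrix from dosages centered by twice the observed
("current") allele frequencies; missing dosages are mean-imputed to 2pⱼ
before centering. Because G from sample frequencies is singular (rows sum
to zero) and often rank-deficient at low SNP counts, G is first rescaled so
its mean diagonal and mean off-diagonal match A₂₂'s (solving a 2×2 linear
system in an intercept and slope), then blended G* = (1−β)G + βA₂₂ with
β = 0.05 by default. The blending and tuning constants are package
defaults, declared in every run manifest; they are the kind of
compatibility adjustment evaluation software applies routinely, and results
at this scale are insensitive to β in [0.01, 0.10].

Solvers: dense Cholesky by default (systems here are at most a few thousand
equations) with a relative-residual check at 1e-8, or Jacobi-preconditioned
conjugate gradients; both are tested to agree to 1e-6.

## REML

`reml_estimate` fits (σ²ₐ, σ²꜀, σ²ₑ) for one trait. The default is EM-REML:
monotone and robust but slow near the optimum (it routinely needs hundreds
to a few thousand iterations, each a dense factorization). The `ai` method
takes average-information steps — exact first derivatives via the standard
mixed-model-equation trace identities, the AI matrix from quadratic forms
in P·fᵢ with f_a = Z₁â/σ²ₐ, f_c = Z₂ĉ/σ²꜀, f_e = Py — with step-halving
and EM fallback whenever a step would leave the parameter space; it
typically converges in 8–15 iterations. Both methods are verified in the
tests against an independent oracle that maximizes the restricted
likelihood with the dense phenotypic covariance V; they agree to four
significant figures. Components pinned at the floor (1e-8 of the
phenotypic variance) are reported as boundary estimates; non-convergence
raises with the full parameter trajectory attached.

Cross-validation re-uses full-data variance components (PBLUP-estimated)
for both models, so PBLUP/ssGBLUP comparisons are not confounded by
re-estimation — matching how validation studies with small genotyped sets
are usually run.

## Cross-validation, predictive ability, inflation

Animals eligible for validation are those with a phenotype and, when
genomic data are present, a genotype. They are split into k = 5 mutually
exclusive folds (sizes differing by at most one, deterministic in the
seed). Each fold's phenotypes are removed from the data — masked records
never reach the training equations, which a permutation (leakage) test
verifies — and the model is re-solved with the fixed variance components.

Predictive ability is cor(y*, (G)EBV) over the fold's validation animals,
with y* = y − Xb̂ and b̂ from the full-data PBLUP fit (a flag switches to
training-only adjustment). The report gives the mean over folds ± the
fold-based SE (sd/√k) and, in addition, the analytic SE √((1−r²)/(n−2)),
since which of the two a published ±SE represents is often ambiguous.
Inflation b1 (with intercept b0) is the OLS slope of y* on (G)EBV pooled
over the validation pairs of all folds — one slope per trait × model ×
panel. The five folds are treated as the five replicates; a `repeats` flag
re-partitions and pools for the stricter multi-pass reading.

## LD, decay and effective population size

r² = D²/(P_A P_a P_B P_b) with D = P_AB − P_A·P_B. From unphased genotypes,
P_AB is estimated per pair by EM over the double-heterozygote ambiguity
(60 iterations, vectorized over all pairs of a chromosome via 3×3 genotype
count tables; missing calls drop an animal from that pair only). The
composite estimator — squared Pearson correlation of dosages, PLINK's
convention — is available as `method="composite"` and is what the pruning
step uses. Pairs containing a monomorphic SNP are skipped and counted.

Mean LD per chromosome is the plain average of its pairwise r²; the
genome-wide figure is reported both as the mean of chromosome means and as
the mean over all pairs, since the two differ when chromosomes contribute
unequal pair counts. Sved's curve E[r²] = 1/(1 + 4N_e d) is fitted by
bounded nonlinear least squares (distances in Morgan at a configurable
uniform map rate, 1 cM/Mb by default); a noiseless curve is recovered to
1e-6, flat r² drives N_e to the zero boundary and is flagged. The
closed-form N_e of the mean-LD equation uses d_t = the chromosome's map
extent and n = the number of genotyped animals as the sample-size
adjustment, with α = 2 (mutation present). M_e = 4·N_e·L with L either
supplied (32.3 Morgan for the trout genome) or computed from the map.

Plugging published per-chromosome mean r² and spans into the closed form at
1 cM/Mb does not reproduce published per-chromosome N_e values — the d_t
and n actually used upstream are not recoverable — so per-chromosome N_e is
reported but deliberately not treated as a reference quantity.

## Panel reduction

LD pruning follows the windowed greedy scheme (window 50 SNPs, step 5):
within each window, while any surviving pair exceeds the r² threshold, the
pair's lower-MAF member is dropped (tie: the higher map index, emulating
the usual tool behaviour in spirit; the exact removal rule is not specified
anywhere authoritative). A brute-force audit in the tests confirms no
surviving within-window pair exceeds the threshold, and pruning is
idempotent.

Variance-based reduction back-solves SNP effects from the genotyped
animals' GEBV in a single pass, û = kDM′G⁻¹â with k = 1/(2Σpⱼ(1−pⱼ)),
assigns each SNP the share ûⱼ²·2pⱼ(1−pⱼ) as a percentage of their sum, and
keeps SNPs above a percentage threshold, per trait. Iterative reweighting
(full wssGBLUP) is out of scope by design.

Sweeps validate every panel on the same fold partition as the full panel
(paired-comparison contract) and flag fold-paired t-test p < 0.05. Reduced
panels keep all genotyped animals genotyped on fewer SNPs; nothing is
re-imputed.

## Synthetic populations

The generator emulates the study system: a multi-generation full-sib
pedigree (founders, then configurable generations of monogamous sire×dam
families), two phenotyped year-classes by default, genotypes for the
phenotyped generations plus their parents, 29 chromosomes totalling
32.3 Morgan, and two traits with default h² = 0.25 and 0.38 and a
common-environment fraction c² = 0.10 per trait (a typical tank-effect
magnitude for sib-reared fish; total phenotypic variance is 1, so
σ²ₑ = 1 − h² − c²). Fixed effects of hatch-year and harvest group
(5 levels) are drawn once per trait with SD 0.3.

LD arises from two mechanisms: founder haplotypes follow a first-order
Markov chain along each chromosome (adjacent-marker copy probability 0.92),
and the founder pool is small, adding drift LD. This produces the monotone
decay and appreciable long-range LD the analysis relies on; it does not
attempt coalescent realism, chromosome-specific inversions, admixture, or
genotyping error. Gametes are dropped down the pedigree with recombination
between adjacent markers at Haldane map-function probabilities
½(1 − e^(−2d)) — the exact marker-resolution marginal of a Poisson crossover
process with uniform crossover positions, chosen because it vectorizes over
all gametes of a generation.

Breeding values are sums over `n_qtl_per_trait` QTL (SNPs drawn from the
panel) with normal effects, optionally correlated between traits. The
additive scale is calibrated in one of two ways: `tbv_scale="base"`
(default) rescales so t′A⁻¹t/n = h², the base-population variance that an
animal-model REML estimates — on a multi-generation pedigree the realized
variance among phenotyped animals is smaller than the base variance
(relatives covary), and REML recovers the base parameter;
`tbv_scale="realized"` instead fixes the sample variance of TBV among
phenotyped animals at h², which is what the realized-heritability helper
`empirical_h2` (var(TBV)/var(y − fixed)) measures. A one-generation design
from unrelated founders makes the two scales coincide but leaves σ²ₐ and
σ²꜀ unidentifiable (only between- vs within-family variance is observed),
which is why variance-component recovery is exercised on two-generation
pedigrees.

What passing tests show — and do not show. On these synthetic populations
the suite demonstrates: REML recovers the simulated heritabilities within
±0.07 at 2000 phenotyped animals; ssGBLUP beats PBLUP in cross-validated
predictive ability (paired across ten population replicates) and in
accuracy against true breeding values (sign test); predictive ability does
not improve when panels shrink from thousands of SNPs to tens; QTL-linked
SNPs are enriched in the top decile of back-solved variance shares. These
are structural properties of the estimators under the generator's
assumptions (additive QTL, homogeneous families, no genotyping error,
random fold assignment); they support the implementation's correctness and
the direction of the full-scale findings, not their numerical values on
real hatchery data.

## Problem sizes and numerical conventions

Test and demonstration runs use populations of roughly 500–2500 animals
with 300–3000 SNPs — sizes chosen so the full pipeline (simulation,
relationship matrices, REML, three cross-validation runs per replicate)
stays interactive on a laptop while leaving the estimators' behaviour
unchanged in kind. Dense factorizations are used throughout (the largest
systems are a few thousand equations); A assembly is O(n²) tabular;
coordinates are 1-based bp; missing genotype code "0 0", missing phenotype
"NA"; PED dosages count the first allele of the first non-missing call
(overridable per SNP); phenotype writers emit 12-significant-digit floats
so write∘read is byte-stable. One global seed drives every stochastic draw
in a run.
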