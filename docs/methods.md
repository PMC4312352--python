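# Methods

This note documents the models implemented in `admixpower`, the parameter
choices that matter, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would want spelled out.

## Genotype container and PLINK text handling

Genotypes are diploid dosages 0/1/2 with a distinguished missing code, plus
per-marker chromosome, genetic position (Morgans) and physical position.
Reading `.ped/.map` codes each marker as the dosage of its **minor allele in
the file**, with a tie broken toward the lexicographically smaller allele,
and `0 0` pairs becoming missing. The `.map` genetic-distance column is read
as Morgans (PLINK's documented unit); `map_unit="cM"` / `--map-unit cM`
declares centimorgan maps.

One consequence of data-derived minor coding: a matrix produced by a
generator counts a fixed model allele, which may be the *major* allele at
some markers; writing such a matrix and reading it back flips the coding
there. Read → write → read is always an exact identity (the canonical form
is a fixed point), and `align_frequencies` re-orients any reference
frequency vector onto a matrix's counted alleles — the CLI frequency tables
carry an `allele` column for exactly this purpose.

## Sample QC

Two rules, in order: individuals with missing-call fraction strictly above
0.20 are removed; then PI_HAT is computed for all remaining pairs and, for
each pair above 0.5, the member with the higher missing fraction is removed
(ties: the later sample). PI_HAT uses the classic method of moments: the
observed counts of IBS sharing classes are equated with their expectations
given IBD state (computed from sample allele frequencies over jointly
non-missing, polymorphic markers), negative solutions are clipped to zero
and the triple renormalised, and PI_HAT = P(IBD=1)/2 + P(IBD=2). Allele
frequencies default to the full-matrix estimates; a marker mask is exposed
because pruned-versus-full marker sets are a legitimate analysis choice.

## Synthetic reference panels and artificial admixture

The Balding–Nichols model stands in for real diverged populations: per
marker, an ancestral frequency p ~ Uniform(0.05, 0.95), then each
population's frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so that the
expected divergence between two panels is governed by F. Defaults: F = 0.1,
5,000 markers, 50 diploid individuals per panel. F = 0 returns the
ancestral frequencies exactly. The frequency range excludes the boundaries
because downstream estimators need polymorphism; the Hudson Fst of two
generated panels recovers the nominal F to within ~0.02 at these sizes.

Artificial admixed genomes mix at the **marker level**: per individual and
marker, the genotype is Binomial(2, f_source) with probability α, else
Binomial(2, f_background). This matches the construction used for
recent-admixture power assessment on unlinked markers (resampling whole
genotypes rather than single alleles), and makes α the exact expected
source fraction per individual.

What these panels do *not* emulate: realistic site-frequency spectra,
background LD, genotyping error, and the shared drift structure of real
population pairs. Recovery results on them demonstrate estimator
correctness and sampling noise at a given divergence, not performance on
any particular real dataset.

## Ancestry-mosaic haplotypes

For LD-based dating, haplotypes are painted with ancestry tracts: boundaries
follow a Poisson process of intensity λ per Morgan, each tract is source
with probability m, and alleles are drawn from the tract ancestry's panel
frequency. Tract lengths are therefore Exponential(λ) (interior tracts;
chromosome-edge tracts are censored), the marker-level ancestry
autocovariance is m(1−m)e^(−λd), and λ is interpreted as generations since
admixture. Defaults λ = 240 (≈6 Ky at 25 y/generation), m = 0.3.

## The admixture likelihood and EM

The binomial admixture model: dosage g_il ~ Binomial(2, Σ_k q_ik f_kl).
Optimisation is plain EM — the same optimum as accelerated quasi-Newton
implementations, chosen for verifiability. Defaults: tolerance 10⁻⁶
log-likelihood units, max 2,000 iterations, frequency clamp ε = 10⁻⁶
(keeps the likelihood finite; no reported quantity changes at stated
precision). Supervised mode fixes F at reference frequencies and starts
every individual at q = 1/K, making the result deterministic; the
per-individual problem is concave and the estimates match 1-D grid search
at 10⁻⁴ resolution. Unsupervised mode starts Q from a seeded Dirichlet and
resolves label switching by sorting components on mean allele frequency.
K = 1 is closed-form. EM's likelihood ascent near the simplex boundary is
slow; `converged=False` after max_iter with an essentially flat trace is
expected behaviour there, not failure. Choosing K by cross-validation is
out of scope; K is always user-specified.

A statistical floor worth knowing: with F = 0.1 panels and 5,000 markers
the per-individual supervised MLE has sampling noise of roughly ±0.02 (one
s.d., from the Fisher information ≈ 2L·E[(f₁−f₂)²/(f(1−f))]). Means over 16
individuals are accurate to a few parts in a thousand, but *individual*
null estimates in the 0.02–0.04 range occur at the expected Gaussian-tail
rate and are not evidence of admixture.

## Forward simulation of the pulse demography

Epoch structure (generations before present, defaults in brackets): one
ancestral population of size N_anc1 [10,000] from t_start [3800]; at
t_split1 [1000] a Source branch splits off and expands instantaneously to
N_source [30,000] (no growth curve is modelled; the intermediate branch
keeps N_anc1); at t_split2 [440] the remainder splits into Control
[N_control = 2,000] and Admixed [N_admix = 2,000]; at t_pulse [240] each
Admixed individual is independently replaced by a Source migrant with
probability m. Defaults encode 95/25/11/6 Kya at 25 years per generation.
These sizes are package defaults chosen to be plausible for the populations
modelled (a large expanded source, small isolated daughters); no published
estimates were available, every value is configurable, and the test suite
asserts order and martingale properties rather than size-dependent numbers.

Because the 2,200 loci are unlinked and mating is random, the population
allele-frequency process is simulated exactly as the Wright–Fisher binomial
chain (2N gametes per generation and locus), initialised Uniform(0.05,
0.95) at t_start, and sampled individuals' genotypes are drawn
Binomial(2, p) under Hardy–Weinberg — marginally identical to an
individual-based engine at a tiny fraction of the cost. True ancestry is
tracked as an exact per-individual scalar: migrants start at 1 and each
offspring carries the mean of its two parents' values. The realised migrant
count couples the ancestry process to the frequency pulse; thereafter the
two processes run on independent pedigrees, so individual genotypes are not
correlated with individual ancestry *within* the admixed sample. This does
not affect population-mean detection (the quantity power is defined on) and
is the one deliberate departure from a literal individual-based model.

"Immediately after" the pulse is implemented as one mating generation after
it, so post-pulse individual ancestries are {0, ½, 1} rather than {0, 1}.

Under scalar parental-mean bookkeeping the within-population ancestry
variance halves each generation, so the population mean drifts with total
standard deviation ≈ √(m(1−m)/N_admix) — small at the default sizes. The
cross-replicate mean stays at m (ancestry is a martingale), which is what
the acceptance checks assert. Strong individual-level heterogeneity and
frequent loss of the admixture signal, as would follow from much smaller
admixed populations, appear only when N_admix is set low; the defaults do
not produce them.

## f3, LD decay, Ne, weighted LD

- **f3**: per SNP (c−a)(c−b), minus h_c/n_c (h_c = n_c c(1−c)/(n_c−1)) when
  target chromosome counts are supplied; mean over SNPs; SE by
  leave-one-block-out jackknife over contiguous SNP blocks (equal block
  size, last block possibly shorter). The statistic is exactly symmetric in
  the two sources; SE = 0 yields z = NaN rather than ±∞.
- **LD decay**: r² is the squared Pearson correlation of dosage vectors
  (Rogers–Huff style, appropriate for unphased data) over jointly
  non-missing individuals, pooled across chromosomes into genetic-distance
  bins; the reported value subtracts 1/n. Monomorphic pairs are skipped.
- **Ne trajectory**: Ne = (1/(4c))(1/r²_adj − 2) at t = 1/(2c). The drift
  constant 2 is exposed as a parameter since published variants differ.
  Bins with r²_adj ≤ 0 or ≥ 1/constant are reported as skipped with
  reasons, not raised. A two-locus Wright–Fisher simulator
  (`simulate_linked_pairs`, exact multinomial resampling with deterministic
  recombination of expected gamete frequencies) provides the independent
  truth for validating this inversion; recovery at N = 1,000 is within a
  factor of two, the accuracy one should expect of the method itself.
- **Weighted LD**: per marker pair, cov(g₁, g₂)·w₁·w₂ with w the
  reference-frequency contrast, bin-averaged with weights w₁²w₂² so an
  admixed target yields ≈ 2m(1−m)e^(−λd). The exponential fit
  A·e^(−λd) + c₀ uses least squares with a log-linear initial guess;
  non-convergence returns a flagged fit with infinite residual, and a flat
  curve (amplitude within noise of zero) is flagged unidentifiable. This is
  a deliberately simplified admixture-LD machine: no FFT pair aggregation,
  no affine pre-tests, no two-reference jackknife — a single decay fit used
  as a yes/no-plus-date signal.
- **Fragment survival**: CDF(x) = 1 − e^(−λx). The headline evaluation uses
  rate 6000 with x = 5×10⁻⁴ Morgans (50 kb at the genome-wide average
  1 cM/Mb), giving 0.9502; with λ read as 240 generations the same
  statement does not follow, so the rate is an explicit argument rather
  than a hard-coded interpretation.

## Power study

`run_power_study` simulates each migration rate with replicate seeds
derived deterministically from a base seed (shared across rates, so rates
differ only through the pulse), and scores detection as present-day
sample-mean ancestry ≥ θ. By default the bookkept true ancestry is used —
power then measures whether the demography *leaves* a mean signal of size θ
to find, given an assay able to measure mean admixture that precisely. With
`use_estimates=True` the supervised EM estimate (references: the simulated
present-day Source and Control samples — panels one could actually
genotype) replaces the truth; at 2,200 loci the estimator's own noise floor
(±0.4% on a 50-individual mean, and upward-biased near the boundary because
estimates are non-negative) dominates thresholds of 0.1–0.5%, so
estimate-based power at those thresholds reflects the estimator, not the
demography. Both modes are first-class; the default keeps the two questions
separate.

Study sizes used by the shipped checks: 50 replicates per rate over rates
{0, 1%, 5%, 10%} and thresholds {0.1%, 0.5%}, 2,200 loci, samples of 50 —
chosen as the smallest design that pins the monotonicity and martingale
properties at 3σ.

## Known limitations

- No linkage in the forward engine (by design — the analyses assume
  unlinked markers); admixture-LD dating is exercised on the mosaic
  generator instead.
- Genotype–ancestry coupling within the simulated admixed sample is not
  modelled (see above).
- The EM is unaccelerated; very large unsupervised problems converge
  slowly.
- Binary PLINK, VCF, per-marker QC (MAF/HWE), PCA projection and
  graph-based migration fitting are out of scope.
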