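# Methods

This note documents the models, the defaults and the numerical choices
behind `admixlpa`, and what the synthetic cohorts can and cannot show.

## Cohort generator

The generator emulates an African-American community cohort. Global
African ancestry θ_i is Beta-distributed with mean 0.83 and concentration
chosen to give sd 0.09 (both configurable), matching the distribution
typical of large African-American cohorts. Sex is Bernoulli (male fraction
0.368 by default) and family sizes are drawn from a user-supplied
distribution (singletons by default; the demonstration cohort uses
70/20/10% families of size 1/2/3 so that unrelated-subsampling is
exercised).

Each chromosome copy carries a two-state ancestry chain along the genetic
map: over a gap of d Morgans the ancestry is kept with probability
e^{−λd}, otherwise redrawn from Bernoulli(θ_i). λ defaults to 6 per
Morgan, a standard figure for the age of African-American admixture
(~6 generations). Alleles are drawn from f_afr or f_eur per copy, so the
only linkage disequilibrium in the simulator is admixture LD — real
haplotype-background LD within the ancestral populations is deliberately
not modeled. Consequences: tests that pass here demonstrate correctness of
the inference machinery under the model's own assumptions, not robustness
to ancestral-LD misspecification, array artifacts, or phasing error.

The trait is log-normal: ln y = μ + β_sex·1[male] + β_θ·θ + Σ_s β_s g_s +
ε, ε ~ N(0, σ²). Percent effects convert exactly via β = ln(1 + e/100);
this inversion is tested to machine precision. Survival times are
exponential with hazard ∝ HR^g and a censoring threshold placed at the
n_events-th order statistic, so the event count is exact by construction
in every replicate.

## Local-ancestry HMM

A deterministic plug-in replacement for MCMC samplers of the same model:
ancestral allele frequencies and θ̂ are fixed at point estimates instead of
being integrated over. θ̂ maximizes the marker-independent genotype
likelihood on a grid (0.01–0.99, step 0.01) refined by bounded local
search; individuals with a flat likelihood (all markers uninformative or
all genotypes missing) are flagged and set to the grid midpoint. The
diploid chain has states a ∈ {0,1,2} built from two independent per-copy
chains (random-mating assumption); emissions mix the clean convolution
model with a genotype-error rate (default 0.01, uniform over the three
genotypes). Posteriors come from a scaled forward–backward pass,
vectorized across individuals; chromosomes are independent.

Correctness is anchored by an exhaustive-enumeration oracle (all 2^m × 2^m
per-copy paths on ≤5 markers, agreement to 1e-10) and by calibration
checks on synthetic cohorts (among pairs with p₂ ≥ 0.9 the true state is 2
in ≥90% of cases). Accuracy improves monotonically with marker density, as
it should.

## Cases-only admixture scan

Cases are the top ⌈qn⌉ (default q = 0.2) of the sex-adjusted log trait.
The per-locus Bayes factor tilts each case's Hardy–Weinberg prior by ψ per
African allele and averages the likelihood ratio over a uniform grid
ψ ∈ {0.3, …, 3.0} \ {1} (grid configurable; the spacing of 0.1 makes the
prior proper and symmetric on the ratio scale around 1 in neither
direction — it simply brackets plausible ancestry risk ratios). Because
the posterior and the prior come from the same HMM, the ratio
Σ_a p_a ψ^a / Σ_a π_a ψ^a needs no re-decoding. LOD > 5 is called
significant. The credible interval normalizes 10^LOD over positive-LOD
loci on the peak chromosome and grows the interval from the argmax toward
whichever neighbor adds more area until 95% is enclosed; negative-LOD loci
carry zero area (clipping at 0 keeps the area finite and concentrates the
interval on the peak). Controls are reported alongside for the
opposite-direction sanity check but never enter the statistic.

## Association layer

The phenotype everywhere is the residual of ln(trait) on sex. SNP tests
are nested-model ANOVA F-tests (reduced: ancestry covariates; full:
+ genotype, additive coding); for a single added term this equals the
squared-t test, which is asserted as an identity. Effect sizes are
percent-change per unit with delta-method standard errors. The
genotype × local-ancestry interaction multiplies genotype (0–2) by local
African fraction (0–1), giving a covariate in [0, 2]. QC drops SNPs below
90% call rate, then samples below 85%; Hardy–Weinberg is a 1-df χ²
goodness-of-fit test. LD is the squared Pearson correlation of dosages
(composite LD — no phasing exists in this pipeline). Missing genotypes are
dropped listwise per test. The multiple-testing flag defaults to
0.05/59 ≈ 0.00085, the Bonferroni level for a 59-SNP fine-mapping panel.
Family structure is handled by analysis on resampled unrelated groups (one
member per family per group) rather than by a variance-component model;
stratified analyses (AFR-2 / EUR-1_2 / EUR-2 at posterior threshold 0.95)
are available with or without θ̂ as a within-stratum covariate.

## Mediation and cross-validation

π = 1 − R²_geno / R², with adjusted R² ((n−1)/(n−p−1) correction)
throughout. This orientation makes π the fraction of the ancestry-trait
association removed by genotype adjustment, lying in [0, 1] under
mediation; the algebraically inverted form (which flips sign in the
mediating direction) is available behind a flag for comparability. π is
undefined (NaN, with a diagnostic) when the base ancestry R² is not
positive.

Stepwise model building adds, at each step, the candidate with the
smallest group-averaged nested-ANOVA p-value, if below 0.05; ties break by
candidate order, and perfectly collinear duplicates can never both enter.
Five-fold CV rotates roles — three folds discover (marginal p < 0.05,
ancestry-adjusted by default, toggleable), one builds the stepwise model
and its coefficients, one evaluates out of sample; a rotation that
discovers nothing contributes 0%. Two-fold CV (coefficients on one half,
out-of-sample R² on the other) serves the single-SNP estimates. The
anti-overfitting property (out-of-sample ≤ in-sample R² in expectation)
and the agreement of the single-SNP estimate with the closed form
2pqβ²/(2pqβ² + σ²) to within one percentage point are both under test.

## Cox power

`simulate_power` fits each iteration with an in-package Newton solver for
the single-covariate Cox partial likelihood (score and information via
reverse cumulative sums). The simulated times are continuous so event
times are almost surely distinct; censorings tied with an event sort after
it and therefore remain in its risk set. The solver is tested against
lifelines to 1e-5 on β and against a hand-written partial likelihood on a
four-row example; `cox_snp_association`, the general interface, uses
lifelines itself (Efron ties). The Newton route keeps a 1000-iteration
power run at n = 3225 to a few seconds.

The per-iteration hazard ratio is drawn Normal(hr_mean, hr_cv·hr_mean),
truncated positive. hr_cv defaults to 0.01: the dispersion is meant to
mirror the sampling standard deviation of a well-estimated demographic
coefficient (age) as a fraction of its mean, which at cohort sizes in the
thousands is of order 1%. This choice matters — at the reference design
(3225 individuals, 389 events, allele frequency 0.19, HR 1.067 per
allele), measured power is 10.8% at cv = 0, 11.0% at cv = 0.01 and 14.0%
at cv = 0.05, because power is convex in the log hazard ratio and a
dispersion comparable to the mean log-HR (0.065) inflates it
substantially. The closed-form score approximation
Φ(−z_{α/2} + |β|√(2pq·D)) gives 10.9% and anchors the simulation in tests.

Hazard-ratio rescaling across effect sizes uses log-proportionality:
HR per c′-fold change = HR_ref^{ln c′ / ln c}. A reference of 1.22 per
doubling gives 1.0661 per exactly 1.25-fold change and 1.0671 per
1.254-fold change (the per-allele trait factor the pipeline's reference
design uses); the package quotes the latter, 1.067 at three decimals.

## Occupancy scanner

PWM rows are regularized with a background-proportional pseudocount
(default 0.01) so zero counts stay finite; the background is uniform 0.25
by default and overridable (genome-wide background estimation is out of
scope). The free concentration [X] is anchored at the dissociation
constant of the motif's own optimal site — the strongest site the matrix
can describe — which pins consensus occupancy at exactly 50% and bounds
all occupancies in (0, 0.5]. Both strands are scanned and the maximum
taken. Only windows overlapping the variant base can differ between
alleles, so the allele delta is computed over those windows, while the
occupancy floor (p_min) may be met by any window in the flank. Defaults
p_min = delta_min = 0.20; the hit/no-hit decision on the test fixtures is
stable across thresholds 0.10–0.30. JASPAR pfm and TRANSFAC matrices are
parsed by Bio.motifs.

## Pipeline, seeds and sizes

Every stochastic stage takes a seed; the pipeline driver derives per-stage
seeds from one global seed (CRC-mixed, below 2³¹) so stages can be re-run
in isolation and reports are byte-identical across runs. Coordinates are
1-based inclusive except BED output (0-based half-open).

Problem sizes used by the shipped analyses and tests are desk-scale by
design: the demonstration cohort is 4464 individuals × 600 markers;
acceptance-level simulations use 100 null scans at n = 1000, effect
recovery at n = 3300, mediation at n = 5000, 1000–2000 Cox iterations, and
20 replicate cohorts for the cross-validated variance fraction. These
sizes give Monte-Carlo errors comfortably inside the tolerances asserted
in the test suite while keeping the full suite around a minute.

## Known limitations

* No ancestral-population haplotype LD, no phasing, no X-chromosome
  special-casing, no reference-panel models.
* The HMM plugs in point estimates of frequencies and θ; credible
  statements about posterior uncertainty in those quantities are outside
  its scope.
* Family structure is handled by subsampling, not by kinship models.
* The occupancy model's [X] anchor is per-motif, not genome-wide; absolute
  occupancies are therefore comparable within a motif, not across motifs.
* The cases-only scan assumes the HMM's own prior is the correct
  genome-wide reference; systematic θ̂ bias would shift LOD scores.
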