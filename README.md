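# admixlpa

Admixture mapping of a positive, log-normal serum trait (modeled on
lipoprotein(a)) in a recently admixed cohort, implemented end to end as a
tested Python library plus numbered analysis drivers. It is written for
statistical geneticists who want a self-contained, simulation-backed
version of the full analytic chain: cohort simulation with known ground
truth, local-ancestry inference, a cases-only admixture scan, ancestry- and
genotype-trait association, ancestry-mediation variance partitioning,
survival power analysis, and allele-aware transcription-factor occupancy
scanning.

## The models

**Local ancestry.** Each individual draws a global African-ancestry
proportion θ ~ Beta(mean 0.83, sd 0.09). Along the genetic map each
chromosome copy follows a Markov process: ancestry switches at rate λ per
Morgan and is redrawn from Bernoulli(θ). The African-allele count
a ∈ {0,1,2} at a marker is inferred by forward–backward over the diploid
chain, with genotype emission P(g | a) the convolution of Bernoulli(f_afr)
over African copies and Bernoulli(f_eur) over European copies. θ̂ itself is
the grid maximum of the marker-independent likelihood ∏_m P(g_m | θ·f_afr +
(1−θ)·f_eur).

**Cases-only scan.** With cases the top quintile of sex-adjusted log trait,
the per-locus statistic is a Bayes factor averaging over ancestry risk
ratios ψ: for case i, BF_i(ψ) = Σ_a p_ia ψ^a / Σ_a π_ia ψ^a, where p is the
locus posterior and π the Hardy–Weinberg prior from θ̂_i. LOD =
log₁₀(mean_ψ ∏_i BF_i(ψ)); peaks above LOD 5 are significant, and a 95%
credible interval accumulates 95% of the normalized 10^LOD area around the
peak.

**Association.** All models act on ln(trait) residualized on sex. Effects
are quoted as percent change per unit: effect% = 100·(e^{βΔ} − 1). SNPs are
tested by nested-model ANOVA (ancestry covariates vs + genotype, additive
coding).

**Mediation.** For a SNP set G, π = 1 − R²_geno / R², where R² is the
adjusted R² linking local African dosage to the sex-adjusted trait and
R²_geno the same after residualizing the trait on G. π is the fraction of
the ancestry–trait association the genotypes explain; it is estimated
honestly by five-fold cross-validation (discovery / stepwise model building
/ held-out evaluation on resampled unrelated groups), with two-fold CV for
single-SNP variance explained.

**Survival power.** Exponential survival times with hazard ∝ HR^g, the
censoring threshold placed so every simulated cohort has exactly the target
event count, and power the fraction of per-allele Cox Wald tests below α.
A reference HR per c-fold trait change rescales as HR^{ln c′ / ln c}.

**Occupancy.** A PWM window scores s = Σ_j ln(f′_{b_j j} / p_{b_j});
binding follows the isotherm p = [X]/([X]+K_d) with [X] anchored at the
optimal site's K_d, so p = 1/(1+e^{s_max−s}) and a consensus site sits at
exactly 50%. SNP flanks (20 bp each side) are scanned on both strands; an
allele-specific hit needs occupancy > 0.20 and an allele difference > 0.20.

## Worked example

The numbered drivers run the whole chain on a simulated 4464-person cohort
(600 ancestry-informative markers on 10 chromosomes; three
frequency-differentiated trait SNPs at one locus, 25.4% per allele each):

```sh
python analysis/01_simulate_cohort.py   # raw cohort -> scratch/cohort/
python analysis/02_infer_ancestry.py
python analysis/03_admixture_scan.py
python analysis/04_snp_association.py
python analysis/05_variance_partition.py
python analysis/06_chd_power.py
python analysis/07_tfbs_scan.py
```

Selected output (summary tables land under `results/`):

```
max LOD 17.8 at chr6:32000000 (significant at LOD>5)
95% credible interval: chr6:31000000-32000000
peak ancestry, cases 90.2% vs controls 73.3% (p=8.8e-53)

global ancestry: +11.9±1.4% per 10% (p=1.1e-18)
local ancestry | global: +9.6±0.6% per 10% (p=2.5e-55); global | local p=0.17

R2(ancestry) 0.0693 -> after genotype adjustment 0.0096; pi = 0.86
single-SNP variance explained (two-fold CV): 4.8±0.8%
ancestry association explained (five-fold CV): 91±9%

HR 1.22 per doubling -> 1.067 per one-allele (25.4%) change
power at alpha=0.05 over 1000 iterations: 12.3% (MC se 1.0%)
```

Reading this: the scan finds the trait locus (and only it) genome-wide
significant, with cases carrying far more African ancestry there than
controls; the local-ancestry term absorbs the global-ancestry association
(global p = 0.17 once local is in the model), as expected when
frequency-differentiated SNPs at the locus drive the ancestry effect; the
lead SNP alone explains ~5% of trait variance out of sample while the
three-SNP model explains ~90% of the ancestry association; and a
prospective Cox study with 389 events would have only ~12% power to detect
the hazard ratio implied by a 25%-per-allele trait effect.

The same stages are available as a CLI (`admixlpa simulate / ancestry /
scan / power / tfbs / run`) for file-based workflows.

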