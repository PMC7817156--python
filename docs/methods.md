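# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Score model and inference

The (weighted or unweighted) genetic score of individual *i* is treated as a
binomial proportion with trials m_i, the number of panel SNPs genotyped in
that individual, and logit-linear mean in date (years BP), latitude,
longitude and ten principal components. For the weighted score the success
count m_i·S_i is non-integer; the likelihood is evaluated identically with the
combinatorial constant dropped (it does not involve the coefficients), and the
MLE is found by iteratively reweighted least squares with the trials as prior
weights. Convergence is a maximum coefficient change below 1e-8 within 100
iterations; hitting the cap (which is also how complete separation manifests)
clears the `converged` flag. Covariate columns are scaled to unit SD
internally — an exact reparametrization that keeps the normal equations well
conditioned when dates are in years — and coefficients and standard errors
are mapped back. Standard errors come from the observed information; they are
reported but *inference on the date term never uses them*, because residual
overdispersion across individuals makes them anticonservative.

Inference instead uses a genome-wide empirical null: B random panels, each
matching every trait SNP by effect-allele frequency within ±0.01 and keeping
the trait effect sizes as weights, are rescored and refitted under the
identical design. Matching is without replacement within a panel and with
replacement across panels. The one-sided p is (1 + #{null at least as extreme
toward decline})/(B + 1); the add-one keeps p > 0 and an observation beyond
all nulls is reported as a bound ("P < 1/B"). With date coded in years BP a
decline toward the present is a positive date coefficient, so "more extreme
toward decline" means a larger null coefficient. A batched IRLS solver fits
hundreds of null replicates against one shared design matrix at once, which
is what makes B = 10,000 nulls routine.

Ancestry groups use the cutoffs: hunter-gatherer when that component exceeds
60%; Steppe when it exceeds 30% *and* the sample is younger than 5,000 BP
(overriding an Early Farmer component above 60%); Early Farmer above 60%
otherwise; else unassigned. The hunter-gatherer/Steppe conflict has no
defined precedence, so it is resolved to hunter-gatherer with a warning.
Group slope differences are tested through group×date interactions in a
pooled model, with the interaction refitted on the same matched null panels —
a documented package choice, since no method is prescribed for that
comparison.

The per-SNP model is Bernoulli logistic (allele presence on date + PCs, no
latitude/longitude), with likelihood-ratio tests against nested models: drop
the date term for the date p (1 df), drop the PC block for the ancestry p
(10 df). Monomorphic SNPs and SNPs with fewer than 30 calls are skipped with
a code. The effect-size-vs-frequency-change regression (OLS of |date
coefficient| on |GWAS β|) excludes non-converged per-SNP fits, whose
coefficients are arbitrary under quasi-separation.

## PCA covariates

PCs are fitted on a complete (or mean-imputed) reference panel with SNP-wise
centering by mean dosage and scaling by sqrt(f(1−f)), then incomplete
pseudohaploid samples are projected by least squares on the loadings
restricted to each sample's called sites (at zero missingness this equals the
fitted scores exactly). Component signs are fixed by making the
largest-magnitude loading positive. Samples covering under 10% of model SNPs
are excluded. One caveat verified during calibration: PCs must be built from
SNPs disjoint from (or at least overwhelmingly larger than) the set of SNPs
being tested per-SNP, otherwise the PCA is self-referential and the ancestry
LRT becomes anticonservative.

## PBS scan

Hudson's estimator is used exactly as defined (it can be negative; negative
values are kept so genome-wide percentiles are honest, giving T < 0 through
T = −ln(1 − FST), natural log). Window FST is the ratio of summed numerators
to summed denominators over a window's informative SNPs — the standard
aggregation for Hudson-type estimators — with SNPs above 90% missingness
excluded first, windows formed from 20 (or 40) consecutive retained SNPs
within a chromosome, and trailing remainders dropped. A window is "centered
on" a SNP when the SNP is its ⌈size/2⌉-th member. When source frequencies
come from an ADMIXTURE-style P matrix, the effective per-source sample size
at a SNP is the sum of ancestry fractions of the individuals called there
(haploid counts) — a documented convention, as no standard exists.

## Qx

Mean genetic values Z_pop = 2Σβf are centered across populations and scaled
by sqrt(V_A), V_A = 4Σβ²ε(1−ε) with ε the across-population mean frequency.
The neutral covariance averages outer products of centered frequencies scaled
by sqrt(ε(1−ε)) over genome-wide SNPs; because of the centering its rows sum
to zero, so the statistic is formed on an orthonormal (n_pop − 1)-dimensional
contrast basis, Cholesky-whitened, and summed as squares: chi-squared with
n_pop − 1 df under drift. The empirical p draws panels matched on pooled
minor-allele frequency (±0.02), keeps the observed effect sizes, and counts
null Qx values at least as large. Frequencies of matched null SNPs are used
as stored (no allele flipping); matching on MAF makes the null panels
exchangeable with the trait panel under neutrality, which the calibration
tests confirm.

## Synthetic-data generator

The generator emulates the study conditions end to end. All SNPs start from
an ancestral frequency drawn uniformly on (0.05, 0.95). Three source
populations drift independently for 250 generations at Ne = 10,000, then
continue drifting (binomial sampling of 2Ne gametes per generation) through
the sampling window, 15,000 years at 29 years/generation. Two outgroups drift
2,200 and 1,600 generations. These spans were anchored to published FST
scales — source-source FST ≈ 0.05, European-African ≈ 0.15,
European-East-Asian ≈ 0.11 — rather than tuned to any test.

Selection is directional on the light (non-effect) allele: the deterministic
update q' = q(1+s)/(1+sq) precedes drift each generation. Presets:
`neutral` (s = 0 everywhere — the master calibration condition), `sweep-top`
(s = 0.02 at the 5 largest-|β| SNPs in every source through the sampling
window), `branch-selection` (s = 0.05 at the single largest-effect SNP in one
source, acting from the branch point, with the ancestral frequency of the
selected locus pinned at 0.55 so the completed sweep shifts that branch by
≈0.5), and `post-admixture` (selection starting at 5,000 BP). The
branch-selection preset also emulates hitchhiking: flanking SNPs within
250 kb receive an effective coefficient decaying as exp(−d/100 kb), the
deterministic analogue of a sweep footprint of order s/2r. Without it a
single shifted SNP is diluted ~1:19 inside a 20-SNP window and the scan has
little power — which is itself an accurate statement about sweeps without
linked footprints.

Individuals draw dates uniformly over the window; ancestry fractions follow a
piecewise-linear schedule (pure hunter-gatherer before 8,500 BP, Early Farmer
ramping to 75% by 5,000 BP, Steppe arriving after 5,000 BP and plateauing at
45%) with Dirichlet noise (concentration 50); geography is mildly
ancestry-correlated. Each SNP yields one Bernoulli pseudohaploid call from
the ancestry-weighted source frequency at the individual's generation
(null-SNP trajectories are snapshotted every 5 generations; trait SNPs at
full resolution), and calls are dropped independently with probability
exp(−coverage), coverage being lognormal(0, 1) — median 1×, ~1% of samples
below the 0.1× QC cutoff. Effect sizes are a 5%/95% mixture of
normal(0.5, 0.15) magnitudes and exponential(0.04) magnitudes, i.e. a few
large effects over a polygenic background, with standard errors scaled to a
356,530-sample GWAS.

What the generator does **not** emulate: linkage disequilibrium among null
SNPs (except the sweep footprint), aDNA damage and contamination, non-uniform
sampling through time, date uncertainty, and reference bias. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the stated model, not that real-data complications are handled.

## Problem sizes and tolerances

The calibration suite runs one neutral study of 300 individuals × 20,000 null
SNPs × 100 trait SNPs, with 500 empirical-null replicates at B = 200 (fresh
trait-panel draws from the shared null pool — the exchangeability being
tested concerns the panel draw, not the genome), 200 Qx replicates, 500
per-SNP LRTs on a no-structure variant, and six PBS genomes of ~1,000 windows
each. Power and localization checks use 50 replicates at the sizes stated in
their docstrings. Exact formula checks use 10,000 random inputs at 1e-12;
the GLM is checked against direct numerical maximum likelihood at 1e-6.
Scores are clipped to [0, 1] against float rounding at the boundaries;
FST = 1 windows have T capped with a flag; empirical p-values use add-one
smoothing throughout.

## Known limitations

- The leave-top-k attenuation exceeds 100% in individual replicates whenever
  the residual panel's date coefficient crosses zero; only its expectation is
  monotone in k.
- The IBS duplicate-detection Z score is self-contaminating in small cohorts:
  below ~100 samples the duplicate pair inflates the SD of the maxima and a
  true duplicate can fall short of Z = 7. The rule behaves as intended at the
  cohort sizes it was designed for (hundreds to thousands).
- Least-squares PC projection is a stand-in for shrinkage-aware projection;
  it is adequate for covariate construction but mildly overdisperses
  high-missingness samples along late PCs.
- The curated multi-ancestry panel shipped under `data/` is a synthetic
  stand-in (real coordinates and effects are not distributable); it exercises
  the unweighted-score path only.
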