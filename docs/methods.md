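# Methods

This note documents the models behind each stage, the defaults and why,
what the synthetic generators do and do not emulate, and the numerical
choices a maintainer would want to know.

## Simulated RIL populations

Lines descend from the F1 of two fully inbred founders by explicit
generational selfing (default 10 generations, an F2:11 design), so
residual heterozygosity ≈ 0.5¹⁰ ≈ 0.1% survives into the calls and
downstream code is exercised on rare heterozygous calls, as in real lines.
Meiosis places a Poisson(L) number of crossovers (L = genetic length in
Morgans) uniformly on the genetic map, mapped to bp by linear
interpolation; there is no crossover interference, so simulated distances
are Haldane-consistent. The `map_function` field names the convention used
when converting between cM and recombination fractions elsewhere; it does
not alter the crossover process. Truth is retained as per-line diplotype
mosaics (exact float breakpoints plus genotype states), which every
recovery test measures against.

Genotyping error is a symmetric substitution among {AA, AB, BB} (default
1%) followed by masking to missing (default 2%). Neither rate is reported
for the emulated study design; these are nominal resequencing values and
are exposed in `SimConfig`.

**Phenotypes.** y_ijr = μ + Σ_q (a_q + dev_qj)·x_iq + env_j + ge_ij +
ε_ijr, with x ∈ {−1, 0, +1} signed toward parent 1 and heterozygotes at
the additive midpoint (0). Given the realized genetic variance V_G, the
random G×E and residual variances are scaled so the entry-mean
heritability h² = V_G/(V_G + V_GE/n_E + V_e/(n_E·n_R)) hits `target_h2`
exactly in expectation; `ge_variance_fraction` (default 0.25) splits the
non-genetic budget between G×E and residual. With one environment the G×E
share is forced to zero. With no QTLs the trait is pure noise at
`residual_sd`.

**Structured panels.** Accessions are fully inbred (one haplotype,
doubled). Subpopulation allele frequencies follow Balding–Nichols
(Beta((1−F)p/F, (1−F)(1−p)/F) around Uniform(maf_floor, 1−maf_floor)
ancestral frequencies). Linkage disequilibrium comes from latent Gaussian
AR(1) processes along the chromosome with autocorrelation
exp(−d/`ld_decay_bp`): one sheet per accession (haplotype state), one per
subpopulation (drift), and one for the ancestral frequencies, the latter
two pushed through Gaussian copulas so the per-site marginal frequencies —
and therefore Fst — are exactly Balding–Nichols. A haplotype-copying pool
was considered and rejected: a finite founder pool adds ≈ 1/K extra drift
on top of the Fst target, whereas the copula construction keeps Hudson-
estimator recovery of the target Fst within sampling error while giving
the same tunable exponential r²-vs-distance decay. The generators do not
emulate admixture gradients, selection, call-rate variation correlated
with relatedness, or unequal subpopulation sizes beyond rounding.

## Window correction

The rule is literal: a window of W = 15 consecutive SNPs centred on the
focal position; count(AA) ≥ 11 ⇒ AA, else count(BB) ≥ 11 ⇒ BB, else AB
("fill and correct", so missing focal calls are always filled). Missing
calls inside the window are excluded from the counts but the threshold is
not rescaled for them — windows depleted by missingness conservatively
yield AB. Boundary windows are truncated with the threshold scaled
proportionally, T′ = ⌈T·w/W⌉, preserving the 11/15 majority fraction at
chromosome ends; a chromosome shorter than W degenerates gracefully to a
whole-chromosome window. Every position is evaluated against the original
track, so corrections cannot cascade within a pass and the result is
independent of sweep order.

One pass is the default. Iterating the rule does **not** converge: the AB
fill around every true junction (where neither homozygote class can reach
11/15) widens by about three SNPs per side per pass, without bound.
`correct_until_stable` exists to measure and report this honestly; the
pipeline never iterates.

## Bins and the linkage map

Breakpoints are midpoints between consecutive informative (homozygous)
SNPs whose state flips; an AB/missing run between opposite homozygous
states is crossed by a single breakpoint at the run midpoint (unbiased
absent further information). Bin edges are the union of all lines'
breakpoints plus the chromosome ends (position 0 and one past the last
SNP — chromosome physical lengths are not part of a call matrix). A bin's
genotype is the consensus homozygous state, AB when only heterozygous
calls are present, missing when uninformative; conflicting homozygotes
(possible only through residual error) fall back to majority with ties to
AB.

Filters: length < 10 kb, and χ² goodness-of-fit against 1:1 AA:BB at
p < 0.001 (AB/missing excluded). A rescue pass restores the longest
rejected bins on any chromosome whose retained density falls below 1 bin
per 2 Mb — the intent of "add some bin markers with unfixed parameters"
made concrete, with the floor exposed in config.

Adjacent-bin recombinant fractions count only lines homozygous and
non-missing at both bins (selfed-RIL theory assumes homozygotes; residual
heterozygosity is ~0.1%). R inverts to meiotic r = R/(2(1−R)), clamped to
[0, 0.4999]; fewer than 10 scorable lines flags the interval
low-confidence. Distances are Kosambi, d = 25·ln((1+2r)/(1−2r)) cM, with
exact inverse r = ½·tanh(d/50). Marker order is inherited from physical
position rather than re-estimated — justified a posteriori by the
Spearman collinearity statistic the package itself computes (≈ 1.0 on
simulated data). Per-group "average distance" is total distance divided by
bin count (not count − 1); the published per-group rows verify this
convention.

**Scale caveat.** Bin-boundary precision is limited by the AB fill width
(~6 SNPs per junction), so simulations must keep SNPs-per-junction well
above the window size. The test populations use 100 SNPs/cM at 158 lines
(~30 SNPs per bin), a conservative miniature of real resequencing density
(~300 SNPs/cM); at unrealistically sparse density the fill swallows whole
bins and map length collapses.

## QTL scans

CIM is Haley–Knott regression: expected signed dosage at each 1-cM grid
position given the flanking bins, with RIL-scale transition probabilities
R = 2r/(1+2r) from Kosambi-inverted distances; heterozygous or missing
flanks are treated as uninformative. Cofactors are the five bins chosen by
forward stepwise regression (largest RSS reduction ≡ largest partial F,
ties to the first bin); at each test position, cofactors within 10 cM on
the same group are masked. LOD = (n/2)·log₁₀(RSS_reduced/RSS_full);
PVE = 100·(RSS_reduced − RSS_full)/TSS — a regression R² definition,
documented because mixture-likelihood software may differ slightly. The
additive effect is the dosage coefficient: half the AA-vs-BB difference,
signed toward parent 1.

Permutation thresholds shuffle the phenotype against the intact genotype
matrix (preserving marker LD) and re-select cofactors each time; the
threshold is the empirical (1−α) quantile (method "higher", so α = 1
returns the minimum and the threshold is monotone in α). Peaks are local
maxima above threshold separated by at least the cofactor window; support
intervals use the 1-LOD drop, a conventional choice where no definition is
published. The level experiment gives every null replicate its own
permutation threshold — a single shared threshold has large conditional
variance (measured type-I 0.015–0.10 across genotype draws at nominal
0.05) and does not measure the procedure's level.

The multi-environment scan is a two-stage inclusive procedure: cofactors
from stepwise regression on the environment-centred stacked phenotype,
then a joint model per grid position with environment mains, the shared
dosage, and dosage×environment terms. The joint LOD compares full vs
no-QTL models; additive and interaction PVE are the sequential RSS drops
over the stacked TSS. Replicates are averaged; lines missing any
environment are dropped from the joint model.

## Mixed-model association

Kinship is the VanRaden centred GRM (the emulated study names its tool but
not an estimator); for fully inbred panels the diagonal is ≈ 2. The
"relative kinship" report floors negatives at zero, which reproduces the
convention under which most unrelated pairs report exactly 0 — note that
with a centred GRM this flooring sends roughly half of even an
unstructured panel's pairs to zero, and nearly all cross-subpopulation
pairs.

EMMAX: δ = σ²ₑ/σ²_g is REML-estimated once under the no-SNP null by Brent
search on the profiled likelihood over the spectrum of the projected
kinship; every SNP is then a GLS t-test with V = σ²_g·K + σ²ₑ·I fixed
(missing dosages mean-imputed). At K = I this reduces exactly to OLS. The
approximation is excellent in its operating regime (typical effect sizes):
against exact per-SNP REML refits the median |Δlog₁₀p| is ~0.005 and rank
correlation > 0.99; at the strongest structure-confounded loci the exact
refit re-partitions the polygenic variance and can move p by 1–2 orders —
a known property of null-variance approximations, asserted as such (≥95%
of SNPs within one order) rather than hidden. Structure covariates (e.g.
external PCs) can be supplied; the default is kinship-only. Non-PSD
kinship is floored at zero eigenvalues with a warning.

LD r² is squared dosage correlation (inbred accessions ⇒ dosage ≈
haplotype; no phased EM estimation), pooled into distance bins; the decay
distance interpolates the first crossing of the reference level (0.2).
Haplotype analysis groups accessions by the joint allele string at the
defining SNPs, drops groups under 5, and tests with Welch's t (two
groups) or one-way ANOVA F.

## Trait statistics

Summaries use ddof-1 SD, SE = SD/√n, CV = 100·SD/mean, and bias-adjusted
sample skewness and *excess* kurtosis (the excess convention is inferred
from published values clustering near 0). Variance components solve the
expected-mean-squares equations on balanced data and fall back to REML
(statsmodels MixedLM; the genotype random intercept requires
`re_formula="1"` alongside the G×E variance component) otherwise; with a
single replicate per cell σ²_GE is confounded with error and reported as
0 with the residual absorbing both. Heritability is entry-mean:
h² = σ²_G/(σ²_G + σ²_GE/n_E + σ²ₑ/(n_E·n_R)), the standard for
multi-environment line trials; the emulated study reports only the number
(78.54%), not a formula. Published summary rows are shipped as data; two
of the 13 CVs differ from the printed value by 0.01 because the printed
mean/SD inputs are themselves rounded — checks therefore use a 0.015
band, the propagated half-ULP of those inputs.

BLUP line values fit μ + env (fixed, via environment means) + line
(random): each line's environment-adjusted mean deviation is shrunk by
λ_i = σ²_L/(σ²_L + σ²ₑ/n_i) with one-way EMS variance components, so
sparsely observed lines shrink hardest; σ²ₑ = 0 recovers the adjusted
means exactly. In a balanced design shrinkage is uniform and BLUP is a
monotone transform of the line means — the efficiency gain over raw means
appears only under unbalance, which is how the tests measure it.

## Candidate-gene triage

"Expressed" means any parent-timepoint FPKM > 0.5 (exposed); "coincident"
partner expression means Pearson correlation of log₂(FPKM+1) profiles
≥ 0.8 **and** identical DEG status (the source concept is used without a
definition; both knobs are config). Rules fire in a fixed order —
unexpressed → unique-gene retention (only when the syntenic region carries
no QTL) → coincident-partner exclusion (blocked by any coding-sequence
variant: missense or synonymous; regulatory-region variants deliberately
do not block) → DEG retention → default retention — so each gene gets
exactly one verdict and input order is irrelevant. The bundled fixture
reproduces a 24-gene, 180-kb interval with 8 unexpressed genes, 4 DEGs,
one missense variant, and documented syntenic pairs; the expressed
non-DEG filler genes carry coincident partners so that triage resolves to
exactly three candidates.

## Problem sizes and determinism

Validation experiments run on one CPU: 158-line populations on two 50-cM
chromosomes at 100 SNPs/cM; 200 null replicates × 200 permutations for
the CIM level; 50 replicate populations for QTL recovery; 50–204
accession panels for the association checks — about two minutes
altogether, chosen as the smallest sizes at which the binomial/sampling
error of each measured rate is comfortably inside its assertion band. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; same seed ⇒ byte-identical outputs (the
pipeline manifest records digests to prove it).

## Known limitations

- No crossover interference, so simulated Kosambi distances are exact only
  in the small-r limit; assembled map lengths are validated to 15%.
- Bin-boundary precision is bounded by the AB fill width; see the scale
  caveat above.
- EMMAX is the single association model (no multi-locus or Bayesian
  alternatives); exact per-SNP REML exists only as a test oracle.
- The triage fixture is a synthetic reconstruction of a published
  interval scenario, not the study's expression matrices; triage logic,
  not biology, is what it validates.
- Read-level simulation, variant calling, marker-order estimation and
  population-structure inference (ADMIXTURE-style) are out of scope by
  design; physical coordinates supply marker order.
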