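# Methods

`admixstats` implements four statistical analyses of three-way admixed
genomes (African, European, Native American ancestry) together with a
synthetic-cohort generator that supplies ground truth for all of them. This
note records the models, the defaults and the reasoning behind the open
design choices.

## The synthetic cohort model

**Ancestral frequencies.** Each site's derived-allele frequency on the
African panel is drawn from a rare-skewed Beta(α=0.2, β=1.8) (mean 0.1, mass
concentrated near zero, mimicking a deep-coalescence frequency spectrum).
European and Native American frequencies derive from the African value
through a Balding–Nichols transform: p_k ~ Beta with mean p_AFR and variance
F_k·p_AFR(1−p_AFR), with drift coefficients F_EUR = 0.10 and F_NAM = 0.15 by
default — the scale of F_ST created by the out-of-Africa and American
founder bottlenecks. Frequencies within 10⁻³ of the boundary are clamped to
0 or 1, so bottlenecked panels genuinely lose and fix alleles: they
segregate fewer sites but carry more fixed/homozygous derived alleles, while
the transform preserves the mean frequency. These two facts together produce
the burden structure the load analysis tests (more heterozygotes on African
backgrounds, more derived homozygotes on European ones, flat totals).

**Selection proxy.** Conservation scores are standard normal at non-coding
sites and a heavier-tailed mixture at coding sites (75% N(0.3,1), 25%
N(2,1.5²)). Purifying selection is modelled as a frequency reduction
exp(−s·max(score,0)) applied to the African base frequency before drift
(default s = 0.3, i.e. roughly a 60% frequency reduction at a score of 3).
An optional African-panel-specific extra factor at coding sites
(`sel_coding_afr`) creates ancestry-differential constraint; it defaults to
0 and is switched on only in the stratified-proportion studies.

**Novelty.** A site is "known" with probability increasing in its mean
frequency across panels and reduced by a factor 0.35 when it segregates only
on the African panel — the discovery-bias structure that makes novel alleles
cluster on African backgrounds.

**Local ancestry.** Each haplotype follows a Markov chain along a uniform
1 cM/Mb map: switch events arrive at g per Morgan (g = generations since a
single admixture pulse, default 8) and redraw the ancestry from the
individual's proportions q, so the chain is stationary with tract lengths
Exponential(mean 100/g cM). Because a redraw can repeat the current
ancestry, the *observable* tract of ancestry k has mean 100/(g(1−q_k)) cM —
the identity the tests assert. The two haplotype labels collapse into the
0–6 unordered diplotype code (0 unknown, 1 EUR:EUR, 2 EUR:AFR, 3 AFR:AFR,
4 EUR:NAM, 5 AFR:NAM, 6 NAM:NAM). Code 0 is injected at a configurable rate
(default 0) to exercise degenerate handling.

**Sex-specific contributions.** Female and male ancestral contribution
simplexes s_f, s_m give the expectations q_auto = (s_f+s_m)/2 and
q_X = (2s_f+s_m)/3. Individual proportions are Dirichlet around these with
concentration 30 (individual ancestry sd ≈ 0.07 at q = 0.8, matching the
within-population spread of admixed cohorts). Genotypes at a site with
diplotype (a,b) are Bernoulli(f_a)+Bernoulli(f_b); male X is a single draw
encoded 0/2 with a hemizygote flag. Missing calls are injected at rate 0.005.

**What the generator does not emulate:** linkage disequilibrium beyond
ancestry tracts (genotypes are independent given the mosaic), genotyping
error, multi-allelic sites, recent continuous migration, and relatedness.
Passing tests therefore demonstrate correctness of the statistics under the
admixture model, not robustness to those real-data complications.

**Seeding.** One master seed; each stage (panel, global ancestry, sex,
local ancestry, genotypes, missingness) uses a child generator derived via a
CRC-keyed SeedSequence, so runs are bit-reproducible and stages are
independently perturbable.

## Variant catalogue

Allele counts use sex-aware denominators (1 chromosome for male X). MAF
classes follow the convention: singletons (derived count exactly 1; a
carrier-count-1 alternative sits behind `singleton_mode="carrier"` because
"observed in a single individual" is ambiguous — allele-count-1 matches
standard SFS usage), MAF<1% exclusive, 1%≤MAF≤5% inclusive both ends,
MAF>5%. Sites with low-confidence ancestral calls are excluded from all
derived-allele analyses but kept in MAF accounting. The SFS is built over
autosomes; with missing data it either restricts to complete-call sites or
hypergeometrically projects each site down to a common chromosome count
(the pipeline projects to the 5th percentile of called counts).

## Discovery rarefaction and projection

Rarefaction is the exact hypergeometric expectation of the number of sites
*polymorphic* in a subsample of n of N chromosomes:
E[S(n)] = Σ_i ξ_i (1 − [C(N−i,n)+C(i,n)]/C(N,n)). Both monomorphic terms are
subtracted because a subsample fixed for the derived allele reveals no
variant; with the neutral spectrum ξ_i = θ/i this reduces exactly to
θ·H_{n−1}, the partial harmonic series. Combinatorics are computed as
lgamma differences, safe for spectra with millions of sites.

Projection beyond N uses a Newton-forward extrapolation whose backward
differences at n = N have the exact closed form
∇^j E[S](N) = (−1)^{j+1}(ξ_j + ξ_{N−j})/C(N,j), giving

    Ŝ_k(M) = S_obs + Σ_{j=1..k} C(M−N+j−1, j) (−1)^{j+1} (ξ_j + ξ_{N−j}) / C(N,j).

The projection therefore depends only on the spectrum's edges — the
low-frequency tail that encodes undiscovered variation. The order is chosen
by a stability rule: the smallest k (capped at 5) whose successive
projections differ by <1%, else the k with the smallest successive change;
the full order-by-order table is returned as a diagnostic. Because true
discovery is non-decreasing in sample size, projections are floored at
S_obs, which also makes the reported discovery gain non-negative. The
weights are validated against an exhaustive subsampling oracle and against
direct simulation truth rather than against any published weight table.

## Doubleton sharing

Doubletons are sites with exactly two derived copies and missingness ≤5%
(inclusive). Two single-copy carriers define a pair-type doubleton and
increment that pair's cell; a single homozygous carrier is self-type and is
excluded from the pair matrix (no pair is defined) but reported separately,
so both the pair-only and the inclusive total are available.
Population-level sharing divides summed pair counts by n(n−1)/2 within and
n₁n₂ between populations; single-individual populations yield an undefined
(NaN) within cell.

## Deleterious burden

The deleterious cutoff is the 99.9th empirical percentile of the
conservation score by nearest rank (deterministic; a linear-interpolation
variant is available), with sites *at* the cutoff deleterious. Robustness
modes intersect the conservation flag with CADD ≥ 30 (99.9th percentile) or
CADD ≥ 20 (99th). Burden profiles count heterozygotes and derived
homozygotes per individual over flagged diploid calls — hemizygous male-X
entries are excluded so n_derived = n_het + 2·n_homder holds exactly —
split by coding class, and are correlated with African ancestry by Spearman
rank (average ranks, t-approximation p). Stratified proportions use only
the unambiguous backgrounds (codes 3 and 1): deleterious derived copies
over all derived copies per individual per background, compared by
two-sided Mann–Whitney with continuity correction. Proportions weight all
sites equally (no callable-length weighting).

**Scale-down for simulation studies.** The burden pattern is driven by the
*number of flagged sites* L: the het/homder correlations grow like √L while
the drift-realisation noise on the total-burden correlation does not shrink
with L (sd ≈ sd(q)·√(2F) per cohort). The real-genome analysis flags tens
of thousands of sites; at a 5×10⁴-site synthetic genome a 99.9th-percentile
cutoff would flag ~50 — powerless by construction. The simulation studies
therefore flag the top 2% (~1,000 sites), matching the flagged-count scale
rather than the percentile, use a three-population cohort spanning African
ancestry 0.2–0.8 (CAAPA-like spread, ancestry sd ≈ 0.25), and summarise 10
replicates by mean correlations with Stouffer-combined p-values; the
total-burden flatness is asserted on the replicate mean for the same
reason. The null study (no drift, no selection) checks per-component
calibration across 100 replicates of ~400 individuals.

## Sex-biased admixture

Ancestry proportions are estimated per individual by maximum likelihood
under the supervised binomial admixture model (allele copy from ancestry k
with probability q_k, derived with the fixed panel frequency f_ks), via the
classical EM recursion on the simplex. Initialisation is the barycentre
(1/3,1/3,1/3); convergence when an individual's log-likelihood improves by
<10⁻⁶, capped at 1,000 iterations; converged individuals are frozen while
the rest iterate. The log-likelihood is non-decreasing by construction, the
update preserves the simplex, and relabelling ancestries together with
their panels permutes the estimates (asserted to 10⁻¹²). A panel with no
frequency differentiation raises a non-identifiability error. With ~10⁴
informative sites the estimator shows mild shrinkage of extreme proportions
toward the interior — visible in the examples — which the paired contrast
tolerates because both scopes shrink in the same direction.

The X-vs-autosome contrast is computed on females only (diploid X against
diploid autosomes): per ancestry, a paired t-test on q_X − q_auto, Bonferroni
over the number of tests actually run (components × populations by default;
configurable because published analyses have used study-specific counts,
e.g. 57). X > autosome flags a female-biased contribution of that ancestry,
X < autosome male-biased. Type-I calibration and power are verified on
cohort-level truth proportions (the test's input contract), not on EM
output, to keep the 1,000-replicate calibration study tractable; estimator
accuracy is verified separately.

## Numerical and degenerate-input choices

- Percentile rank uses a 10⁻⁹ round guard before the ceiling so exact-integer
  ranks are not inflated by floating point.
- Zero-variance paired differences: t = 0, p = 1 when the mean difference is
  also zero (flagged degenerate), otherwise reported as a degenerate
  no-test.
- Constant vectors make rank correlations undefined and raise.
- All-equal conservation scores flag every site and emit a warning.
- Sites with zero called chromosomes are flagged non-segregating and drop
  out of downstream analyses.
- Positions are 1-based VCF coordinates throughout (a single convention,
  rather than converting at the I/O boundary); phased separators are treated
  as unphased; multi-allelic records are skipped and counted.

## Problem sizes

The verification studies run at: 200 random spectra (N ≤ 12) against the
exhaustive oracle; harmonic identity at N = 40; 20 projection replicates at
2,000/1,000 chromosomes; doubleton oracle at 20×5,000; burden pattern at 10
replicates of ~200 individuals × 5×10⁴ sites; null calibration at 100
replicates of ~400 × 8×10³; stratified sign at 50 replicates of 100 × 5×10⁴;
sex-bias calibration at 1,000 replicates of 100 females and power at 100
replicates; estimator accuracy at 60 × 10⁴ sites. These sizes give each
check the power its tolerance needs while keeping the whole suite runnable
on a laptop in a few minutes.

## Known limitations

- Single-pulse admixture only; no continuous migration, so g is a tract-scale
  parameter, not an estimate of any cohort's history.
- No linkage within ancestry segments; statistics whose null distributions
  depend on LD (e.g. genome-wide significance of burden correlations) are
  calibrated only under site independence.
- The jackknife order-selection rule is heuristic; the order table should be
  inspected when spectra are irregular.
- Doubleton sharing is reported as raw normalized counts; no coalescent-time
  interpretation is attached.
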