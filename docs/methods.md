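# Methods

## Scope and data model

The pipeline analyses pooled-sequencing allele-frequency time series of
two coevolving, exclusively asexual species — a eukaryotic microbial
host (~42 Mb genome, mostly non-coding) and a lytic dsDNA virus
(~330 kb, mostly coding) — grown together in chemostats with constant
dilution.  Inputs are (a) per-site nucleotide-count tables in the
popoolation2 `sync` dialect, one count block per sampling day, (b) daily
host/virus census counts, and (c) cross-infection growth-rate assays.
Analysis starts from counts: read QC, alignment and effect annotation
are upstream of this package, and structural variants are out of scope.

## Variant filtering

Because the populations start isogenic, every real signal is a derived
allele absent from the ancestor.  Filtering proceeds in a fixed,
audited order:

1. **Coverage mask** (per time point): sites with depth ≤ 10× or outside
   mean ± 3 SD are set to missing; a time point whose mean depth falls
   below 10× is dropped entirely.  Mean and SD are computed over the
   non-missing sites of the table being filtered, after any
   downsampling.  Deep virus data can first be binomially thinned to
   1000× mean coverage, which preserves expected frequencies and the
   shape of the depth distribution.
2. **Indel proximity**: ±10 bp (inclusive) around indel calls is
   discarded — alignment noise concentrates there.
3. **Ancestral purity**: any locus with derived frequency > 1% at day 0
   (ancestral allele < 99%) is treated as an artifact of the isogenic
   start and removed.  The comparison is strict, and a locus missing at
   day 0 cannot be assessed by this step and is retained.
4. **Detection limit**: a trajectory must exceed the coverage-scaled
   threshold (0.05 virus, 0.25 host by default; both configurable) at
   more than one time point; pooled low-frequency counts are otherwise
   indistinguishable from sequencing error.
5. **Missingness**: more than 1 (virus) or 3 (host) missing time points
   disqualifies a locus.

Each step's removals are returned in a ledger, and
input = output + Σ removed is asserted in the test suite; filtering is
idempotent.  The derived allele of a site is the nonreference base with
the highest mean frequency across time points, ties broken by the fixed
order A<C<G<T for determinism.  A zero-coverage count block means
"not observed", never "0%".

SNPs within 1000 bp whose trajectories correlate at Pearson r ≥ 0.9
over at least three shared non-missing time points are collapsed
(single-linkage components) into one row with member-averaged
frequencies and the most severe member effect
(nonsense/frameshift > missense > synonymous > intergenic); the member
list is retained so clusters can be dissolved.  The correlation measure
and its threshold are deliberate choices exposed in `FilterConfig`;
"move together within a kilobase" is the operational definition of a
candidate structural event observed as multiple SNPs.

## Diversity, sweeps and selection

Nucleotide diversity is the mean expected heterozygosity
π(t) = ⟨2p(1−p)⟩ over the variable loci with data at t.  No
genome-length normalisation is applied: only relative changes through
time are interpreted, and the constant factor cancels.  A sweep is
called when π falls by at least a threshold fraction (default 50%)
between consecutive time points; the detector works on ratios and is
scale-invariant.

Selection coefficients use a haploid single-locus model with Malthusian
fitness w = e^s: one generation maps p to p·e^s / (p·e^s + 1 − p), so
logit p increases by exactly s per generation and

s = [logit(p₁) − logit(p₀)] / Δgenerations.

The Malthusian convention was chosen over the discrete w = 1+s
parameterisation precisely so that this log-odds estimator is exact for
the model that generates the data (under w = 1+s it estimates ln(1+s),
a 19% downward bias at s = 0.5); both organisms are asexual, so the
sweeping genotype behaves as a single haploid allele.  Frequencies at
the boundary are clamped to half the detection limit and flagged.
Generations default to 1 per day (~100 days ≈ 100 generations).

Census counts are log10-transformed and smoothed with natural cubic
splines (zeros, e.g. virus before introduction, are excluded from that
species' spline); growth at day d is the smoothed log10 change over the
3 days leading up to d, matching the genetic sampling cadence.  The
association between the binary neutral-fit indicator and growth is a
binomial GLMM with a per-replicate random intercept, fitted by
variational Bayes (statsmodels `BinomialBayesMixedGLM`); with a single
replicate, or on fit failure such as complete separation, it falls back
to a fixed-effects logistic fit with a warning.

## The neutrality-curve test

For a neutrally expanding population the cumulative number of variants
at frequency ≥ f follows M(f) = (μ/β)(1/f − 1/f_max), the cumulative
form of the Luria–Delbrück mutant-frequency distribution, with μ the
per-division mutation rate and β the effective surviving-offspring
rate.  The test takes the variants inside the analysis window
[f_min, f_max] = [0.05, 0.40], computes the empirical cumulative count
M̂(f) (variants with frequency ≥ f, so M̂ is decreasing like the closed
form), normalises y = M̂/max(M̂) and transforms
x = (1/f − 1/f_max)/(1/f_min − 1/f_max).  Restricting both the counts
and the transform to the window makes the true f_max of the underlying
process cancel, so under neutrality the points lie on y = x regardless
of μ, β or the age of the expansion.

Goodness of fit is the Kolmogorov distance KS = max|yᵢ − xᵢ| plus the
trapezoidal area under the (x, y) curve (origin included).  A time
point passes with KS < 0.25 and AUC < 3.  On a normalised unit-square
curve the area cannot reach 3, so the KS criterion is the load-bearing
one; the AUC threshold is retained as a configurable guard with its
conventional default, since its original scale (raw counts vs
normalised area) is ambiguous.  Fewer than 5 window variants yields an
explicit "no call" — the virus case, where variants are too few for
distributional statistics.

Feasibility arithmetic: a neutral mutation can reach ~10% frequency
purely by hitchhiking only if it arises within the first ~10 divisions
of the sweeping cell, requiring a per-site per-division mutation
probability of roughly 1/(genome length × 10) — about 2.4×10⁻⁹ for a
42 Mb host genome (plausible) and 3.0×10⁻⁷ for a 330 kb virus genome
(why post-sweep diversity rebuilds in the host but not the virus).

## Replicate-overlap null

If de novo mutations are neutral and uniform over the genome, each
replicate's observed mutations are a uniform draw without replacement
from the evaluable positions (marbles from a vase).  The null
distribution of the number of positions shared by all (or ≥ 2)
replicates is simulated; the p-value uses the add-one estimator
(1 + exceedances)/(1 + n_sims), which is conservative and never reports
exactly zero.  A vase-size grid reports, for the empirical draw count,
the largest pool of mutable sites at which the observed recurrence is
unremarkable (p > 0.05).  The simulated pairwise mean is validated
against the exact hypergeometric expectation k₁k₂/N.

## Phenotype processing

A clone is susceptible to a virus population when mean + 2 SD of its
four virus-exposed technical replicates lies strictly below mean − 2 SD
of its virus-free controls, or when its exposed mean growth is negative;
SDs use n−1.  Resistance range is the fraction of assayed virus time
points a clone resists; infectivity range the fraction of assayed clones
a virus infects; over one complete call matrix the two means are exact
complements.  Match/mismatch intervals start from an initial match
(ancestral virus infects ancestral host): resistance evolution (hosts
newly resist past-and-contemporary virus, maintained at the next host
time point) opens a mismatch; infectivity evolution (virus newly
infects previously resistant hosts, maintained at the next virus time
point) opens a match.  Events are placed at the assay day where the
phenotype is first observed; phenotypes not maintained at the next step
are ignored, and presence of a phenotype means any clone carries it,
irrespective of frequency.  The trade-off between resistance and growth
is the Pearson correlation of virus-free growth with resistance range,
undefined (flagged) under zero variance.

## The forward simulator

**Branching expansion.** Generation-synchronous: every cell divides;
each daughter survives with probability (1+β)/2, giving expected growth
1+β per generation, and acquires Poisson(μ/2) new mutations at uniform
positions (μ per division).  Every mutated surviving daughter founds a
lineage carrying its parent's mutations plus its own; final VAFs are
subtree sums.  Two simplifications are deliberate: a daughter's
multiple simultaneous new mutations share one lineage, but mutations of
different daughters of the same division are independent lineages
(affects linkage between same-division mutations only, not the marginal
VAF spectrum); and extinction before the horizon is an explicit result,
not an error.  Binned variant counts are tested against the closed-form
density (μ/β)(1/a − 1/b) at three standard errors over 100 seeds.

Desk-scale defaults are μ = 5 substitutions/genome/division, β = 0.7,
26 generations from one cell.  These are the smallest settings at which
the final population reliably exceeds 10⁵ cells with ≥ 50 variants in
the 5–40% window — the regime where the KS statistic of a truly neutral
expansion stays below 0.25 in well over 90% of runs.  β matters
qualitatively: near β = 1 division is almost deterministic and the VAF
spectrum condenses onto atoms at 2⁻ᵍ, which a Kolmogorov test
(correctly) rejects; β = 0.7 provides enough reproductive noise to
smooth the spectrum while keeping extinction rare (~2%).  A real host
at μ ≈ 0.1/genome/division compensates with ~10⁴-fold larger
populations; the window statistics, not the absolute rates, are what
the analysis consumes.

**Clonal interference.** n cohorts with distinct selection coefficients
s_i are assigned fractions w_i ∝ (1+s_i)^g after g competition
generations (conditioning on the realised balance keeps the programmed
scenario reproducible).  Each cohort carries an internal
neutral-expansion spectrum rescaled by w_i plus private hitchhikers at
exactly w_i — the mutations accumulated along its selected line of
descent, Poisson(μ/2 × rise duration) with rise duration
log(cohort size)/log(1+s).  The hitchhiker mass at cohort frequencies
is what violates the power law: the rescaled continuous spectra alone
would still sum to a 1/f shape, so a simulator without this trunk
mutation load would not actually model the deviation that clonal
interference causes.

**Chemostat.** Discrete-time Euler recursion (default step 0.1 day)
over explicit genotype classes: logistic host growth (r = 1.2/day,
K = 2×10⁶), constant dilution (0.1/day), mass-action infection
(φ = 6×10⁻⁸ ml/particle/day), burst size 50, virus decay 0.5/day.
Genotypes form an arms-race staircase — virus type j infects host types
≤ j — and scheduled sweep events seed new types with 10 individuals.
Virus enters at day 12 at 10⁴ particles.  These rates were chosen once
to produce the qualitative regime the analysis assumes — damped
host–virus cycles spanning ≥ 2 orders of magnitude with a period of
~10 days, host recovery to carrying capacity after resistance fixes —
and the package makes no attempt to fit observed abundances.  The step
is validated against the fastest local rate each iteration and the
recursion aborts, naming `step_days`, rather than integrate an
unresolved dynamic; abundances are clamped nonnegative.

**Pool-seq observation.** Per site and time point, depth ~
Poisson(mean), derived reads ~ Binomial(depth, freq), and every read is
misread with the per-base error probability, uniformly to the other
three bases.  Monomorphic background sites are emitted so coverage
filters see a realistic site pool.  Missing population samples become
zero-coverage blocks.

**Scenario generator.** `simulate_coevolution_experiment` composes the
layers into one replicate sampled at days
{0, 6, 12, 18, 24, 30, 36, 44}: 200 standing variants at intermediate
frequencies (hitchhikers of the initial expansion, consistent with the
hundreds of variants such experiments detect before virus introduction)
arise by day 6 and decline as 1 − f_sweep; a sweep locus plus 5 linked
hitchhikers follow the resistant genotype's frequency f_sweep taken
from the chemostat (seeded day 16, fixation between days 24 and 30);
and a fresh branching-process spectrum rescaled by f_sweep models
diversity regenerated inside the expanding resistant cohort.  Host
coverage is 1000×, so the detection limit appropriate for this
synthetic host is 0.05.  Ground truth (true frequencies, sweep days,
f_sweep) is returned for every run.

What the generator does **not** emulate: genetic drift and bottleneck
purging during the host's ecological crashes (standing-variant
frequencies move only through the sweep term); within-cohort frequency
dynamics after the cohort saturates (post-sweep spectra are frozen);
later sweeps' genetic consequences (the second virus attack at day 40
changes ecology but not the host trajectory matrix); linkage between
the observation noise of nearby sites; and real coverage biases (GC,
mappability), which makes the coverage-outlier mask exercise only
Poisson tails.  Passing tests therefore demonstrate correct bookkeeping
and statistical behaviour of the estimators under their assumed models,
not robustness to every artifact of real sequencing data.

## Numerical choices and degenerate inputs

Pearson correlation for collapsing requires ≥ 3 shared time points and
nonzero variance, else the pair cannot link.  π over an all-missing
time point is missing, and sweep intervals skip missing time points.
The universal curve clips x into [0, 1] against floating-point
spill.  Susceptibility calls at exact rule equality are resistant
(strict "lower than").  All simulators draw from named generators
spawned from one seed (`SimConfig.rng("component")`), so a fixed seed
fixes every output byte and components are independently reproducible.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run 100-seed batches of
expansions to ~10⁵–10⁶ cells, 10⁵ overlap simulations, 10⁴-locus
filtering fixtures and single-replicate end-to-end scenarios — sizes
chosen so the statistical assertions (3-SE bands, ≥ 90% pass/fail
rates, < 10% recovery bias) are well resolved while a full run stays in
the minutes range on one core.
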