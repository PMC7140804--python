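# Methods

## Sleep phenotypes

Sleep is operationalised as any maximal run of ≥ 5 consecutive minutes with
zero beam breaks (`min_sleep`, configurable).  Per fly, per 24 h day and per
12 h phase we compute sleep time (min), bout number, mean bout length (min)
and waking activity (total beam breaks over awake minutes).  Bouts that span
the light/dark boundary are split minute-wise for sleep time — so a phase
can hold at most 720 sleeping minutes — while for bout *counting* the bout
is assigned to the phase of its onset minute (`bout_phase_rule="onset"`,
the common convention; a `"split"` rule that counts the bout in every phase
it touches is provided because the original choice is not documented
anywhere we could rely on).  Light/dark phase is protocol-defined (12h:12h,
lights on 08:00 by default); the DAM hardware light-sensor flag is retained
for QC only, since the assay's phases are set by the incubator programme,
not by the sensor.

Per-fly trait values are means over days (bout length over days with at
least one bout); genotype means are means over flies.  Bout-length traits
(LBL, DBL) get a log10 companion column computed on genotype means, used
for mapping because their among-fly variance grows with the mean.  A mean
of zero under the log transform is a hard error unless an explicit offset
is supplied — silently shifting data would change the trait definition.
A dead-fly filter (zero activity over the final 24 h) exists but is off by
default; no such exclusion is part of the assay definition.

DAM files are read strictly: gaps in the minute sequence are an error by
default (optionally zero-filled up to a configured limit, with filled rows
flagged) because fabricated zeros are indistinguishable from sleep.
Records with unexpected status codes are flagged, never dropped; status
semantics vary by firmware, so validity is configuration (`(1,)` by
default).

## QTL mapping

Genotype means are regressed, at each grid position, on the 16 additive
founder probabilities (8 maternal + 8 paternal) plus a subpopulation
indicator, and

    LOD = (n/2) * log10(RSS_null / RSS_full),

with the null holding intercept + covariates.  Each 8-probability block
sums to 1, so the full design is rank deficient; we drop the last column of
each block and, because only the column space matters for RSS, verify in
tests that the result matches a pseudo-inverse fit of all 16 columns.  All
projections go through an orthonormal basis of the design (SVD), so
additional rank loss (e.g., a founder absent from the sample) is handled
transparently.

Genomewide thresholds: genotype means are permuted against probability rows
*within subpopulation* (preserving the covariate structure; unstratified
shuffling is available), the genomewide maximum LOD is recorded per
permutation, and threshold(α) is the empirical (1−α) quantile.  Defaults
follow the standard reporting grid α ∈ {0.01, 0.05, 0.10, 0.20}; 1000
permutations by default, reducible for calibration experiments.

Support intervals are 3-LOD drops: the boundary is the first grid position,
walking outward from the peak, whose LOD is strictly below peak − 3
(a plateau exactly at peak − 3 stays inside), clipped at chromosome ends.
Peaks are local maxima above threshold; maxima whose support intervals
overlap are merged, the highest LOD winning — multi-peak resolution within
a chromosome is otherwise ill-defined.

Effect sizes (PVE, % of among-genotype variance) are df-adjusted,
`100 * (1 − s²_full / s²_null)`: the raw RSS ratio overstates the
contribution of 14 founder predictors by roughly k/n even under the null
(≈ +3.5 points at n = 400), which would make planted-effect recovery
systematically biased.  The raw ratio is available (`adjusted=False`).

Founder effects at a peak are phenotype means over genotypes hard-assigned
per panel to the founder with probability ≥ 0.95 (`assign_threshold`, a
logged parameter — the ≥10-observation reporting rule implies hard
assignment but no published cutoff), and are reported only when backed by
at least `min_obs = 10` genotypes.

## QTL groups, eQTL and expression integration

Trait-specific QTL whose support intervals overlap (closed intervals,
touching counts) form QTL groups — connected components of the
interval-overlap graph per chromosome.  The group interval is the mutual
intersection of member intervals; in chain-overlap topologies with no
common region the fallback is the minimal interval covering all pairwise
overlap regions, and the rule used is recorded per group, surfacing the
ambiguity instead of hiding it.  Intervals are stored 1-based inclusive;
BED exports are 0-based half-open.

Founder-effect similarity between two loci is the Pearson correlation over
founders estimated with ≥ `min_obs` genotypes on *both* sides; fewer than 3
shared founders yields no result.  QTL×cis-eQTL correlations are emitted
for every (member QTL, gene inside the group interval) pair with nominal
p-values plus a Bonferroni flag over all emitted pairs — with at most 16
founders per correlation, family-wise correction is expected to be
punishing, so both views are reported.  Expression–phenotype screens are
Benjamini–Hochberg controlled within trait (default FDR 5%); p-values come
from the t transform t = r·sqrt((n−2)/(1−r²)).

## Enrichment

Observed variant counts inside intervals are compared with a resampling
null: per run, regions matching the true interval sizes are placed
uniformly at random, non-overlapping, wholly within chromosomes (rejection
sampling with a retry cap, chromosome chosen proportional to the number of
valid start positions).  Enrichment is one-sided against the null's 95th
percentile.  The binomial expectation `n_variants × covered_fraction` is
reported alongside.  The null mean matches that expectation when regions
are sparse relative to the genome; at high packing densities the
non-overlap constraint biases coverage slightly low (a ~3% effect at ~20%
packing in our checks), which is inherent to the statistic, not a defect of
the sampler.  No mappability or annotation masking is applied.

## Heritability

H² = σ²_genotype / (σ²_genotype + σ²_residual) from per-fly replicates,
genotype nested in subpopulation.  Subpopulation is a fixed effect by
default and its variance enters neither numerator nor denominator — the
two-subpopulation contrast is a design variable, not segregating variation;
`subpop="random"` estimates it as an outer variance component (reported,
still excluded from H²).  Estimation is REML (statsmodels MixedLM) for
general designs; a closed-form nested-ANOVA moments path (negative
estimates truncated at 0) is restricted to balanced designs and doubles as
the independent cross-check: on balanced simulations the two agree to
< 0.02.

## The synthetic-data generator

The generator produces data with the statistical structure the analysis
assumes; it is plumbing for testing and calibration, not a population-
genetic simulator.

* **Mosaics.**  Crossovers are Poisson on the cM map without interference.
  RIL formation is approximated by expected map expansion rather than
  pedigree simulation: `generations/2` for the advanced intercross plus
  `EFFECTIVE_RIL_MEIOSES = 4.0` for sibling-mated inbreeding (the autosomal
  map-expansion factor).  The panel default of 50 intercross generations
  gives ≈ 29 expected crossovers per Morgan per haplotype.  The effective
  constant is a parameter, not a claim about any particular panel.
* **Drift.**  Block-wise founder frequencies (25 cM blocks, per panel ×
  subpopulation) are Dirichlet with variance matched to the Wright–Fisher
  fixation index F = 1 − (1 − 1/(2Ne))^g (Ne default 200), so founder
  composition departs from 1/8, differs between subpopulations, and the
  departure grows with generations.
* **Phenotypes.**  Per-fly value = Σ QTL contributions + subpopulation
  shift + genotype-level noise + replicate noise.  Noise variances are
  solved so broad-sense heritability matches `h2_target` (0 = pure
  replicate noise, 1 = noise-free; the closed endpoints support degenerate
  test cases).  A planted QTL's `pve` is defined as its share of
  among-genotype-**mean** variance (σ²_G + σ²_E/n_flies) — the quantity
  "among-genotype variation" actually measured when mapping on genotype
  means — so PVE recovery is well-posed.  At 10% PVE the remaining 90% of
  genotype variance is noise, which caps founder-effect ordering recovery
  at a rank correlation of ≈ 0.75 (per-founder SE ≈ 0.14 units vs planted
  effect spread ≈ 0.24 at n = 400); the property tests assert that
  attainable level, not perfect recovery.
* **Expression.**  Per-genotype expression = probabilities · planted
  16-founder effect vector + Gaussian noise; the truth table is emitted in
  the standard eQTL layout so correlation machinery can be tested against
  planted truth.
* **Activity traces.**  A two-state (wake/sleep) per-minute Markov chain
  with phase-specific onset and wake probabilities and Poisson waking
  counts; genotype dependence enters by shifting P(sleep→wake) on the logit
  scale linearly in genetic value.  Default architecture (onset 0.05/0.12,
  wake 0.10/0.04 light/dark, waking rates 2.5/2.0 counts·min⁻¹) yields
  realistic fly-like totals: more sleep in the dark, a few hundred sleeping
  minutes per phase.

What the generator does **not** emulate: linkage disequilibrium decay from
real pedigrees, genotyping error in haplotype inference (only a uniform
`certainty` blur), selection during panel maintenance, X-chromosome dosage,
batch effects, non-Poisson activity bursts, and circadian structure beyond
the square-wave photoperiod.  Passing tests therefore demonstrate
correctness of the estimators under the assumed model, not robustness to
real-data artefacts.

## Problem sizes and determinism

Calibration suites run at reduced scale chosen to keep Monte-Carlo error
small relative to the tolerance being asserted: detection/PVE recovery uses
20 replicates of a 400-genotype panel on one 100 cM chromosome with 200
permutations; threshold calibration uses 200 null scans at n = 100;
heritability recovery uses 300 genotypes × 8 flies.  Every stochastic
routine takes an explicit seed, all randomness flows through
`numpy.random.default_rng`, and pipeline outputs are a pure function of
(config, seeds) — reruns are byte-identical.

## Known limitations

* Single-position models only: no multi-QTL model selection, epistasis, or
  X-specific dosage modelling.
* The moments heritability path requires balance; unbalanced data must use
  REML.
* Enrichment placement treats chromosomes as uniform spaces (no
  centromere/arm structure), and the null mean is binomial only in the
  sparse-packing regime.
* Hard founder assignment discards genotypes with ambiguous haplotypes at
  a peak; with low `certainty` panels the founder-means table can be empty.
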