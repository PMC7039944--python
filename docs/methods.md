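# Methods

`ccqtl` re-implements, as a tested pipeline, a haplotype-based genome-wide
association analysis for Collaborative Cross (CC) mouse cohorts of the kind
used to map bone-microarchitecture QTLs: replicated inbred lines descended
from eight founder strains, phenotyped by µCT, genotyped as founder-descent
probability matrices. Because the mouse-level phenotype and genotype data of
such studies are typically not deposited, the package ships a first-class
synthetic-cohort generator whose statistical structure matches what the
analysis assumes; every downstream stage is validated against it.

## The cohort model

A cohort is a set of CC lines (default 34, the published panel size), each
with replicate mice (default 5). The single-trait mouse-level model is

    y_ij = mu + covariate shifts + sum_q g_q(line i) + u_i + e_ij

with line effect `u_i ~ N(0, sigma_L^2)`, residual `e_ij ~ N(0, sigma_e^2)`
and total line-level genetic variance `sigma_G^2` chosen so that

    h2_line = sigma_G^2 / (sigma_G^2 + sigma_e^2)

on the single-mouse scale. The default `h2_line = 0.6` sits in the middle of
the 0.5–0.65 broad-sense heritability range typical of µCT traits in CC
panels. Covariates (sex, age, batch, month, season, year, experimenter) are
categorical and applied as additive shifts; pairwise interaction shifts are
available to exercise the ANOVA interaction decomposition. Covariate levels
are assigned independently per mouse; the dependence between month, season
and year in a real dissection calendar is not emulated, so passing tests say
nothing about confounded calendars.

A planted QTL (`QTLSpec`) acts through the line's founder-descent
probabilities at its marker, either as eight additive founder effects or as
a biallelic variant with a strain distribution pattern (SDP) acting through
imputed dosage. When `variance_explained` is set, the planted line-level
values are centred and rescaled to that share of `sigma_G^2` (sample
variance over lines), with the remainder assigned to the polygenic line
effect; this makes parameter-recovery tests exact in expectation. When it is
`None` the raw effects are used verbatim outside the variance budget, which
is what the noiseless (`sigma_e = 0`) limits need.

Genomes are marker maps with 0.5 Mb spacing by default (marker density is a
free parameter of such scans; the synthetic default is chosen so a
100-marker chromosome spans a realistic 50–100 Mb). Line mosaics have
Poisson-distributed breakpoints (`expected_segments_per_chrom - 1`,
default 8 segments), uniform founders per segment, and residual
heterozygosity modelled as segments carrying two founders at probability
one half each (default segment probability 0.15, the midpoint of the
80–90% homozygosity of real CC lines at inbreeding generations 11–37).
Descent probabilities are the mosaic's exact descent mixed with uniform
noise, `(1-eps) * mosaic + eps/8` with `eps = 1 - prob_sharpness`
(default sharpness 0.95), standing in for HMM haplotype-reconstruction
uncertainty; the reconstruction itself is out of scope since all downstream
mathematics consumes only the probability matrix.

## Haplotype scan

At each marker the trait is regressed on the eight founder-probability
columns on top of the covariates, with one column dropped for
identifiability (WSB/EiJ, the conventional wild-derived reference). The
statistic is the nested-model partial F (7 numerator df, mouse-level
residual df), reported as `logP = -log10 P`, capped at 50 to avoid tail
underflow. Rank-deficient markers (e.g. monomorphic descent) report
`logP = 0` with a degenerate flag, detected by an absolute singular-value
threshold (1e-8 on probability-scale columns). This classical fixed-effects
test replaces the hierarchical Bayesian random-effects machinery some
published analyses use; it is fully specifiable, fast, and exactly
reproducible, at the cost of less shrinkage (see Power below).

The `ScanEngine` orthonormalises the covariate design once and each
marker's residualised probability columns once (batched SVD); scanning any
batch of phenotype vectors then costs two matrix products. Permutation
thresholds and resampling CIs reuse the same factorisation, which is what
keeps the calibration and coverage experiments cheap.

### Genome-wide thresholds

Null phenotypes are built by line-level permutation: the covariate-adjusted
line-mean deviations are permuted across line labels while every mouse
keeps its covariates and its within-line residual. The line is the unit of
replication in a RIL panel, and under exchangeability of lines this
permutation is exact regardless of the polygenic variance — the empirical
check in the test suite gives a 99th-percentile exceedance rate of 1.0%
over 200 null cohorts. Moving whole phenotype vectors between line labels
is ill-defined when replicate counts differ, which is why the permuted
object is the line-mean component. Thresholds are empirical 95th/99th
percentiles of the per-permutation maximum logP (default 200 permutations).

Note that the mouse-level fixed-effects F is strongly inflated by polygenic
line variance (7 df can capture a large chance share of 34 line means), so
absolute logP values and thresholds are both much larger than those of
shrinkage-based analyses; only their comparison is meaningful, and the
permutation scheme guarantees that comparison is calibrated.

### QTL calling, regional heritability, founder effects

Contiguous super-threshold runs collapse to one call at their maximum-logP
marker (leftmost on ties); runs separated by less than 2 Mb of
sub-threshold markers merge, since a single locus should yield a single
call. Regional heritability `H2_r` is the fraction of covariate-adjusted
line-mean variance explained by the locus descent probabilities,
`(RSS_null - RSS_genetic)/RSS_null` clipped to [0, 1]; note the 7-df
regression also captures part of the polygenic background, so `H2_r`
overshoots the planted share by roughly the chance-capture fraction
(7/33 of the remainder at 34 lines). Founder effects are re-based as
deviations from WSB/EiJ; when another reference is requested the SEs of the
re-based contrasts are approximate (coefficient covariance with the old
reference is ignored).

### Power

With 34 lines × 5 replicates and a 200-marker genome, a planted haplotype
QTL holding exactly half of the line-mean variance is detected at the
99th-percentile threshold in only ~40% of replicates: the 7-df test's
chance capture of line variance sets a high bar at this panel size. Power
crosses 80% when the QTL holds about 60% of line-mean variance and exceeds
95% at about two thirds. The power property in the test suite therefore
plants a QTL at two thirds of line-mean variance — a well-powered design —
and this boundary behaviour is the package's honest account of what the
fixed-effects substitute can and cannot detect at desk scale.

## Merge analysis

A catalogued variant's dosage in a line is
`2 * sum_s P(descent from founder s) * allele_s`, taken at the nearest
marker (interval interpolation was rejected for simplicity; at the default
0.5 Mb spacing the nearest marker is at most 0.25 Mb away). The merge test
is the 1-df partial F of the dosage against the covariate null — additive
only, since CC lines are essentially homozygous. The candidate flag is the
literal rule `merge logP > haplotype logP` at the variant's nearest scanned
marker. When the causal architecture is a biallelic variant whose SDP the
catalogue contains, the 1-df test concentrates the signal and wins the
comparison in ~80% of replicates; when the causal founder grouping is
graded and not expressible by any SDP, the 7-df haplotype test wins in
~90%. Gene shortlisting assigns variants to overlapping genes, or to the
nearest gene (both, flagged ambiguous, on exact ties), and ranks genes by
their best merge logP inside the window.

## Peak-location confidence intervals

The full model at the observed peak (covariates + founder probabilities) is
fitted once; replicate phenotypes are its fitted values plus resampled
residuals; all markers within a window (default ±10 Mb) are rescanned; and
the 50/90/95% intervals are central equal-tail quantiles of the replicate
argmax positions (equal-tail rather than highest-density, so asymmetric,
left-skewed peak distributions are representable). Equal-tail intervals at
nested levels are nested by construction, and the zero-noise limit
collapses to width 0.

Residuals are resampled hierarchically by default: line-mean residual
deviations with replacement across lines, plus within-line residuals across
mice. The peak model contains no line factor, so the polygenic line
variance lives in its residuals; resampling whole-mouse residuals
unconditionally scatters that layer as independent mouse noise, the
rescans under-disperse, and the 95% interval covers the true planted QTL in
only ~80% of replicates. The hierarchical scheme preserves both variance
layers of the replicated-line design — following the data-generating
process is the entire point of residual resampling here — and restores
~96% empirical coverage. The unconditional (`"mouse"`) and strictly
within-line schemes remain available through the `resample` flag.

## Phenotype statistics

Broad-sense heritability uses the covariate-adjusted line ANOVA with the
expected-mean-squares variance-component estimator,

    H2 = (MS_line - MS_resid) / (MS_line + (n0 - 1) MS_resid),

where `n0 = (N - sum n_i^2/N)/(k - 1)` is the effective replicate number
for unbalanced designs, clipped to [0, 1]; `logP` is the line-factor F
test. Line-mean heritability is `H2n = H2 / (H2 + (1 - H2)/n_bar)` — with
about five replicates per line this maps H2 of 0.5–0.65 onto H2n of about
0.82–0.88, the familiar line-mean range for CC panels. Parameter recovery
in simulation is unbiased to within 0.02 at the study scale.

Covariate ANOVA uses Type II sums of squares computed by explicit nested
model comparisons (covariates here are nuisance factors with no modelled
line interaction); covariates that add no rank to the design are reported
and dropped rather than silently absorbed. The interaction percentage is
the joint sum of squares of all pairwise interaction terms over the total
sum of squares. Duncan's multiple-range grouping uses the studentized range
at protection level `1 - (1-alpha)^(p-1)` for span p (default alpha 0.001,
matching the stringent grouping used for line-mean displays), harmonic-mean
replicate counts when unbalanced, and the usual containment protection;
letters are assigned to maximal non-separable runs in descending-mean
order. BH-FDR adjustment delegates to statsmodels and is cross-checked
against a brute-force step-up oracle in the tests. Welch's t uses the
Satterthwaite df; two zero-variance groups with equal means return P = 1
with a degeneracy flag.

## Expression linkage

qPCR relative expression is the standard ddCt reading:
`dCt = Ct_target - Ct_housekeeping`, re-centred on the reference line's
mean dCt, `fold = 2^(-ddCt)`. Per-line folds are computed from per-line
mean dCt, so the reference line's fold is exactly 1 and folds are invariant
to any constant Ct shift. Samples undetected at the cycle cap (default 35)
are flagged ND and excluded. Amplification-efficiency correction is not
applied. Expression–trait correlation is plain Pearson on line-level pairs
and shares its kernel with the trait–trait correlation matrix. The RNA-seq
window operation consumes an externally summarised count table (read
alignment and repository retrieval are out of scope); the expressed flag
defaults to a raw count of 10, configurable because "negligible
expression" has no universal cut-off.

## Numerical and interface conventions

Positions are 1-based bp integers with closed intervals internally; BED
input is converted from 0-based half-open on read and back on write; VCF is
1-based as usual. Founder columns are always normalised to the canonical
order A/J, C57BL/6J, 129S1/SvImJ, NOD/LtJ, NZO/HiLtJ, CAST/EiJ, PWK/PhJ,
WSB/EiJ from file headers. Reports print Mb to 2 decimals. Descent rows
must sum to 1 within 1e-9 internally (1e-6 on file read, with the
offending line and marker named). logP is capped at 50 everywhere. All
generators and resampling procedures are deterministic given a seed, and a
fixed-seed pipeline run is byte-reproducible.

## Problem sizes

The simulation experiments in the test suite and the acceptance script run
at 34 lines × 5 mice with 100–200 marker genomes, 200 permutations per
threshold, 300–1000 resamples per confidence interval, and 50–200 outer
replicates per property — the published analysis scale for the cohort, with
genome size set by the package's own choice of a synthetic marker density
that keeps per-chromosome structure realistic.

## Known limitations

- No kinship or population-structure correction: CC lines are treated as
  exchangeable, as is conventional for this panel.
- No X-chromosome dosage handling, no epistatic QTLs, no pedigree-accurate
  funnel breeding.
- Mouse-level fixed-effects logP values are inflated by polygenic line
  variance relative to shrinkage-based analyses; thresholds are calibrated
  to the same scale, but absolute logP values are not comparable across
  methods.
- The synthetic generator draws covariates independently of line and of
  each other, so aliasing pathologies of real dissection calendars are only
  exercised by dedicated constructed fixtures.
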