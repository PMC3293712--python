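# Methods

## The problem

In a pooled-DNA case-control GWAS, genomic DNA from many individuals is
mixed into pools and each pool is assayed on replicate two-channel SNP
arrays, instead of genotyping every individual.  The group allele frequency
at each marker must then be estimated from the pooled fluorescence signals,
and case-control association must be tested against the variability between
pools — not between arrays — because pools, not arrays, are the independent
sampling units.

Two systematic artifacts stand between raw signals and frequencies:

1. **Allelic preferential amplification / hybridisation.**  The two alleles
   of a heterozygote do not fluoresce equally despite equal dosage.  The raw
   relative allele signal RAS = a/(a+b) is therefore biased.  For a marker
   with amplification ratio k (allele A fluoresces k times brighter per
   copy), a pool with true allele-A frequency f has expected raw estimate

       E[RAS] ≈ k·f / (k·f + (1 − f)),

   e.g. 2/3 instead of 0.5 when k = 2.
2. **Array-to-array brightness differences.**  Whole-channel intensity can
   drift between replicate arrays.

## Frequency estimation

Per-marker correction factors are estimated from individually genotyped
heterozygotes measured on the same platform (signals a_i, b_i per
heterozygote i):

* `k_h` — arithmetic mean of the per-heterozygote ratios a_i/b_i
  (heterozygotes with b_i = 0 are excluded and counted);
* `ras_het_mean` — arithmetic mean of the per-heterozygote RAS
  a_i/(a_i+b_i).

Four estimates of the pooled allele-A frequency are computed in parallel
tracks for every (marker, replicate array):

| track | formula | notes |
|-------|---------|-------|
| U | a/(a+b) | unadjusted RAS |
| H | a/(a + k_h·b) | ratio-mean correction |
| M | R/(R + κ(1−R)), R = a/(a+b), κ = r̄/(1−r̄) | RAS-mean correction; algebraically equal to a/(a+κb) |
| N | per-replicate channel normalisation, then the M formula | see below |

H and M differ only through how the heterozygote summary is averaged (mean
of ratios vs odds of the mean RAS); with a common κ they are identical to
rounding, which the test suite exploits as a cross-check.  M is deliberately
computed through the RAS form so that the identity is a genuine check, not
a tautology.

**Normalisation (track N).**  For replicate r with channel means ā(r),
b̄(r) over the marker set, and grand per-channel means T_a, T_b across
replicates, the channels are rescaled by c_a(r) = T_a/ā(r) and
c_b(r) = T_b/b̄(r) before applying the M formula.  This equalises
per-channel brightness across arrays (already-homogeneous replicates get
unit scales) while leaving the cohort-average channel balance — and hence
the heterozygote calibration — unchanged.  A total-intensity scaling could
never change a replicate's RAS, so it could not produce a distinct track;
per-channel scaling can and does.

Markers whose correction factor is unusable (fewer than `min_het`
heterozygotes, default 2, or a degenerate summary) get *invalid* H/M/N
estimates; they are never silently replaced by the unadjusted value, so the
four tracks remain independent analyses of the same data.  Estimates are
likewise marked invalid rather than clamped if a denominator vanishes or a
value leaves [0, 1].

`min_het = 2` reflects the design trade-off of the approach: with common
variants (MAF ≥ 5%) one expects roughly 2–3 heterozygotes among 20–30
individually genotyped samples, which is about the smallest panel worth
running alongside the pools.

## Quality control

Per method track, a marker survives iff

* pooled MAF ≥ `maf_min` (default 0.01), where MAF = min(f̄, 1−f̄) and f̄
  is the mean of the track's valid replicate estimates over all pools of
  both groups;
* individual-sample call rate ≥ `call_rate_min` (default 0.80), with the
  declared genotyped-cohort size as denominator;
* at most `max_invalid_replicates` (default 0) invalid replicate estimates.

Markers exactly at a threshold pass (removal applies to values strictly
below).  Because MAF and validity depend on the track's own estimates, the
four survivor sets can differ; the call-rate criterion is shared.  The QC
report counts each failure mode separately (a marker may fail several) and
removes the union once.

## Association: nested ANOVA

Replicate measurements y_ijk (group i, pool j, replicate k) are modelled
with pools as a random effect nested in groups.  With actual counts n_ij,
N_i and the usual dot-notation means:

    SS_group = Σ_i N_i (ȳ_i·· − ȳ···)²          df = g − 1
    SS_pool  = Σ_ij n_ij (ȳ_ij· − ȳ_i··)²       df = Σ_i (b_i − 1)
    SS_error = Σ_ijk (y_ijk − ȳ_ij·)²           df = Σ_ij (n_ij − 1)

    F = MS_group / MS_pool,   p = P(F(df_group, df_pool) > F).

MS_pool — not MS_error — is the denominator: replicate arrays only measure
a pool more precisely, they do not add independent sampling of the
population, and testing against MS_error would grossly inflate
significance.  MS_error is still computed and reported.  For balanced
designs with b pools per group, df_den = 2(b − 1); the default
2 groups × 6 pools × 3 replicates design tests with F(1, 10).  With
unbalanced data (replicates lost to validity filtering) the actual-counts
sums of squares give the standard approximation to the random-effects F.

The test is run on the frequency scale (the quantity of scientific
interest is the difference in mean pooled allele frequency); an arcsine
square-root transform is available as an opt-in flag.  No multiple-testing
correction is applied: screening uses a deliberately lenient threshold
(default p < 1e-4) and hits are expected to be confirmed by individual
genotyping.  A marker is "suggestive" if it passes the threshold in at
least one of the four tracks (union rule).

**Degeneracies.**  An all-constant response carries no evidence: F is
undefined and p = 1 (flag `constant`).  Zero pool-within-group variance
with a nonzero group contrast gives p = 0 (flag `zero_pool_ms`).  Mean
squares are compared against a floor of 1e-18 per unit scale — far above
double-precision rounding of centred sums, far below any real replicate
noise.  Flagged markers are excluded from the significance union by
default.  Markers left with fewer than two data-bearing pools in a group
are flagged `insufficient_pools` and not tested.

## Accuracy evaluation

For a marker set measured both in pools and in individually genotyped
samples, the signed per-marker difference d = pooled − reference is
summarised per group and for the case−control contrast
(d = Δpooled − Δreference): mean, sample SD (n−1 throughout), mean and SD
of |d|, and the percentage of markers with d strictly > 0
("over-estimated"; exact ties do not count).  The pooled value per marker
and group is the mean over all replicate estimates of that group's pools.
The reference is normally the individual-sample allele frequency
(2·#AA + #AB)/(2·#called); in simulations the generator's true group
frequencies can serve instead, which isolates the pool-side error from the
reference panel's own sampling noise.

## The synthetic-study generator

`SimulationConfig` defaults describe the emulated study: 1000 independent
markers with allele-A frequency ~ Uniform(0.05, 0.5) (the common-variant
range GWAS targets); two groups of 300 pool members each, partitioned into
6 pools of 50 with 3 technical replicates per pool (36 arrays); a separate
individually genotyped reference panel of 100 + 100 samples; per-marker
amplification ratio k ~ log-uniform(0.5, 2); base intensity 1000 units.

Noise model, each component independently switchable:

* **Genotypes:** iid Hardy–Weinberg draws; no-calls injected at 1%.
* **Individual signals:** expected a* = base·(d/2)·k, b* = base·(1−d/2)
  for A-dosage d, times lognormal multiplicative noise with mean 1 and
  CV 10% per channel (signals are positive; homozygote zero-channels stay
  zero unless an optional cross-hybridisation leakage is enabled).
* **Pools:** realised frequency = members' mean dosage/2, plus normal
  construction error with sd = CV·f (CV 2%, modelling unequal DNA
  contribution), plus an optional uniform bias (for accuracy-recovery
  experiments), clamped to [0, 1].  Pool membership is a fixed partition —
  pools are physical objects, identical across markers.
* **Replicate arrays:** expected a* = base·f·k, b* = base·(1−f), times the
  same lognormal channel noise.

What the generator does *not* model: linkage disequilibrium (markers are
independent), batch/plate structure, probe-level bead replicates within an
array, and chip manifest structure.  Passing tests therefore demonstrate
correctness of the estimators and the test statistic under a clean
hierarchical noise model, not robustness to correlated real-array
artifacts.

## Statistical behaviour worth knowing

* **Pool-composition variance dominates.**  A pool of 50 individuals has
  composition variance p(1−p)/100 in its realised frequency (sd ≈ 0.05 at
  p = 0.5) — larger than either the 10% replicate noise (≈ 0.035 on the
  frequency scale) or the 2% construction error.  With 6 pools per group
  the sd of a group-mean estimate is ≈ 0.02.  Consequently a true
  case-control difference of Δ = 0.10 yields a noncentrality of only
  ≈ 3.2–3.5 on the F(1, 10) test: per-marker power is high but not
  certain, and in a 1000-marker screen with 50 such effects typically
  ~45 of 50 (not all 50) land in the 100 smallest p-values.  Larger pools
  do not help — the variance is a property of how many *individuals* are
  pooled per group.
* **Noise-induced estimator bias is second-order.**  With lognormal channel
  noise at CV 10%, the mean of a/(a+b) differs from its noise-free value by
  |bias| < 1e-3 (the convexity and mean-shift terms largely cancel); the
  closed-form comparisons in the tests budget 0.003 = that bound plus five
  Monte-Carlo standard errors at 10⁴ draws.
* **k̂ is slightly inflated by design:** E[a/b] = k·exp(σ²) ≈ 1.01·k at
  CV 10% (ratio of lognormals), well inside the 3% recovery tolerance at
  n_het = 25.
* **Type-I error is nominal.**  On null studies the nested F matches its
  reference distribution (rejection ≈ 0.05 at α = 0.05 and ≈ 0.01 at
  α = 0.01 over 2000 markers); correction-factor error cancels between
  groups because both share the same k̂ per marker.

## Problem sizes and numerical choices

Simulation-backed tests use 1000–2000 markers with the default design —
large enough that binomial counting error is a fraction of each tolerance,
small enough to run comfortably on a laptop (the full test suite runs in
well under a minute; the acceptance script in ~20 s).  All randomness flows
from a single integer seed through `numpy.random.default_rng`; identical
seeds give byte-identical file bundles and pipeline outputs (tables are
written with a fixed `%.10g` float format).  Ties and orderings are
deterministic: results sort by marker id, significance summaries by best p
then marker id.

## Known limitations

* The unbalanced-design F is the standard actual-counts approximation, not
  an exact random-effects likelihood-ratio test.
* MAF filtering uses pooled estimates (per track); with very small pool
  counts the MAF estimate itself is noisy near the threshold.
* The N track's normalisation marker set defaults to all markers; a
  user-supplied control-marker set is supported but no automatic selection
  is attempted.
* Individual-sample and pooled data are assumed to share the A/B strand
  convention; no strand reconciliation is performed.
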