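# Methods

`hybmap` implements the genetics of a two-species hybrid F2 intercross —
segregation distortion, QTL mapping, selective-sweep scanning and
recombinant fine-mapping — together with the synthetic-data generators
needed to exercise and validate every stage.  The two parental alleles
are written `N` and `S` throughout (for the *Arabis nemorensis* ×
*A. sagittata* system the package is modeled on); genotypes are NN, NS,
SS.

## Cross simulator (`cross_sim`)

An F2 individual is the union of one maternal and one paternal gamete
drawn from F1 heterozygotes.  Gametes are simulated marker-by-marker
along each linkage group: the first allele is a fair coin, and a
crossover occurs between adjacent markers with the recombination
fraction given by the map function.  Haldane's function,
r = (1 − e^(−2d))/2 with d in Morgan, is the default (no crossover
interference); Kosambi is selectable.  Chromosomes assort
independently.

*Gametic drive.*  A drive locus transmits the S allele with probability
k per sex (k = 0.5 is Mendelian).  Drive is implemented by rejection
sampling of whole gametes — a gamete is accepted with probability
proportional to k (if it carries S at the driver) or 1 − k — so the
linkage between the driver and its flanking markers is exactly
preserved.  With equal k in both sexes the resulting genotype
frequencies are p², 2pq, q² at p = 1 − k: allele frequencies are
distorted but Hardy–Weinberg proportions hold, the defining signature
of prezygotic (gametic) distortion.  k = 0.68 reproduces an N-allele
frequency of 0.32 at n = 742, the regime of the strongly distorted
chromosomes in the motivating cross.

*Viability selection.*  After zygote formation each individual survives
with relative probability (1 − t)^NN (1 − u)^NS (1 − s)^SS multiplied
across viability loci; the population is refilled by resampling until
the configured n is reached.  Genotyping error flips a code to one of
the two alternatives uniformly at `error_rate`; `missing_rate` masks
entries.

*Phenotypes.*  y = intercept + Σ_q (a_q x_q + d_q z_q) + covariates +
noise, with x ∈ {−1 (NN), 0 (NS), +1 (SS)} and z = 1 for NS.  The sign
convention is fixed so a positive additive effect means the S allele
increases the trait (the source material states the convention both
ways; we document one and keep it).  Genotypes at QTL positions are
taken from the nearest marker; a missing genotype contributes its
expected score under the marker's observed marginal frequencies.  A
designated fertility locus multiplies the trait mean of heterozygotes
by (1 − δ); δ = 0.30 reproduces a 30% heterozygote seed-production
deficit.  Covariates are a cross-direction contrast and random
tray effects.

*Default map.*  8 linkage groups, 240 cM, 2082 markers allocated
160–369 per chromosome with irregular (Dirichlet) spacing and linear bp
coordinates — the scale of a dense RAD-seq intercross map.

*F3 fine-mapping families* descend from F2 parents heterozygous across
a region bounded by 5 ordered markers (4 intervals); offspring arise by
selfing with recombination inside the region, and the causal variant
sits at the midpoint of its interval.  Study-condition defaults, chosen
once: 15 families × 90 seeds sown × 27 plants retained; two trials with
family-blocked trays (a family's plants share a tray within a trial,
matching how seed families are sown); flowering time is Poisson with a
200-day baseline (days from autumn sowing to first flower) and
log-scale family (sd 0.05), trial (0.10) and tray (sd 0.03) effects;
the causal additive effect is 0.10 per S allele (~20 days, the scale of
a major flowering-time QTL).  The generator records ground truth
(causal interval and genotypes, recombinant flags) for validation.

The generator does **not** emulate: linkage-map estimation error,
segregation of residual parental heterozygosity, epistatic trait
architectures, seed dormancy/germination differences, or selfing beyond
F3.  Passing tests therefore validate the statistical machinery under a
correctly specified map and architecture, not robustness to map error.

## Distortion scan (`distortion`)

Per marker (missing genotypes excluded): allele frequency
freqN = (2 nNN + nNS)/(2n); HWE-expected counts freqN²·n,
2·freqN·freqS·n, freqS²·n (they sum to n exactly); three goodness-of-fit
tests — genotypes vs 1:2:1 (2 df), alleles vs 1:1 (1 df), and genotypes
vs the HWE expectations.  The HWE test is reported with 2 df, following
the convention of the analysis this reimplements; the statistically
standard 1 df (one estimated allele frequency) is available via
`hwe_df=1` and is what makes the test exactly calibrated — the 2-df
convention is strictly conservative.  Cells with zero expectation are
excluded from the chi-squared sum and counted.

Selection coefficients against the homozygotes are
t = 1 − (nNN/expNN)/(nNS/expNS) and s = 1 − (nSS/expSS)/(nNS/expNS).
Two baselines for the expected counts are provided, and the distinction
matters:

* `hwe` (default, used in the scan): expectations from *observed*
  allele frequencies.  Purely gametic distortion cancels out, so
  nonzero t/s isolates postzygotic effects; symmetric heterozygote
  advantage is estimated correctly.  Under one-sided viability
  selection, however, the surviving population's allele frequency is
  itself shifted, and this estimator is attenuated (t = 0.3 on NN
  yields t̂ ≈ 0.18 and a spurious ŝ ≈ 0.15 in expectation).
* `mendelian`: expectations from the F2 1:2:1 ratio.  This is the
  consistent estimator of zygotic viability coefficients when
  transmission is unbiased, and is what the viability-recovery
  validation uses.

Multiple testing: Bonferroni threshold α/m (0.05/2082 ≈ 2.4 × 10⁻⁵ at
the default scale) on all three tests; Benjamini–Hochberg FDR on the
HWE p-values provides the significance flags for t/s.  Classification:
`gametic_distortion` (allele test Bonferroni-significant, HWE not),
`het_advantage` (HWE FDR-significant, t > 0 and s > 0), `het_deficit`
(both negative), `mendelian` (nothing significant), `mixed` otherwise.
Interlocus association between marker pairs uses the Pearson
chi-squared of the 3 × 3 joint genotype table (4 df), with empty
rows/columns dropped.

## QTL scan (`qtl`)

Phenotypes are residualized on cross-direction and tray (least squares;
log-link Poisson for count traits) and standardized.  Genotype
probabilities on a 1-cM grid come from the standard three-state F2
hidden Markov model: transitions between adjacent positions from the
map function (per-gamete allele transitions squared into genotype
transitions), emissions 1 − e for the observed code and e/2 for each
alternative (e = `error_prob`, default 0).  An individual untyped on a
whole chromosome receives the 1:2:1 prior everywhere.

Haley–Knott regression at each grid position: residuals on
x* = pSS − pNN and z* = pNS; LOD = (n/2) log₁₀(RSS₀/RSS₁), capped at 50
for degenerate fits; percent variance = 100 (1 − RSS₁/RSS₀).
Genome-wide thresholds are the (1 − α) quantile (upper order statistic)
of max-LOD over seeded residual permutations, computed efficiently by
projecting permuted responses onto per-position orthonormal design
bases.  Support intervals use the 1.5-LOD drop, expanded one grid point
on each side and clipped to the chromosome.

Multiple QTL are found by conditional forward search: repeatedly add
the position with the highest LOD conditional on the current model
while it exceeds the permutation threshold (max 5 QTL), then refit all
effects jointly; per-QTL LOD and percent variance come from drop-one
RSS comparisons, and per-QTL intervals from a profile scan conditional
on the other QTLs.  This replaces a full two-dimensional scan with
penalized model search — defensible here because the architecture being
emulated showed no QTL × QTL interactions.

Effect-distribution summaries (moments, Shapiro–Wilk) are computed on
the additive and dominance lists of a multi-trait peak table after
removing QTLs on designated distortion chromosomes, the fertility
trait's own QTLs, and QTLs whose intervals overlap fertility QTL
intervals on the same chromosome.  Kurtosis is reported in Pearson
(non-excess) form.  Recomputing these statistics from the bundled
58-QTL reference table shows the published dominance outlier
(d = −0.366) is retained only under the distortion-chromosome-only
exclusion; the soft validation uses that variant.

## Population simulator (`pop_sim`)

A discrete-generation diploid Wright–Fisher simulator: an ancestral
population (burn-in 8N generations) splits into two populations which
evolve for `t_split` generations with instantaneous admixture pulses
(at a pulse, a fraction f of the destination's parents are drawn from
the source).  Per meiosis, crossovers are Poisson(ρL) at uniform
positions and new mutations Poisson(μL) at fresh integer positions
(infinite sites with collision rejection).  A sweep allele is injected
as a single copy at its introduction time with genotype fitnesses
1 : 1 + hs : 1 + s, and the trajectory is conditioned on non-loss by
restarting from the injection-time state (bounded retries).

All sizes are desk-scale stand-ins (defaults N = 500 per population,
t_split = 1000, L = 100 kb, μ = 5 × 10⁻⁷/bp, ρ = 5.5 × 10⁻⁸/bp, samples
20 + 17 haplotypes): population sizes and times are scaled down and μ
scaled up relative to any real system, and the pulse times/fractions
(one ancient pulse just after the split at fraction 0.10, one recent at
0.05) are placeholders for a split-with-two-pulses history; the
realized configuration is recorded in the output metadata.  For bulk
*neutral* replicates, `neutral_replicates` defaults to an exact
coalescent backend (msprime, haploid lineages of size 2N to match the
diploid timescale), which is two orders of magnitude faster; the
forward simulator is the only backend supporting sweeps and is
cross-checked against the coalescent backend (pairwise diversity vs
4Nμ) in the tests.

## Sweep scan (`sweep`)

r² between binary sites is the squared allele-frequency correlation;
missing entries are dropped pairwise, monomorphic sites excluded.  For
an ordered SNP block split after ℓ sites,

ω = [ (C(ℓ,2) + C(S−ℓ,2))⁻¹ (Σ within-left r² + Σ within-right r²) ]
    / [ (ℓ(S−ℓ))⁻¹ Σ cross r² ].

The grid scan evaluates ω on a bp grid (defaults: spacing 200 kb, flank
windows between minwin 50 kb and maxwin 100 kb, ≥ 2 SNPs per flank),
maximizing over all flank extents realizable as "all SNPs within w" for
w ∈ [minwin, maxwin] on each side — the normative search space, since
the exact flank placement of the original LD scanner is not published
line-by-line.  Cumulative pair-sum recursions make the maximization
O(W²) per grid point, and the scan is verified against an exhaustive
oracle on small instances.  A vanishing cross-flank sum (< ε) yields a
configurable capped ω (default 1000) with a flag rather than infinity;
positions with no admissible configuration are NaN/`undefined`.

Thresholds are the empirical 99th percentile (linear interpolation
between order statistics) of per-replicate maximum ω over neutral
replicates.  The validation calibrates on 200 replicates of 100 kb with
the window geometry scaled by the same factor (grid 10 kb, flanks
2.5–5 kb) — a stand-in for the original 10 000 × 2 Mb design — and
checks ~1% exceedance on fresh replicates.

QTL–sweep overlap: each QTL contributes a peak-centered region spanning
10% of its support-interval length (peak ± 5%; one documented reading
of "10-percent quantile regions").  The null relocates sweep windows
uniformly within their chromosome, preserving per-chromosome counts and
widths; add-one empirical p-values are reported for the overlap count
(≥ observed) and the mean peak-to-nearest-sweep distance (≤ observed).
QTLs on chromosomes without sweeps do not contribute distances.

## Parental contrasts and trait network (`pheno`)

Per trait: raw species means and their absolute difference ("distance",
model-free), a species contrast adjusted for tray (least squares;
log-link Poisson giving rate ratios for counts; contingency chi-squared
for categorical traits such as flooding survival), BH FDR across
traits.  The reference species is the lexicographically first label,
so the rate ratio inverts under label swap.  Residualization for the
network uses fixed effects (cross-direction + tray) rather than mixed
models — variance components are not available to fit against, and the
downstream Spearman correlations are invariant to any monotone
per-trait transformation.  Network edges are Spearman correlations with
unadjusted p < α (α = 0.05 by design), on pairwise-complete
observations with ≥ 10 pairs.

## Fine-mapping (`finemap`)

Interval genotypes: an interval takes the genotype shared by its two
boundary markers, `ambiguous` when they disagree (a crossover inside)
or either is missing; a plant is recombinant when any two typed
boundaries differ.  Flowering time is residualized on
family × (trial with tray nested in trial); because that design is
saturated in the (family, trial, tray) cells, the log-link
(quasi-)Poisson fit's predictions are exactly the cell means, and the
implementation uses them directly (quasi-Poisson dispersion affects
only standard errors, which are not used downstream).  Each interval is
then tested by a Gaussian regression of the residuals on the −1/0/+1
interval code, ambiguous plants dropped for that interval.  Because the
four fits drop different plants, raw AICs are not comparable; the best
interval minimizes the AIC difference to the intercept-only model on
the same plants (Δ-AIC), with the per-interval p as tie-break.
Expected recombinants over a region of map length d are reported both
per gamete (2 n r) and per plant (n(1 − (1 − r)²)) with r = map
function of d; for 410 plants across 17 cM these give ≈ 118 and ≈ 110 —
neither reproduces the "expected 80" sometimes quoted for this design,
whose derivation is not stated; both conventions are therefore exposed.

## Numerical and validation choices

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configuration + seed is
  byte-reproducible.
* Coordinates: cM continuous; bp 1-based inclusive internally; BED
  exports 0-based half-open.
* Validation problem sizes (the package's own choices): distortion
  regime and coefficient recovery at n = 742 on a one-chromosome panel
  (the statistics are per-marker); QTL recovery at n = 742 on the full
  2082-marker map over 100 replicates; ω-threshold calibration on
  200 + 1000 replicates of 100 kb; fine-mapping recovery over 200
  replicates of the 15 × 27 design; forward-simulator checks at
  N = 100–200 with L = 20–50 kb.
* Known limitations: no crossover interference in the default map
  function; the HMM assumes the map itself is known without error; the
  forward simulator has no background selection or gene conversion; the
  sweep-injection retry scheme conditions on non-loss, not on fixation.
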