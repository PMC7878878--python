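# Methods

`paleospd` implements a chronometric-statistical pipeline for sparse,
time-averaged death assemblages: radiocarbon calibration, summed
probability distributions (SPDs) with a mark-permutation significance
test, minimum-number-of-individuals (MNI) and first/last-appearance
summaries, and a convex-hull quantification of settlement intensity.  This
note records the models, the defaults and why, the numerical choices, and
what the synthetic-data experiments do and do not demonstrate.

## Calendar convention

Ages are in calendar years before present (cal BP), with 0 = 1950 CE and
larger values older.  "Post 3400 cal BP" therefore means cal BP < 3400.
This convention is used everywhere without exception.

## Radiocarbon calibration

A conventional measurement m ± σ_m (¹⁴C yr BP) is calibrated against a
tabulated curve (μ(θ), σ_c(θ)) by evaluating, on a 1-calendar-year grid,

    p(θ) ∝ exp( −(m − μ(θ))² / 2s(θ)² ) / s(θ),    s(θ)² = σ_m² + σ_c(θ)²,

normalized over the grid — standard intercept-free probabilistic
calibration.  μ and σ_c are linearly interpolated between curve knots
(curves are tabulated at 5–20 yr steps); the 1-yr grid makes integer-year
intervals well defined.

Numerical choices:

* **Truncation.** After normalization, grid years with mass below 1e-12 of
  the peak are dropped and the density renormalized.  The discarded tail
  mass is ~1e-13, so the stored density is within 1e-9 total variation of
  the untruncated one while supports stay compact.
* **Median.** The 50% quantile of the cumulative mass taken young→old; an
  exact 0.5 crossing reports the older year.  Arbitrary but fixed.
* **HPD intervals.** Greedy highest-density set: years ranked by mass
  (ties toward the older year), accumulated to the target level, merged
  into maximal contiguous runs.  2σ ≙ level 0.954.  `level = 1` returns
  the full support.
* **Range status.** A date is *beyond range* when m − 2σ_m exceeds the
  curve's oldest ¹⁴C age, *modern* when m + 2σ_m falls below its youngest;
  k = 2 is exposed as a parameter.  Such dates carry no density and are
  excluded from SPDs and FAD/LAD, but are reported in all counts.

No reservoir correction, marine mixing, post-bomb (F14C) calibration or
Bayesian sequence modelling is attempted.  Any conformant three-column
`.14c` file is accepted; no particular curve is hard-coded.

## Occurrence summaries

* **MNI.**  Specimens of one taxon at one site whose 0.954-HPD interval
  sets overlap are linked; clusters are the transitive closure (single
  linkage) and each cluster counts one individual.  Overlap rather than
  exact interval equality is used because distinct measurements almost
  never produce identical intervals.  Modern and beyond-range specimens
  demonstrably differ in age from every calibrated specimen and count as
  singleton occurrences.
* **Bins.** Within each (site, taxon) series, uncalibrated ¹⁴C ages are
  clustered by single linkage with gap cutoff h (default 100 ¹⁴C yr,
  exposed everywhere as a flag); h = 0 merges only exactly equal ages.
  Bins are the permutation unit: same-event duplicate dates collapse into
  one bin so they cannot inflate significance.  Binning per site *and*
  taxon (rather than per site alone) is required so that each bin carries
  exactly one taxon mark.
* **FAD/LAD.** Oldest and youngest calibrated medians.  A bound mode (2σ
  interval endpoints instead of medians) is not provided; medians are the
  stable choice for sparse data.  With no calibrated record the result is
  explicitly undefined, never silent zeros.
* **Post-threshold fraction.** Strict inequality on the calibrated median
  (a median exactly at the threshold is *not* counted as younger).

## SPDs and the mark-permutation test

Calibrated densities (each normalized to mass 1) are summed per taxon;
with bins, member densities are first averaged within each bin, so the
total SPD mass equals the number of bins.

The significance test asks whether the focal taxon's dates are distributed
non-randomly in time relative to the pooled assemblage.  Taxon labels are
reassigned to bins uniformly at random, preserving label counts, for
`n_sim` permutations (default 1,000); the focal SPD is recomputed for
each.  From the simulated curves:

* the per-year 95% envelope (2.5/97.5 percentiles, raw scale — the
  convention SPD figures use);
* per-year z-scores, (obs − sim mean)/sim sd, with z = 0 where sd = 0;
* *deviation intervals*: maximal contiguous runs where the observed curve
  exits the envelope, signed positive/negative, with an optional minimum
  run length;
* a *global statistic*: the summed squared exceedance of the
  **z-transformed** observed curve beyond the z-scale envelope, and
  p = (1 + #{simulated statistic ≥ observed}) / (n_sim + 1).

The per-year z-transform is affine, so the set of years outside the
envelope is identical on the raw and z scales; only the global statistic's
weighting differs.  The z scale weights each year by its local simulation
spread, which measured closer to the nominal test size than the raw scale
under exchangeable nulls (2.5% vs 1.75% rejections at α = 0.05 over 400
synthetic null datasets).  The +1 correction keeps p ≥ 1/(n_sim+1).  Each
simulated statistic is measured against the pooled envelope of the full
simulation set (not a leave-one-out envelope), and all simulations flow
from one top-level seed, so identical inputs and seed are bitwise
reproducible.  An |·|¹ exceedance variant is available via a flag.

The test is somewhat conservative (ties at zero exceedance under the
null) and its power depends strongly on how *concentrated* the departure
is: a focal taxon drawn from a 500-yr window against a uniform background
(n = 20 each) is flagged in essentially every replicate, whereas a diffuse
tenfold rate step spread over 3,400 years at the same sample size is
flagged in only roughly half of replicates.  Users should not read a
non-significant global p at n ≈ 20 as evidence of homogeneity.

## Settlement intensity

Occupation per historical period is proxied by the convex hull drawn
around the period's site geometries: hull area (shoelace formula) in
hectares, classified low (< 0.5 ha), medium (0.5–1.0 ha, bounds
inclusive, as the closed printed range implies), high (> 1.0 ha), or
no-occupation for periods without mapped sites.  The default merges all of
a period's vertices into a single hull (the single convex outline
convention); a per-site-sum mode is a flag.  Coordinates must be in a
projected metric CRS; inputs that look geographic (all |x| ≤ 180°,
|y| ≤ 90°) are refused rather than silently mis-measured.

## Synthetic data generator

The pipeline's sampling assumption — cave fills are a time-random, sparse
sample of the regional death assemblage — is formalized as the weakest
generative model consistent with it: per taxon, calendar ages are i.i.d.
draws from a piecewise-constant deposition intensity with optional change
points.  Each age is pushed back through the calibration curve with
Gaussian noise, sd = sqrt(σ_c² + σ_lab²), rounded to integer ¹⁴C yr, and
assigned to a site by weighted sampling.  Defaults, chosen once:

* lab errors uniform in 20–30 ¹⁴C yr (the magnitude of modern AMS
  determinations on well-preserved Holocene bone);
* twenty cave sites with equal weight;
* the three-taxon study emulation (`carnivore_study_config`): a
  commensal scavenger appearing at 7.2 ka whose rate steps up tenfold at
  3.4 ka cal BP, an apex predator present throughout that disappears at
  3.4 ka, and a uniform small-carnivore control — the community
  restructuring pattern the pipeline is designed to detect.

A truth table of true calendar ages is always written next to the
specimen table; there is no blind mode.  The generator does **not**
emulate inter-specimen dependence (same-carcass duplicate dates), bone
survival/taphonomic loss, spatial structure among caves, or
curve-plateau-induced multimodality beyond what the synthetic wiggly curve
produces; passing tests therefore validate the statistical machinery under
the stated sampling model, not the field realism of any particular
assemblage.

Synthetic calibration curves are `identity` (μ(θ) = θ; calibration
reduces to a Gaussian, giving closed-form checks) and `wiggly` (a seeded
sum of six sinusoids with a hard amplitude bound, default 50 ¹⁴C yr,
emulating centennial-scale curve structure).

## Validation experiments and problem sizes

`scripts/acceptance.py --seed N --out results/acceptance.json` recomputes,
from scratch: the maximum total-variation distance between the calibration
and a brute-force per-year oracle (100 random curves); the identity-curve
closed forms (50 dates); the null rejection rate of the permutation test
(200 two-taxon exchangeable datasets, n = 20 per taxon, n_sim = 199); its
power and deviation-interval location against the study-emulation step
scenario (100 replicates); simulate–calibrate HPD coverage (500 draws);
settlement classification accuracy and hull-area error (100 random
polygons); and one full study-emulation run (n_sim = 999).  These sizes
keep the whole script under about a minute on one CPU while holding Monte
Carlo error on rates to a few percentage points.  All randomness derives
from the single `--seed`.

## Known limitations

* The permutation test's global p is conservative and its power against
  diffuse rate changes at n ≈ 20 is modest (see above).
* The bin cutoff h that any given published bin count corresponds to is
  generally unknowable; report bin counts across a sweep of h rather than
  asserting one.
* MNI by chronological-overlap clustering is a lower bound and sensitive
  to the HPD level used.
* FAD/LAD from sparse records are biased inward (latest find ≠ last
  occurrence); the generator's hard-cutoff scenario shows the LAD
  estimate approaching the true cutoff from above only as n grows.
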