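# Methods

This note records the models, parameter choices and numerical decisions
behind `villimorph`, in the order the pipeline runs.

## Synthetic histology (`synthhist`)

The generator renders an idealised jejunal cross-section: a horizontal
muscularis mucosae baseline near the bottom edge, a lamina-propria band
above it containing vertical crypt axes, and upright finger-like villi
rising from a flat inter-villous plateau. Intensities are two-valued
(tissue 60, lumen 200 on the 8-bit scale) before optional additive
Gaussian noise — H&E contrast is emulated only as intensity, never as
stain chemistry or nuclear texture.

Villus profiles come in two families chosen for closed-form oracles:

- rectangle (width `w`, height `h`): base-excluded perimeter `2h + w`,
  area `w·h`;
- rectangle with a semicircular cap (total height `h`, straight side
  `h − w/2`): perimeter `2(h − w/2) + πw/2`, area
  `w(h − w/2) + πw²/8`.

Ground truth is computed in continuous μm coordinates, not from pixels;
the cap is discretized at 64 segments only for rendering and
annotation (length error < 0.05%). Geometry uses image-style
coordinates (origin top-left, y down) with an explicit μm-per-pixel
scale; the default is 1 μm/pixel, carried in every sidecar because
microscope magnification alone does not determine a physical scale.
Inadequate orientation is simulated as a 45° shear of the villi about
their bases (area-preserving; the perimeter is re-measured on the
sheared outline), giving the adequacy screen an objective failure to
detect. Crypts are annotation-level polylines (axes with the true
depth), not rendered lumina: crypt depth is measured by the landmark
path, so pixel-level crypt cavities would only perturb the villous
measurements they do not participate in.

## Morphometry (`morphometry`)

*Thresholding.* "Automatic threshold" is implemented as global Otsu
(maximum between-class variance) with an explicit tissue-polarity flag;
tissue is the darker class. A constant image is an error, never a
silent empty mask.

*Contours.* Villi are the connected tissue components strictly above
the inter-villous plateau, located as the modal per-column top-of-tissue
elevation (the plateau is flat; villus tops are not). Cutting the mask
at that level separates adjacent villi and defines each base chord.
Contours are extracted by marching squares at the 0.5 level of a
Gaussian-smoothed (σ = 1 px) copy of the binary mask: pixel-boundary
staircase perimeters overestimate smooth contours by up to ~27%,
whereas the smoothed level set recovers sub-pixel positions (residual
bias ≲ 0.5 px from rasterization, i.e. well under 1% at the default
scale; the level-set shift from boundary curvature is of order
σ²/2r ≈ 0.02 px for a 30 px cap). Components narrower than 5 μm are
treated as debris.

*Measurement.* Area is the shoelace polygon area; VP is the closed
boundary length minus the base-chord length. VP and VA are summed over
all villi in the section before normalization — a per-100-μm
denominator is only meaningful for totals over the measured muscularis
span — and normalized as `total / muscularis length × 100`. VH is the
maximum over the section's villi and CD the mean over crypts (both
rules switchable); VW is the maximal chord of the tallest villus
perpendicular to its axis. The orientation screen requires at least one
villus and one crypt and every villus axis within 30° of the muscularis
normal (default, configurable); inadequate biopsies yield NaN records
flagged for downstream exclusion.

Landmark placement itself is out of scope: VH/CD/VW polylines are
derived from the annotation (base-midpoint to farthest vertex), playing
the role of an operator's cursor tracing. Consequently the recovery
tests validate the automatic VP/VA path against rendered truth, and the
landmark arithmetic, but not human tracing variability.

## Cohort simulation (`cohortsim`)

Allocation mimics a masked four-letter design: letters assigned
1:1:1:1 (balanced within ±1), two letters per arm, the letter→arm map
sealed in a `SealedCodeMap` that raises on direct access and opens only
through `unblind()` after an explicit database lock. This makes the
masking contract testable rather than procedural.

Measures are drawn from a Gaussian copula per (arm, HIV-stratum) with
the correlation matrices observed for the five measures in adults with
enteropathy (e.g. ρ(VH, VP) = 0.715 and ρ(VP, VA) = 0.796 HIV-negative,
ρ(VP, VA) = 0.882 HIV-positive). VH, CD and VA have Gaussian marginals;
VP and VW are log-normal, parameterized by median and log-SD. The
default ("paper") scenario uses the reported HIV-negative group
centres — VH means 293.3 v 236.6 μm (SD 36.3), VA means 27623 v 21650
μm²/100 μm, VP medians 355.0 v 273.7 μm/100 μm, CD centres implied by
the villous:crypt ratios 1.83 v 1.56 — and a null HIV-positive
stratum. SDs that are not reported were fixed once at values consistent
with the reported intervals: CD SD 30 μm, VA SD 5900 μm²/100 μm
(back-calculated from the reported 95% CI of the VA difference),
VP log-SD 0.45 and VW log-SD 0.40. The log-SDs are sized so the two
non-Gaussian measures are visibly right-skewed (skewness ≈ 1.5) and
hence detectably non-normal at trial-size samples, which is exactly the
behaviour reported for them; mild skew (log-SD ≤ 0.25) would be
invisible to any normality screen below n ≈ 200 and would contradict
the observed routing. Attrition (orientation failure) is Bernoulli per
participant at per-arm rates 8/26 and 6/26; a random ~37% of adequate
participants receive a post-vaccination biopsy whose values add a
configurable vaccination effect (default zero) plus re-measurement
noise at 0.3× the marginal SD. One master seed spawns per-participant
substreams, so cohorts are reproducible and order-insensitive.

What the simulator does not emulate: real biological covariate–outcome
relationships (age, sex and BMI are decorative), compliance, serial
correlation beyond the single pre/post pair, or measurement error of
the morphometry path (cohort values are drawn directly on the measure
scale). Passing statistics tests therefore demonstrates correctness of
the analysis machinery under the declared data-generating process, not
validity of that process for any particular population.

## Statistics (`stats`)

- Group comparisons default to the pooled-variance Student t (Welch is
  a switch); the 95% CI uses Student-t quantiles, so CI-excludes-zero
  and p < 0.05 coincide exactly.
- Routing applies Shapiro–Wilk to arm-centred residuals pooled within
  stratum: centring removes the treatment shift that would otherwise
  masquerade as non-normality, and pooling gives the screen usable
  power at per-arm sizes of 8–15, where per-group tests are nearly
  blind. At trial sizes the routing of the mildly-skewed measures is
  still stochastic; the routing contract is asserted at a cohort size
  where normality is decidable.
- The median-difference estimate is Hodges–Lehmann (median of all n·m
  pairwise differences); its CI inverts the Mann–Whitney test using the
  exact null distribution of U (convolution) up to n·m = 10⁴ and the
  normal approximation beyond. Degenerate cases fall back to the full
  range of pairwise differences.
- Kruskal–Wallis uses the tie-corrected H with a chi-square reference
  (k − 1 df); an all-tied input reports p = 1 rather than erroring.
  With two groups it is equivalent to the two-sided Mann–Whitney normal
  approximation without continuity correction.
- Fisher's exact p sums hypergeometric probabilities ≤ that of the
  observed table; an empty margin gives p = 1.
- Wilcoxon signed-rank drops zero differences by default (Pratt
  handling switchable); all-zero differences report p = 1, and a
  zero-variance paired t is guarded to p = 1 for identical vectors.
- No multiplicity adjustment by default (a Holm step-down switch
  exists) — mirroring common practice for secondary morphometric
  endpoints.
- When pre- and post-vaccination datasets both exist, the set whose
  primary-variable (VH) comparison has the larger p is selected en
  bloc; ties go to pre. Per-variable cherry-picking is structurally
  impossible.

## Power (`power`)

Power of the two-sided two-sample t-test is computed from the
non-central t distribution: `df = 2n − 2` (or `n₁ + n₂ − 2` for the
unequal-allocation generalization) and non-centrality
`δ / (σ·√(2/n))`; no normal-approximation shortcut. `required_n`
solves the continuous power equation (Brent's method on real-valued n)
and by default reports the nearest integer — the convention under which
sample sizes are conventionally reported from continuous solvers (for
the trial's post-hoc inputs δ = 65, σ = 36.3 the continuous solution is
n* = 6.03, reported as 6, whose achieved power 0.798 rounds to 0.80).
`rounding="ceil"` instead returns the smallest integer whose achieved
power meets the target, a guaranteed bound (7 for those inputs). The
search is capped at 10⁶ per group; an unreachable target errors with
the cap stated.

## Pipeline and reproducibility

Every stage seed derives deterministically from one master seed (stage
name → stable digest → `SeedSequence`). Outputs are plain text (CSV,
JSON, Markdown, YAML) plus 8-bit PNGs; identical config + seed gives
byte-identical files, which the test suite asserts. The run log records
seeds, biopsy exclusions, lock/unblind events and CONSORT counts.

## Problem sizes used by the test suite

Closed-form geometry checks use single-villus sections at 1 μm/pixel;
recovery regressions use 50 random sections (2–4 villi, VH 150–400 μm,
noise SD 0–10). Marginal/correlation convergence uses 10⁴-participant
cohorts; type-I calibration uses 2000 replicates at 40 per group (the
rank test's discrete null makes it conservative at much smaller n, so
calibration is asserted where its chi-square reference is valid); the
trial-power cross-check uses 1000 replicates at 12 per arm. These sizes
were chosen so each property's Monte-Carlo error is small relative to
its tolerance.

## Known limitations

- The villus profile family is convex and upright; real sections show
  branched, fused and obliquely-cut villi the contour extractor has not
  been validated against.
- The plateau estimator assumes a single dominant plateau elevation;
  strongly sloped or folded mucosa would need the muscularis polyline
  to be used as a reference curve instead.
- Crypt depth is never measured from pixels (by design — it mirrors a
  hand-drawn step), so the automatic path cannot detect crypt
  pathology.
- The Mann–Whitney CI inversion assumes no ties when using the exact
  null; heavy ties shift its coverage slightly.
- Power calculations cover the t-test only; no non-parametric power is
  provided.
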