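# Methods

## Astigmatism representation

Every astigmatism is carried as a positive cylinder magnitude C (diopters)
with the axis A of its *flat* meridian, or equivalently as the Jackson
power vector (J0, J45) = ((C/2)cos 2A, (C/2)sin 2A). The double-angle map
makes meridional arithmetic Euclidean: the package's discrepancy metric
between two measurements is the plain vector distance
sqrt(ΔJ0² + ΔJ45²). This is *half* the cylinder that would express the
same difference; `as_cylinder=True` on the delta/ORA functions doubles it.
The meridional power profile F(θ) = (C/2)cos 2(θ−A) gives an independent
interpretation: the vector distance equals sqrt(mean_θ 2·ΔF(θ)²), which
the test suite verifies against a 1° brute-force grid.

Conventions: axes live in [0, 180), zero-cylinder astigmatisms store axis
0 and refuse axis-dependent operations (steep axis, WTR/ATR label) with
`UndefinedAxisError` rather than guessing. WTR means the steep meridian
lies in the closed band [45°, 135°]; the boundary is included in WTR (a
measure-zero choice in practice). Clinical negative-cylinder refractions
are transposed internally; the two principal meridian powers {S, S+C} are
invariant under transposition.

## Vertex transport and ORA

A spectacle-plane power F at vertex distance d metres becomes
Fc = F/(1 − d·F) at the corneal plane (d = 0.012 by default). Because
the formula holds for a single power, each principal meridian is
corrected independently and the sphero-cylinder reassembled on the same
axis — correcting sphere and cylinder directly would be wrong for
nonzero cylinders. The inverse map Fc/(1 + d·Fc) is exposed and used by
the simulator; the round trip is exact to floating-point.

The ORA for keratometry source K and refraction variant v is
|pv(K) − (pv(RA_corneal) + sign·pv(SIA_v))| with sign = +1 by default:
adding the incision's flattening vector back to the postoperative
refraction reconstructs the total ocular astigmatism the eye would show
without the incision, which is the quantity comparable with
*pre*operative keratometry. sign = −1 is exposed for sensitivity
analysis. The incision is modeled as flattening the 0° meridian
(temporal clear corneal incision, right eyes); the axis is a parameter.
Variants RA/RA1/RA2 correspond to assumed SIA magnitudes 0, 0.20 and
0.40 D, spanning the clinical range when per-eye SIAs cannot be
estimated retrospectively (no postoperative keratometry).

## Cohort analysis

Per eye: Δ(TCRP3−AK), Δ(TCRP4−AK), WTR/ATR label (zero-cylinder eyes
excluded from axis tables with a logged count), low/high irregularity
labels under two thresholds, and the nine ORA values. Grouping
thresholds default to cohort-derived statistics — method 1 the median
IR, method 2 mean + 2·SD (sample SD) — with the fixed published values
(0.036, 0.077 mm) available via `threshold_mode="fixed"` since those are
statistics of one particular cohort, not constants. An eye is "high"
iff IR ≥ threshold.

Regressions fit ln(dependent) on raw-scale predictors by OLS
(statsmodels): ln(IR) ~ age + irregular astigmatism, and
ln(Δ) ~ age + IR + AK magnitude. Because "logarithmic transformation"
can also be read as a raw-scale fit reported after transformation
diagnostics, the raw-scale OLS companion of each model is emitted too;
neither reading is lost. Rows with nonpositive dependent values are
dropped with a recorded count; in hand-built degenerate cohorts
(constant covariates) rank-deficient fits are skipped with a warning
rather than failing the whole report.

Group comparisons use Student's t (Mann–Whitney U and the paired t are
available); p-values are two-sided and reported raw — no
multiple-testing correction is applied, matching the single-cohort
descriptive design. A degenerate paired test (all differences exactly
zero) reports (statistic 0, p = 1) with a warning instead of NaN.
Both Pearson and Spearman correlation are provided; no default is
privileged.

## Synthetic cohort generator

The generator emulates a single-surgeon retrospective cataract cohort of
right eyes. Generation order and defaults:

1. **Age** ~ N(68.25, 11.33²) years, truncated to [40, 95] by resampling.
2. **IR** (corneal irregularity index, mm): ln IR = −4.335 + 0.0157·age
   + N(0, 0.393²), floored at 0.005 mm. The intercept/slope/noise are
   calibrated jointly so the marginal is ≈0.042 ± 0.019 mm at the default
   age distribution and the age–IR rank correlation is ≈0.4.
3. **Axis class**: P(ATR | age) = logistic(−4.70 + 0.0623·age), giving
   ≈39 % ATR overall and an ≈8-year WTR/ATR age gap (ATR eyes older).
   The flat meridian sits near 0° (WTR) or 90° (ATR) with 10° Gaussian
   jitter.
4. **AK magnitude** ~ lognormal(−0.20, 0.63²) D (mean ≈1.0 D, SD ≈0.7 D),
   truncated to [0.1, 6].
5. **Discrepancy vector**: magnitude ln δ = −1.867 + 0.007·age +
   1.613·IR + 0.201·AK + N(0, 0.726²) — the covariate coefficients are
   the regression structure the analysis targets, the intercept and
   noise chosen so δ has mean ≈0.43 D and SD ≈0.37 D — with direction
   uniform in the (J0, J45) plane (no directional information is
   assumed). TCRP3 = AK + δ⃗; TCRP4 = AK + 0.9·δ⃗ (the damping reflects
   the larger averaging zone's smaller mean discrepancy; configurable).
6. **Refraction**: TCRP3 is the generative "true cornea". The
   corneal-plane postoperative refractive astigmatism is
   pv(TCRP3) − pv(SIA_true) + ε with ε bivariate Gaussian of
   per-component SD 0.15·(1 + 5·IR) — residual error grows with
   irregularity. SIA_true defaults to 0.40 D at axis 0. A corneal-plane
   spherical equivalent ~ N(−0.25, 0.40²) D completes the
   sphero-cylinder, which is transported to the spectacle plane by the
   inverse vertex map and stored in negative-cylinder notation.
7. **Ancillary columns**: total corneal irregular astigmatism
   = 10·IR + N(0, 0.15²) μm (floored at 0); spherical aberration
   0.326/0.407 ± 0.20 μm for WTR/ATR eyes; anterior radius
   N(7.80, 0.25²) mm with the anterior/posterior curvature ratio
   1.22 − 1.0·IR + N(0, 0.02²), so high-IR eyes have a lower ratio.

All draws come from one `numpy` Generator seeded by `seed`; the cohort
is bit-reproducible and the written CSV byte-stable for a fixed seed.

Choosing TCRP3 as the true cornea makes the headline qualitative
finding — ray-traced keratometry predicts postoperative astigmatism
better in irregular corneas — reproducible as a property: in the
noise-free limit (all SDs zero, analysis SIA = SIA_true) the ORA against
TCRP3 is exactly 0 while the ORA against AK equals the injected
discrepancy magnitude. With default noise, the high-IR subgroup's mean
AK-based ORA exceeds the TCRP-based ORA for every refraction variant.

### What the generator does *not* emulate

Measurement repeatability (inputs are already triplicate means), any
joint axis–magnitude dependence beyond the age-linked class, posterior
corneal astigmatism as a separate vector, optics of Scheimpflug
acquisition, or eyes with surgical complications. Passing tests
therefore demonstrate the correctness and internal consistency of the
*analysis*, not the clinical accuracy of any device.

## Numerical choices and problem sizes

Angles are degrees at every public boundary, radians only inside trig
calls; `normalize_axis` folds into [0, 180) with a guard against float
rounding at the boundary. The vertex map raises `SingularConversionError`
exactly at its pole d·F = 1. CSV output uses 6 significant digits.
Truncated distributions are sampled by resampling, never clipping
(except explicit physical floors noted above). Stochastic checks run at
n = 1000–5000 eyes and 20 seeds for coefficient-recovery coverage —
sizes at which Monte-Carlo error is well below the asserted margins
while the full suite stays fast.

## Known limitations

The SIA application sign and the exact ORA operand order are modeling
choices (both signs exposed); the per-eye SIA is never estimated. The
generator's logistic age–axis model and uniform discrepancy direction
are emulation choices without an empirical joint distribution behind
them. Fixed grouping thresholds (0.036/0.077 mm) describe one historical
cohort and are not defaults.
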