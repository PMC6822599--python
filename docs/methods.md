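# Methods

## The analysis

During steady treadmill gait, where the swing foot lands is tightly coupled
to the mediolateral (ML) state of the body: a step-to-step regression of the
subsequent ML foot placement on the ML trunk CoM position and velocity
explains a large share of placement variance, and the explained fraction is
read as the strength of foot-placement control of lateral balance.

The pipeline implements that analysis end to end:

1. **Preprocessing.** Vertical force and centre of pressure (CoP) are
   low-pass filtered with a zero-phase (forward + backward) 2nd-order
   Butterworth filter, 10 Hz cutoff. Two passes square the magnitude
   response, so the gain at the cutoff is 0.5 rather than 1/sqrt(2); the
   DC gain is exactly 1. Kinematic marker data are never filtered. The ML
   trunk CoM is the pointwise mean of the three trunk-cluster markers; its
   velocity is the central-difference derivative (one-sided at the ends).
2. **Gait events.** Heel strikes (HS) and toe offs (TO) come from the
   force-plate data. Walking (no flight): each heel strike launches a rapid
   ML CoP transfer from the old to the new stance foot; sweeps are located
   on the filtered ML CoP velocity and their edges refined at half the local
   peak, which is unbiased under zero-phase smearing. Running (flight):
   contacts are intervals of vertical force above 20 N (50 ms debounce).
   Contact edges are timing-critical, so running detection filters the
   force with a wider 45 Hz band and refines each edge by linearly
   extrapolating the 10-30 %-of-peak loading flank to zero force; a plain
   threshold crossing on 10 Hz-filtered force is biased ~20 ms early by the
   filter's smearing of the sharp onset. Contact sides come from the ML CoP
   relative to neighbouring contacts, with alternation enforced by parity
   vote. Mid-stance of a leg is defined as 50 % of the contralateral
   TO-to-HS interval — the moment the stance foot is guaranteed stationary —
   and serves as both the coordinate origin and the placement read-out time.
3. **Per-percentage regression.** Each step is the swing phase TO -> HS,
   time-normalized to 0-100 % on a 101-node grid (the grid includes both
   endpoints; the source analysis says only "each percentage"). CoM
   position and the placement read-out are expressed relative to the
   stance-foot heel at the origin mid-stance (heel positions averaged over
   a +/-25 ms window, configurable, where the foot is stationary); left-leg
   ML values are mirrored so both legs share sign semantics; everything is
   zero-centred per node. At every node i an ordinary least-squares fit
   without intercept gives

       FP = beta1(i) * C(i) + beta2(i) * V(i) + eps(i)

   with beta1 dimensionless and beta2 in seconds. R2(i) is the ratio of
   predicted to actual placement variance, identical to 1 - SSE/SST for
   centred no-intercept fits (asserted internally to 1e-10). Coefficient
   significance uses classical two-sided t-tests with n - 2 degrees of
   freedom inside each participant's regression; the per-node percentage of
   non-significant velocity gains across participants is also reported.
   Legs with fewer than 4 steps are excluded with a logged reason.
4. **Step metrics.** Step width is the mean absolute ML separation between
   successive foot placements at their mid-stances; its sample (ddof = 1)
   standard deviation is step-width variability. Absolute separations are
   used because running step widths near zero can cross the midline.
5. **Group inference.** Scalar outcomes use paired t-tests and a 2x2
   fully-within-subject ANOVA (condition x locomotion mode) built from
   single-df contrasts, so every F equals the squared paired t of its
   contrast — an identity the tests assert to 1e-10, and the basis of the
   Bonferroni-adjusted simple-effect post-hocs. Curve outcomes (the R2
   time-series) use 1D statistical parametric mapping: a t or F statistic
   per node with a family-wise threshold at alpha = 0.05 from two
   independent routes: (a) random field theory — the expected Euler
   characteristic of the excursion set, with field smoothness (FWHM)
   estimated from normalized residual gradients; and (b) the (1 - alpha)
   quantile of the max-|t| distribution over sign flips of the paired or
   contrast curves, enumerated exhaustively when 2^n <= 4096. t inference
   is two-sided via |t|; F thresholds for single-df effects use the exact
   F = t^2 correspondence. Clusters are maximal runs of contiguous
   suprathreshold nodes; cluster-level p-values are out of scope. Monte
   Carlo calibration on smooth Gaussian nulls (n = 10, FWHM 10, 500
   repetitions) gives family-wise rates of 0.056 (RFT) and 0.052
   (permutation) with thresholds agreeing within 1 %.

The standard design mirrors a 10-participant study with walking at
1.25 m/s and running at 2.08/2.50/2.92 m/s in a normal and an externally
stabilized condition; walking 1.25 vs running 2.50 are the default contrast
cells, other speeds are selectable via configuration.

## The synthetic gait generator

Real deposited data cannot ship with the package, so every stage is
validated against a generator with a known control law.

**Latent structure.** Step k draws independent (optionally AR(1) across
steps) Gaussian latents: `w_k` — the control-relevant CoM state deviation
(SD `com_noise_sd`); `z_k` — CoM variation in the null space of the law
(SD `com_free_sd`); `u_k` — CoM variation decoupled from the next placement
(SD `com_decouple_sd`); and `eps_k` — the placement residual (SD
`fp_noise_sd`). The mirrored placement deviation is `d_k = w_k + eps_k`,
and footfalls alternate around the midline with mean separation
`mean_step_width`.

**Law-consistent trajectories.** The swing-phase CoM deviation relative to
the stance foot is `C(tau) = w*phi1(tau) + z*phi2(tau) + u*phi3(tau)`,
where `phi1` solves the linear ODE `beta1*phi1 + beta2*phi1'/T = 1` and
`phi2` its homogeneous counterpart (RK4 on a fine grid; algebraic special
cases when `beta2 = 0` or the law is absent). Consequently
`beta1(tau)*C + beta2(tau)*V = w` exactly at every swing percentage where
the law is in force: the same gain profiles hold across the whole swing,
and the true explained variance there is
`com_noise_sd^2 / (com_noise_sd^2 + fp_noise_sd^2)`. The decoupling shape
`phi3 = (1 + cos(pi*tau))/2` vanishes (with zero slope) at heel strike, so
`u` attenuates the correlation early in the swing and R2 rises toward heel
strike. In running, the first ~19 % of the swing is flight: there the CoM
is inherited from the previous step (continuity), followed by a short cubic
blend into the step's own law window (`bridge_frac`, default 0.16), so
early-swing states carry no information about the upcoming placement —
R2 starts at zero and rises after the blend, which is what confines strong
coupling to late swing in running.

**Exact ground truth.** All trajectory segments are linear in the latents,
and so is every pipeline measurement. The ground-truth profiles
(`true_beta1/2`, `true_r2`) are therefore computed exactly by pushing unit
latent impulses through the same discrete measurement chain the pipeline
applies — kinematic-rate sampling, central differences, linear
time-normalization, origin subtraction — and solving the population normal
equations with the known latent covariance. A continuous-time derivation
is kept for reference, but only the impulse route is exact near
segment boundaries, where finite differences mix adjacent segments.

Preset step periods are multiples of the kinematic sample interval
(walking 0.55 s; running 0.38/0.36/0.34 s by speed) so that every swing
samples the CoM process at identical phases; with all noise sources zeroed
the fitted R2 is then 1 to machine precision at every node — the strongest
single check of the whole chain.

**Signals.** Three trunk markers with fixed ML offsets summing to zero
(their mean is exactly the CoM) plus white marker noise (default 0.1 mm,
typical of active-marker systems); heel markers stationary in stance with
smooth swing transport; walking CoP with double-support transfer ramps and
constant-plus-ripple vertical force; running CoP per contact with half-sine
vertical force scaled so the stride impulse equals body weight, zero in
flight. All randomness flows from one seeded generator; identical seeds
give bit-identical trials.

**Study-condition presets** (chosen to land the explained-variance bands
and step-width effects in the ranges the underlying study reports, before
any acceptance test was run):

| parameter | walking | running | unit |
|---|---|---|---|
| step period | 0.55 | 0.36 (2.5 m/s) | s |
| duty factor | 0.62 | 0.38 | – |
| beta1 / beta2 | 1.5 / 0.25 | 1.5 / 0.18 | – / s |
| com_noise_sd (w) | 0.010 | 0.008 | m |
| com_free_sd (z) | 0.006 | 0.005 | m |
| com_decouple_sd (u) | 0.0055 | 0.003 | m |
| fp_noise_sd | 0.0045 | 0.0052 | m |
| mean_step_width | 0.12 | 0.05 | m |
| sway amplitude | 0.025 | 0.015 | m |

yielding R2 ~0.54-0.83 across the walking swing and ~0.70 late in the
running swing, crossing 0.5 near one-third of swing. The stabilized
condition multiplies sway amplitude, state SDs, gains and step width by
mode-specific shrink factors (walking 0.6/0.5/0.7/0.6; running
0.85/0.8/0.9/0.85) with the placement-noise floor unchanged — stabilization
removes CoM excursion and the need to correct it, not sensor/motor noise —
reproducing the direction and rough size of the reported stabilization
effects (R2 down to ~0.29-0.53 walking and ~0.57 running; ~40 % step-width
and ~38 %/13 % variability reductions in walking/running). Cohorts draw
per-participant multiplicative log-normal factors (SD 0.12) on variability,
amplitude, noise, width and gain scale.

## What the generator does and does not emulate

It emulates alternating gait timing with genuine double support and flight,
butterfly-shaped CoP, realistic force profiles, marker/CoP/force noise, a
per-percentage control law with configurable strength and shape, and the
stabilization and mode contrasts. It does not simulate musculoskeletal or
inverted-pendulum dynamics, spring forces, energy cost, marker dropout,
soft-tissue artefact, AP foot-placement control, or drift correction (the
footfall sequence random-walks laterally as deviations accumulate, which
real treadmill walkers correct). Passing tests therefore show that the
analysis chain recovers a known control law under realistic signal
structure and noise — not that real data satisfy the generator's
assumptions.

A relevant measurement effect worth knowing: differentiating unfiltered
100 Hz markers amplifies noise (0.1 mm of marker noise becomes ~4 mm/s of
velocity noise), which attenuates the fitted velocity gain by several
percent where the true velocity variance is small. The parameter-recovery
validation is therefore run with marker noise zeroed — it tests the chain,
not sensor physics — while all study-level analyses keep the noise on.

## Numerical choices

- Filter edges: reflective padding of several filter lengths in
  `sosfiltfilt`; cutoff >= Nyquist is rejected.
- Basis ODE: RK4 with step 1e-3 on a grid overhanging [0, 1] by 0.1 so law
  segments can extend two kinematic samples past TO and HS (keeping
  discrete endpoint velocities law-consistent); results memoized per
  parameter set.
- Event refinement: sub-sample linear interpolation of crossings; walking
  sweeps at half of the local velocity peak; running edges by flank
  extrapolation (falls back to a threshold crossing for degenerate flanks).
- Degenerate inputs: zero force -> "no contacts" error; zero-variance
  paired differences -> flagged, p undefined; rank-deficient regression
  nodes -> NaN with a warning; constant residual fields -> FWHM capped at
  1e6 with a warning; all-zero gain profiles -> R2 identically 0.
- RFT threshold solved by Brent's method on the expected-EC equation;
  in the infinitely smooth limit it reproduces the ordinary two-sided
  critical t exactly.
- Permutation seeds are explicit; exhaustive enumeration replaces sampling
  whenever 2^n <= 4096.

## Problem sizes

Validation uses trials of 200 steps for parameter recovery (seed-averaged
over 10 walking + 10 running seeds), 100-step trials for event-detection
accuracy, 500 Monte-Carlo repetitions for SPM calibration, 10^4 for the
scalar ANOVA null, and 20 cohort seeds (10 participants x 4 cells x 100
steps) for the qualitative orderings — sizes at which the binomial/sampling
error of each check is several times smaller than its tolerance.

## Known limitations

- The RFT expected-EC approximation is validated for two-sided t fields and
  single-df F fields (the designs used here); generic multi-df F thresholds
  use the standard EC density normalized to the k = 1 identity but are not
  separately calibrated.
- The event detector is designed for treadmill data with a single resultant
  CoP; it has no kinematic fallback for overground or split-belt setups.
- `run_replication` expects trials already converted to the package's
  tabular layout; no proprietary motion-capture formats are read.
- Cluster-level inference stops at suprathreshold extents; no cluster-mass
  p-values.
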