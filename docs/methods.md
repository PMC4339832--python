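# Methods

## The problem and the model

During tethered flight a fruit fly beats its wings quasiperiodically at
~200 Hz while steering muscles superimpose subtle, intermittent deformations
of the wing stroke.  This package treats each wingbeat cycle as one sample
of a multivariate signal: the stroke (chord) angle of each wing is read out
at `P = 8` temporally equidistant phases of the cycle, giving a vector
`X = [X1 … X16]` per cycle (phase points 1–8: left wing, 9–16: right wing;
the cycle is anchored at the left wing's dorsal reversal).  Over a segment
of `n = 2500` cycles, the matrix `X` (16 × n) captures the cycle-to-cycle
variability of the stroke *waveform*; the cycle duration is deliberately
excluded and kept as a separate per-cycle period series, so correlations
between waveform components and stroke timing can be assessed afterwards.

The central assumption is linear superposition: independently controlled
stroke deformations add on the angle scale.  A linear transform
`Z = W X` is sought whose rows — the least-dependent components — are as
close as possible to mutual statistical independence, measured by mutual
information (MI):

```
I(Q, R) = H(Q) + H(R) − H(Q, R)        (nats; 1 nat = 1/ln 2 ≈ 1.44 bits)
```

MI vanishes iff the variables are fully independent, covering nonlinear
dependence that correlation misses.  Each component `Z_i` is the activation
time course of a stroke deformation mode, defined by the i-th column of the
mixing matrix `W⁻¹`; the stroke in each cycle is the baseline (mean) stroke
`⟨X⟩` plus `W⁻¹ (Z − ⟨Z⟩)`.  Partial reconstruction (zeroing all mixing
columns outside a chosen set) visualizes single deformation modes and,
dually, removes artifact-carrying components from the data.

## Mutual information estimation

Pairwise MI is estimated with the binless Kraskov k-nearest-neighbour
estimator, default `k = 12`, in the "rectangular" variant: the max-norm
k-neighbourhood of each point defines a rectangle whose per-coordinate
half-widths set the marginal neighbour counts (`ψ(k) − 1/k + ψ(N) −
⟨ψ(n_x) + ψ(n_y)⟩`).  The max-norm-ball ("cubic") variant is available via
configuration.  Exact ties are broken by a seeded jitter of relative scale
1e-9 (warned when >10% of samples are tied).  Small negative estimates are
an expected finite-sample property and are retained wherever spread matters.

On correlated Gaussians the estimator matches the closed form
`−½ ln(1 − ρ²)` within ±0.01 nats at n = 5000.  Its null spread on
independent series of length 2500 is sd ≈ 0.0075 nats and is essentially
invariant to the marginal distributions (the estimator is close to
rank-based), so the α = 0.01 zero-mean-Gaussian significance threshold
computed by the shuffle-surrogate model is ≈ 0.017–0.018 nats at these
settings; it shrinks as segment length grows and is recomputed from the
data at hand rather than hard-coded.

## The decomposition (sweep scheme)

`milca_decompose` first whitens `X` (eigen-decomposition of the sample
covariance; rank deficiency is reported with the offending rows).  The
remaining freedom is the orthogonal group, explored by Jacobi-style sweeps
over all 120 signal pairs.  The 16-dimensional joint MI is not estimated
directly — it is not reliable at a few thousand samples — so the operative
contrast is the sum of pairwise MIs under orthogonal rotations.

Per pair, MI is evaluated on a grid of 32 rotation angles in [0, π/2) (the
contrast is π/2-periodic for whitened pairs) and the curve is fitted with
its first two Fourier harmonics, `a0 + Σ_{m=1,2} a_m cos 4mθ + b_m sin 4mθ`.
The rotation applied is the fitted minimum; the decision and the
convergence accounting use the *fitted* MI drop, which averages out the
estimator noise of the individual grid points.  Four cost controls keep a
16 × 2500 decomposition near 20 s on one CPU without changing the result
materially:

- a pre-screen of 8 grid angles skips pairs whose MI range is below
  4 × the estimator's null spread ("flat contrast", e.g. Gaussian pairs,
  for which the rotation is unidentifiable in principle);
- during the angle search MI is evaluated on an evenly strided subsample
  of at most 1250 cycles;
- rotations with fitted drops below 1 × the null spread are not applied
  (they would be noise-fitting);
- pairs found flat are not re-examined until one of their members rotates.

Sweeps stop when the summed fitted drop falls below 1e-3 nats (default) or
after 50 sweeps; non-convergence returns the best matrix with a flag.
Components are ordered by an event-prominence score (max |z| of the
9-cycle-smoothed course) and signed so each component's largest excursion
from its mean is positive; order and sign are otherwise arbitrary in this
family of methods.  On random 4 × 4 mixtures of non-Gaussian sources the
scheme reaches Amari separation indices of 0.01–0.03.

## Synthetic recordings

The generator stands in for the wingbeat-tracker hardware and defines the
study conditions: 200 Hz wingbeat sampled at 3125 Hz per wing (~15 points
per stroke), leading/trailing edge = chord ± 10° with independent 1°
Gaussian noise per sample, downstroke fraction 0.60 of the cycle (resting
downstroke-to-upstroke ratio 1.5, within the 1.45–1.55 band typical for
tethered flies), 2500-cycle analysis segments.

The baseline chord is a duty-cycled cosine through a smooth monotone
piecewise-quintic phase warp with unit slope and zero warp curvature at
both reversals.  This keeps the waveform locally symmetric around each
reversal, so the mandated zero-phase low-pass filtering does not displace
the detected reversal times; a plain piecewise cosine has unequal flank
curvatures and would bias the measured duration ratio by ~0.2.  Absolute
stroke angles (±70°) are plausible conventions; nothing downstream depends
on absolute offsets.

Seven pattern types are injected as additive per-cycle deformations with
raised-cosine on/off ramps of 5 cycles:

- **I** antisymmetric ventral-amplitude change, period untouched;
- **II** symmetric amplitude change plus a period change of
  `period_coupling` ms per degree;
- **III** a shift of the ventral-reversal phase (duty cycle) —
  e.g. 0.600 → 0.524 drives the duration ratio from 1.5 to 1.10;
- **IV/V** antisymmetric position jitter localized at the dorsal reversal
  (IV) or mid-upstroke (V).  The pulse is a Gaussian-windowed sinc with
  zeros at ±1/8 cycle: band-limited to ~800 Hz so the 3125 Hz tracker
  resolves it, yet vanishing at the neighbouring phase points so the
  deformation stays dominated by a single phase point per wing.  Pulse
  images spilling across a cycle boundary carry their own cycle's
  amplitude, keeping the chord continuous.  The jitter course is an AR(2)
  band-resonant process (resonance 0.15 cycle⁻¹, pole radius 0.7) driven
  by sparse Laplace bursts — temporally correlated and heavy-tailed, with
  Wiener entropy ~0.5–0.7, as physiological position noise appears in real
  components; cycle-to-cycle white Gaussian jitter would be both
  indistinguishable from broadband noise and unseparable by any
  scatter-based method;
- **VI** ventral-amplitude change alternating in sign on successive
  cycles, same sign in both wings;
- **VII** sinusoidal modulation of one wing's dorsal amplitude with a
  40–50-cycle period;
- **mistracking** a displaced edge track in a random ≤2-cycle mid-stroke
  window (the tracker following a leg or vein instead of the wing edge).

Injections commute and superpose exactly (deltas add on the parameter
scale; the per-sample noise pool is frozen by the recording seed), and
every injection records its per-cycle ground-truth activation course.
Because the first generator boundary is not a detectable reversal,
ground-truth courses are aligned to detected cycles via cycle midpoints
(`align_activations`).

What the generator does **not** emulate: pixel-level tracking, body/tether
dynamics, angle-of-attack and deviation degrees of freedom, slow
physiological drifts, and the full heavy-tailed richness of real flight
variability.  Passing tests therefore demonstrate that the analysis chain
recovers known structure under realistic sampling, noise and artifact
conditions — not that real flies exhibit these patterns.

## Preprocessing numerics

Edge series are up-sampled to 50 kHz with a cubic smoothing spline.  The
"assumed noise variance" parameter (default 3 deg²) is an upper bound on
the residual power the fit may absorb; the working target is the noise
power estimated from the data by 6th differences (which annihilate the
band-limited stroke at this sampling density), measured robustly (MAD) so
sharp kinematic transients and tracking artifacts do not trigger
over-smoothing.  The penalty weight achieving the target is found by
bisection on contiguous 5000-sample blocks (a block preserves sampling
density, so the weight transfers to the full series; the median over
three blocks is robust to events inside any one block).  Noise-free input
is reproduced essentially exactly.

The chord is the zero-phase 3rd-order Butterworth low-pass (1500 Hz) of
the edge mean.  Dorsal reversals are prominent chord maxima (prominence
25% of the robust peak-to-peak amplitude; a second pass suppresses
spurious peaks closer than 60% of the median period, keeping the higher
peak).  Cycles of either wing containing two dorsal maxima within 3 ms are
flagged invalid together with the immediately neighbouring cycle on each
side; cycles are shared between wings, so a right-wing artifact flags the
common cycle ("partner wing").  The ventral reversal is the parabola-refined
chord minimum within the cycle.  Invalid cycles are dropped before
segmentation rather than imputed.

## Classification

Components are screened by Wiener entropy (Welch spectrum on the per-cycle
scale: Hann windows of 256 cycles, 50% overlap, DC bin excluded; flatness =
geometric/arithmetic mean).  WE > 0.9 ⇒ broadband noise, excluded from
typing.  Activation events are maximal runs with robust |z| > 3 for ≥ 8
cycles (runs closer than 5 cycles merged).  The type criteria, evaluated
in the order noise → VI → VII → IV → V → I → II → III with the first match
as primary label and the full multi-label set retained:

| type | criterion |
|------|-----------|
| VI | Welch density in [0.45, 0.5] ⩾ 10 × that in [0.30, 0.35] and a run of ≥ 20 cycles of sign-alternating successive differences |
| VII | dominant peak in (0, 0.05] at 0.02 ± 0.005 cycle⁻¹ with power ≥ 5 × the median density |
| IV | ≥ 60% of the scaled separating vector's L1 mass on phase points {1, 9}, opposite signs |
| V | the same dominance on mid-upstroke points {7, 15} |
| I | events of 40–100 cycles, |r(z, period)| < 0.2, and opposite-sign left/right ventral-reversal deviations |
| II | |r(z, period)| > 0.45 and left/right mixing-profile correlation > 0.5 |
| III | events of 40–600 cycles during which |r(z, ratio)| > 0.45 or the 21-cycle-median-filtered ratio departs ≥ 0.1 from its segment median |

Separating vectors are compared after rescaling to act on unit-variance
signals (rows renormalized to unit Euclidean norm).  For a single
component the two wings' per-cycle deviations are exactly proportional, so
the "ventral deviation correlation" reduces to the sign of the product of
the two ventral mixing coefficients; coefficients below 10% of the
column's maximum are treated as absent (correlation 0).  Classification is
deterministic given a decomposition.

Cohort summaries follow the ≥ 25%-of-flies rule for "frequently occurring"
(3 of 10, 2 of 8), bootstrap batches of 5–10 flies with replacement
(duplicates counted), and summarize repeatability as the number of types
shared by segment pairs of one fly.

## Design choices where the design was open

- **Contrast objective.** Joint 16-dimensional MI is replaced by the sum
  of pairwise MIs under orthogonal rotations (see above); this is the
  standard operative contrast for this algorithm family and the only one
  estimable at n = 2500.
- **Significance threshold.** With `k = 12` and `n = 2500` the
  shuffle-surrogate threshold evaluates to ≈ 0.017 nats
  (≈ 0.025 bits).  The estimator's permutation-null spread is a pure
  function of (n, k) — we verified it is insensitive to the component
  marginals, to heavy tails, and to discretization — so this value is a
  property of the stated settings, not of the data richness.  Classifier
  and dependence reports always use the threshold computed from their own
  null model.
- **Event-detector constants** (z > 3, ≥ 8 cycles, 5-cycle merge),
  **dominance threshold** (60% L1), **symmetry bounds** (±0.5) and the
  **Welch parameters** are concrete conventions where only qualitative
  descriptions exist; all are exposed in `ClassificationThresholds`.
- **Cycle-anchor** is the dorsal reversal with phase point j = 0 exactly
  at the reversal and linear interpolation on the 50 kHz grid (spline vs
  linear differ < 0.01° at this density).
- **Ordering/sign** of components: event-prominence ordering and
  positive-excursion signs, for stable reports.

## Problem sizes used by the test-suite and benchmark scripts

Full-scale checks (significance threshold, ratio event, slow modulation,
period-correlation bounds, artifact removal) run on single 2500-cycle
segments at the default estimator settings.  The 50-segment labeled
library used for classifier validation runs on 1500-cycle segments with a
reduced-cost decomposition configuration (16 grid angles, 750-cycle search
subsample, 3 sweeps); 1500 cycles comfortably support the 256-cycle Welch
windows and the 40–250-cycle event scales involved.  The cohort analysis
(10 flies × 2 segments) uses the same reduced configuration.

## Known limitations

- Only the stroke-position angle is modelled; angle-of-attack and stroke
  deviation, and hence aerodynamic forces, are out of scope.
- The decomposition is linear and instantaneous: convolutive mixing,
  nonlinear coupling between patterns (the slow type VII modulation is a
  documented suspect) and non-stationarity within a segment violate its
  assumptions; segments of 2500 cycles balance stationarity against event
  counts, and decompositions of 500-cycle segments are expected to fail
  to separate patterns.
- Gaussian-distributed components are identifiable only up to rotation;
  the pipeline leaves such subspaces at their whitened (PCA) orientation
  and flags the pairs as flat-contrast.
- The type IV/V dominance criterion is sensitive to how sharply localized
  the real jitter is; deformations wider than ~1/8 cycle leak into
  neighbouring phase points and fall below the 60% dominance bound even
  when perfectly separated.
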