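# Methods

This note records the model, the algorithmic and numerical choices, and what
the synthetic validation does and does not demonstrate.

## The oscillating-dipole forward model

A wave-type electric fish is approximated as an ideal current dipole of
time-varying strength lying in a horizontal plane. Two assumptions underlie
everything downstream:

* **Far field.** The dipole length *d* is small against the electrode
  spacing, so the potential at distance *r* and angle *θᵢ* from the axis is
  Φ = K·I(t)·cos θᵢ/r², with K = d/(4πσ) lumping the dipole length and the
  water conductivity σ. Neither is ever needed separately, and K cancels out
  of the normalized observation — the package takes no conductivity input.
* **Horizontal dipole.** The fish holds its body axis parallel to the water
  surface, so the state is X = (x, y, z, θ) with a single planar angle.
  Pitched postures are out of scope.

The discharge current is modelled by its first two harmonics,
I(t) = A·cos(2πft+ψ) + γA·cos(4πft+ξ); higher harmonics are weaker and
unused. Within one analysis window the pose and frequency are treated as
stationary (quasi-static approximation).

Angle convention: θ is measured counterclockwise from the grid frame's +x
axis; the dipole axis is (cos θ, sin θ, 0). θᵢ is the angle between that
horizontal axis and the full 3D displacement vector to electrode *i* — the
dipole and the electrodes need not be coplanar, only the dipole plane and the
electrode plane parallel (the grid loader enforces electrode coplanarity to
1 cm). z is measured downward from the electrode plane; since electrodes are
(near-)coplanar the forward map depends on z only through |z|, so mirror
states above the plane are indistinguishable and the state space is bounded
at z ≥ 0 to resolve the ambiguity.

The observation vector differences the per-electrode signed amplitudes
λᵢ = K·A·cos θᵢ/r²ᵢ against a designated reference electrode and normalizes
to unit length. This removes the unknown ground-electrode contribution, and
all fish-specific constants (K, A, γ), leaving a function h(X) of pose alone.
If the differenced vector's norm falls below 1e-12 the observation is flagged
invalid rather than divided by zero, and the filter skips that update.

## Step 1: frequency tracking

* **STFT**: 0.5 s Hann windows, 0.25 s hop, 4× zero-padding, full windows
  only. 0.5 s spans ≥ 100 EOD cycles at 200 Hz while keeping the quasi-static
  window assumption tenable; zero-padding plus parabolic (log-magnitude)
  peak interpolation gives sub-0.1 Hz frequency precision, comfortably inside
  the 1 Hz association gate. Coefficients are scaled so a bin-centered cosine
  of amplitude A reads A.
* **Signatures**: local magnitude maxima with interpolated fundamental in
  200–700 Hz, magnitude ≥ τ₁ and interpolated magnitude at 2f ≥ τ₂ = τ₁/8
  (both thresholds inclusive). τ₁ defaults to 8× the median in-band magnitude
  per window and electrode — a robust noise-floor estimate standing in for
  the manual per-recording choice an operator would make; it is overridable.
  Two automatic vetoes replace human review of the peak list: a peak must
  dominate its neighbourhood out to ±2 pre-padding bins (rejects the Hann
  window's sidelobes), and a peak whose half-frequency neighbourhood carries
  at least as much magnitude is discarded as the second-harmonic image of a
  lower fundamental (a fish near 350 Hz puts its second harmonic inside the
  species band).
* **Candidates**: greedy first-fit clustering by fundamental frequency within
  0.5 Hz (half the association gate), processing signatures in descending
  amplitude; a weaker duplicate from an electrode already in a cluster is
  dropped. Clusters on ≥ 2 distinct electrodes become candidates; the
  consensus frequency is the amplitude-weighted mean. The voting threshold
  suppresses single-electrode noise.
* **Association**: per window, Hungarian assignment between open track tails
  and new candidates under the Euclidean metric on (w_f·f, per-electrode
  fundamental-amplitude profile, per-electrode second-harmonic profile), with
  amplitudes normalized by the recording's median candidate amplitude and
  w_f = 1. Pairs whose frequencies differ by more than 1 Hz are forbidden.
  Unmatched candidates seed new tracks; remaining track ends and starts two
  windows apart are then stitched, and so on up to the 5 s maximum gap. The
  amplitude *profiles* — not their totals — are what carry identity through
  frequency crossings: two fish with complementary spatial footprints and
  equal total power are indistinguishable by any scalar amplitude summary.
  Tracks shorter than 12 windows (3 s) are pruned as low-confidence
  fragments; movement of a strong source spreads spectral sidebands that
  otherwise nucleate short spurious tracks.
* **Editing**: split/join/delete/reassign operations with the same gap and
  frequency gates (overridable with `force`) replace the interactive review
  step; edited tracks are flagged in their provenance field.
* **Measured observation**: within a candidate, each reporting electrode's
  amplitude is signed +1 if its fundamental phase lies within π/2 of the
  largest-amplitude electrode's phase, else −1 — the two antiphase groups sit
  on either side of the dipole midline. Anchoring to the strongest electrode
  makes the global sign arbitrary per window, so the observation equals
  ±h(X): orientation is observable only modulo π. All orientation estimates
  and errors are therefore axial. A window needs ≥ 3 reporting electrodes
  including the reference; otherwise it is invalid. Electrodes missing from
  a candidate are masked out of both the measurement and the model vector
  before normalization.

## Step 2: particle filter

Standard sequential Monte-Carlo loop per frequency track (tracks are
localized independently): uniform prior over a bounded box with weights 1/N;
zero-mean Gaussian random-walk motion per hop; isotropic Gaussian likelihood
on the residual Λ − h(Xₖ), taking the better of ±Λ because of the sign
ambiguity; weight multiplication and renormalization (Eq.-style w ← w·p / Σ);
pose estimate as the weighted mean, with θ averaged circularly on the doubled
angle and halved (axial data); resampling triggered when N_eff = 1/Σw² < N/2,
rebuilding the cloud as exactly 50 % systematic resampling, 45 % Gaussian
around the current estimate, 5 % uniform over the bounds. The local and
global pools keep particle density available for sudden darting movements
the smooth motion model cannot anticipate. Particles may cross the bounds
during propagation; bounds apply only to initialization and global sampling.

Numerical choices: likelihoods are computed in log space and exponentiated
after subtracting the maximum (they are defined up to a common factor, which
cancels in the weight update); total underflow resets weights to uniform
with a warning. All randomness flows from one seeded generator per filter
run, making runs bit-reproducible.

Parameters (defaults):

| parameter | default | notes |
|---|---|---|
| N | 2.5×10⁴ | desk-scale; 2.5×10⁵ supported for deployment-scale runs |
| σ_obs | 0.2 | unit-vector residual scale; deliberately conservative, see below |
| motion std | (3, 3, 1.5 cm, 0.15 rad) per 0.25 s hop | results insensitive over an order of magnitude |
| bounds | tank box, z ∈ [0, 300] cm | shrink z to the water column for shallow setups |
| N_eff trigger | N/2 | |
| pools | 50/45/5 % | deterministic counts, rounding absorbed by the global pool |
| local std | (5, 5, 5 cm, 0.2 rad) | |

**Observation-noise calibration.** The conservative σ_obs = 0.2 keeps the
filter stable under unmodelled distortions (boundaries, body bending), but on
data the forward model matches well it underweights the measurements: the
actual per-component residual between measured and ideal observation vectors
on simulated scenes is ~0.003–0.006. `calibrate_sigma_obs` measures that
scale directly on any scene with known truth (90th-percentile residual,
floored at 0.005) and the validation scenarios use the calibrated value.
Recovery is insensitive to this choice over at least a 3× range.

**Depth is weakly observable.** The likelihood is nearly flat in z across the
water column at realistic noise levels, so z estimates carry little
information and drift within the bounds; planar position and axial
orientation are the validated outputs, matching how the method is used.

## Simulator

Scenes combine a grid geometry, dipole sources (K, two-harmonic waveform,
pose trajectory), sensor noise, and optional mains interference:

* Per-sample potentials superpose linearly over sources and are recorded
  differentially against a simulated ground electrode ~150 cm off the grid
  corner. Geometry factors are evaluated on the (slow) trajectory clock and
  interpolated to the 20 kHz sample clock.
* Trajectories: `static` (a restrained fish), `smooth` (a kinematic swimmer —
  Ornstein-Uhlenbeck turning rate at 0.7 rad/s std and 1 s correlation, OU
  forward speed around 8 cm/s, orientation equal to heading, reflection at
  the box walls), `darting` (smooth motion with short bursts at 6× speed).
* EOD frequency excursions (field-like behavior, including deliberate
  crossings) are specified as piecewise-linear f(t) and rendered by
  integrating the instantaneous phase.
* Defaults: 20 kHz sampling; lab-range fundamentals 346–452 Hz; harmonic
  ratios γ ∈ [1/8, 1/2]; K·A = 5000 mV·cm² (≈5 mV at one 30 cm grid
  spacing, the order of magnitude of real recordings); per-sample sensor
  noise std 0.2 mV, a synthetic calibration chosen to give a realistic
  spectral SNR (~40 dB at one grid spacing) rather than a measured value —
  no quantitative noise level is available for the real deployments.

What the simulator deliberately omits — and what passing tests therefore do
not demonstrate robustness against: boundary/image-charge field distortions
near tank walls or the water surface, finite body length and tail bending,
conductivity gradients, moving clutter, and electrode-geometry uncertainty.
On real recordings these raise the residual scale substantially (which is
why the conservative σ_obs default exists) and degrade accuracy near
boundaries.

## Evaluation

Position error is planar Euclidean distance (ground truth for the validated
deployments is overhead video, a 2D reference); orientation error is the
minimal circular difference, axial by default (`directed` mode provided).
Pairs are stratified by whether the reference position lies within the closed
square of the outermost electrodes — boundary inclusive; estimates outside
the grid are systematically worse. The permutation test permutes reference
poses against estimates (a true bijection per iteration, seeded), recomputes
cumulative and RMS errors per iteration, and reports the 0.001/0.999
quantiles; 10,000 iterations by default (100,000 supported). Exhaustive
enumeration replaces sampling for small n in tests.

## Validation scenarios and problem sizes

The test suite and `scripts/acceptance.py` run desk-scale versions of the
validation structure: 500 random states for the forward-model invariants;
N = 2×10⁴–2.5×10⁴ particles; a 12 s static noiseless scene compared against
an exhaustive maximum-likelihood search on a 2 cm × 5° lattice (~8.4×10⁵
states, agreement required within one cell in x, y, and axial θ — z is
excluded from the comparison because its likelihood ridge is flat); a 40 s
free-swim scene (159 windows) for recovery rates; a 40 s three-fish scene
with an engineered 1 Hz/s crossing for identity preservation; and 10⁴
permutation iterations. The whole suite runs in well under a minute of
compute plus a few tens of seconds for the scenario syntheses.

## Known limitations

* Orientation is axial (mod 180°); resolving the true heading would require
  carrying discharge phase continuity across windows, which is not attempted.
* Fish closer than about one body length to each other, or sharing a
  frequency for long periods with similar spatial footprints, cannot be
  reliably separated.
* A sweeping track interrupted exactly at a crossing cannot be re-linked by
  the 1 Hz gate if the merge hole spans more than 1 Hz of sweep; identity
  preservation relies on the amplitude profiles steering the merged windows
  to the sweeping fish.
* No smoothing (backward pass) and no joint multi-target filtering; each
  track is filtered independently.
* Near-boundary distortions are unmodelled; real-data accuracy outside the
  grid perimeter is substantially worse than inside.
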