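# Methods

This note documents the models implemented in `dopplerfall`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter.

## 1. Fall kinematics

The body is modelled as a rigid rectangular plate of height `H` pivoting
about its bottom edge. Newton's rotational law with I = mH²/3 and torque
T = mgH sinθ/2 gives

    θ̈ = a sinθ,   a = 3g/(2H),

independent of mass. A trip fall starts upright with an initial tip
velocity `v0` (m/s), i.e. θ̇(0) = v0/H, and ends at floor contact
θ = π/2. The small-angle approximation is *not* valid over a full fall, so
the nonlinear equation is the primary model; the closed-form linearization
θ_lin(t) = v0/(H√a)·sinh(√a t) is kept for early-phase interpretation and
as an ablation condition.

Numerics: fixed-step classical RK4 at the radar sampling interval
(`time_step` = 1 ms), so kinematics samples align one-to-one with baseband
samples. The integrator is validated against the exact first integral
θ̇² = (v0/H)² + 2a(1−cosθ) (residual ~1e-11 in practice, asserted < 1e-6)
and exhibits the expected 4th-order step-size convergence. Degenerate
inputs: `v0 = 0` is an unstable equilibrium that never terminates; a
`time_cap` (default 10 s — an enacted fall lasts 1–2 s, so 10 s is
unambiguous failure) stops integration and flags `terminated = False`. The
terminal sample is clipped to exactly π/2 so downstream geometry never
sees θ > π/2; the energy identity therefore applies to the unclipped
samples.

Units: `v0` is interpreted as m/s with `H` in metres — the initial
condition θ̇(0) = v0/H is dimensionally consistent only under this
reading — and the randomization range [0.5, 5.0] is used in those units.
`g` defaults to 9.81 m/s² and is configurable.

## 2. Plate range geometry

With plate coordinates (x, y), tilt θ and a sensor at distance `d`,
height `h`, azimuth `phi`, the point range is
L = √((x+d sinφ)² + (y cosθ−h)² + (y sinθ+d cosφ)²) = √(X²+Y²+A²) with
A² = h² + d²cos²φ − (d sinθ cosφ − h cosθ)² ≥ 0 (Cauchy–Schwarz). The
area-integrated range D̃(θ) = ∬ L dx dy (units m³) is evaluated with the
standard antiderivative

    F(x,y) = xy·r/3 + x(x²+3A²)/6·asinh(y/√(x²+A²))
           + y(y²+3A²)/6·asinh(x/√(y²+A²)) − A³/3·atan(xy/(A·r)),

r = √(x²+y²+A²), at limits X ∈ [−W/2+d sinφ, W/2+d sinφ] and
Y ∈ [Y_off, H+Y_off], Y_off = d sinθ cosφ − h cosθ, recomputed per sample.
The closed form is treated as an optimization over the ground truth:
adaptive 2-D quadrature of L. The test suite and the acceptance script
sweep random draws across the randomization ranges and require relative
agreement better than 1e-6 (observed ~1e-14). When A² < 1e-9 m² the
arctan term is ill-conditioned and the implementation transparently falls
back to quadrature (this occurs e.g. at φ = ±π/2, θ → 0). Principal
branches are used throughout; a fine-grid continuity test guards against
branch jumps.

The effective range is D = K·D̃ with K in m⁻²; K = 1/(WH) is the
area-averaged range of a uniformly scattering plate, and K is randomized
during synthesis to absorb the deviation of the dominant scattering
center from the uniform average. The plate is kept laterally centered on
the fall line; lateral offsets are out of scope.

## 3. CW radar observation model

Only the post-filter baseband is synthesized: I = α sinφ_d + n_I,
Q = α cosφ_d + n_Q with φ_d = 4π f0 D/c. The sum-frequency term near
2·f0 produced by mixing is removed by the receiver low-pass in hardware
and is not modelled; the start–stop approximation (no range change within
one round trip) is adopted. No wrapping is applied to the synthesized
phase — wrapping happens inside sin/cos.

Amplitude: α(t) = α0 / D(t)^p with p = 2 by default and α0 drawn
log-uniform in [0.5, 2] per trial. The true amplitude law (reflectivity ×
gain × propagation loss) is not identifiable from CW baseband, so a
power-law with configurable exponent (p = 0 disables attenuation) is a
pragmatic, clearly-labelled choice.

Noise is parameterized by per-trial SNR in dB rather than an absolute σ
(scale-invariant under the amplitude randomization): σ per channel is
computed from the noise-free complex signal power as
σ = √(P_sig / (2·10^(SNR/10))). Training corpora draw SNR uniform in
[5, 25] dB; pseudo-measured fixtures in [0, 15] dB.

Not modelled (treated as domain gap): receiver nonlinearity, I/Q
imbalance, phase noise, quantization, multipath, occlusion, RCS.

## 4. Motion classes

* **Fall** — the plate model above; after floor contact the range is held
  constant for `post_fall_hold` (0.5 s) — a body at rest. The clean
  simulator has no post-contact artifacts by design; rebound transients
  exist only in the pseudo-measured generator (§6).
* **Walking** — a kinematic stand-in, not a biomechanical gait model: a
  torso point translates along heading φ with cadence 1.8·√RV steps/s and
  step length 0.26·H·√RV (≈0.8 m/s at RV = 1, H = 1.7 m; linear in the
  speed factor RV), with a vertical bob at twice the cadence and an
  additive leg-swing range modulation at the cadence. This produces the
  qualitative micro-Doppler structure that matters for the three-class
  task — a sustained Doppler line with cadence harmonics — and nothing
  more is claimed for it.
* **Breathing** — a chest-wall stand-in: D = d0 + A sin(2π f_b t) ·
  max(cos φ, 0.2), duration 10 s, amplitude A drawn from [4, 12] mm
  (quiet-breathing chest excursion is millimetric). The facing-angle
  factor is floored at 0.2 so an orthogonally seated subject still
  returns a weak signal.

A class-separability property is asserted: peak radial speed satisfies
fall ≫ walk ≫ breathe at parameter midpoints. This spectral distinctness
is what makes the three-class task tractable — and it bounds what passing
tests show: nothing here demonstrates robustness against fall-*like*
activities (sitting down, bending, kneeling), which are simply absent.

## 5. Domain randomization

Parameters are drawn uniformly on discrete grids: H ∈ [1.50, 1.90] m
(1 mm), W ∈ [0.30, 0.60] m (1 mm), v0 ∈ [0.5, 5.0] (0.01), K ∈ [0.01, 5]
m⁻² (0.01), RV ∈ [0.5, 3.0] (0.01), f_b ∈ [0.1, 0.5] Hz (0.01). Fall/
heading azimuth is continuous in [−π, π) for training corpora and
restricted to the 8-point protocol grid {0°, 45°, …, 315°} for
protocol-style manifests. Sensor range d ∈ [1.5, 4.0] m (the protocol
does not pin numeric location geometry, so this is the package's stand-in
envelope). Corpus generation is fully reproducible from (spec, seed) via
per-trial spawned generators; full-scale corpora default to 3 × 4800 =
14,400 trials, while desk-scale runs use 600.

## 6. Pseudo-measured fixtures

Measured recordings are not distributed with the package, so a
pseudo-measured generator synthesizes stand-in "measured" data for the
full protocol factorial (10 participants × 3 locations × 8 directions ×
2 repetitions × 3 classes = 1440 trials; 48 per participant per class).
It is the same simulator under a deliberately *shifted* regime plus
structured artifacts:

* per-participant body parameters (H, W) drawn once and tied across all
  of that participant's trials — without this, leave-subjects-out
  evaluation would be meaningless;
* per-location sensor range and azimuth offset — giving leave-locations-
  out folds a genuine location-linked shift;
* lowered SNR ([0, 15] dB vs [5, 25] in training);
* a mains clutter tone at 50 Hz;
* on fall trials, a mattress-rebound transient: a damped oscillation
  (1–3 cm, 3–6 Hz, 0.12 s decay) added to the range at floor contact — a
  brief post-fall artifact of the kind seen in measured enacted falls,
  not a sustained signature.

These fixtures exercise the sim-to-real pipeline offline; passing against
them shows robustness to *these modelled* gaps only, not to real
measurement conditions.

## 7. Spectrogram pipeline

STFT of s = I + jQ, Hann window 0.5 s, hop 0.1 s, magnitude retained;
only fully-supported frames are produced (⌊(L−W)/hop⌋+1), and streaming
decisions arrive at 1/hop = 10 Hz. The complex baseband is two-sided;
the 0–500 Hz band is populated by taking, per |f|, the elementwise max of
the +f and −f magnitudes (`fold-max`). This preserves both approaching
and receding motion in one half-band; `positive-only` and `fold-sum` are
exposed as alternatives since the sign convention mapping
approach/recession to ± frequency is itself a modelling choice.
Normalization is log(mag + ε·max) with ε = 1e-10 (numerical floor only),
min–max to [0, 1], bilinear resize to 224×224 with the min–max re-pinned
after interpolation; normalization is idempotent. One `preprocess()`
entry point serves simulated, pseudo-measured and augmented trials alike.

Augmentation operators (all parameters configurable): waveform amplitude
scaling (uniform [0.7, 1.3] — invisible after normalization, by design),
circular time shift (±10 %), additive noise mixing from a noise bank
(generated from the pseudo-measured noise + clutter channel, since the
package ships no measured noise), and random time–frequency masking
(≤ 2 rectangles, ≤ 15 % per axis).

## 8. Similarity metrics

Trial durations differ, so both spectrograms are first time-normalized by
linear resampling to 64 frames (enough to resolve a ~1 s fall at 0.1 s
hop). SSIM uses the standard Gaussian-weighted parameters (σ = 1.5,
K1 = 0.01, K2 = 0.03, dynamic range 1) on normalized log-magnitude at
native frequency resolution. The Doppler ridge is the per-frame argmax
above a DC cut (default 10 Hz ≈ 6 cm/s — well below fall/walk Doppler;
ties break to the lowest frequency). Peak-Doppler error is defined on
ridge maxima rather than the global bin max so isolated noise pixels
cannot dominate. Spectral centroid is Σf·m/Σm over f > dc_cut. All Hz
errors are invariant to common amplitude scaling.

## 9. Classifier and evaluation protocol

The classifier input is the normalized spectrogram image, downsampled to
64×64. Inside the model pipeline the image is converted to
histogram-of-oriented-gradients descriptors (6 orientations, 8×8-pixel
cells, 2×2-cell blocks) and classified by an MLP (one hidden layer of
128 units) trained with adam at learning rate 0.001, batch size 32,
weight decay 1e-4 — the optimization settings of the reference protocol.
A deep residual CNN would be the conventional choice for 224×224
spectrogram images; this package uses HOG + MLP as its image classifier,
a classic pre-CNN design for micro-Doppler signatures whose local-
gradient features are inherently robust to the localized domain-gap
energy (clutter tones, rebound transients) present in the pseudo-measured
fixtures. Two profiles ship: paper-faithful (100 epochs, 14,400-trial
corpus) and desk-scale (10 epochs, 600 trials) used by the tests and the
acceptance script; the desk profile reaches macro-F1 ≈ 0.92 on the
default fixtures.

Splits: LNSO holds out N whole subjects (seeded partition when the
subject count divides evenly; otherwise one fold per subject with N−1
seeded companions so every subject is held out at least once); LNLO
enumerates all location combinations. Partitions are asserted leak-free.

Statistics: participant-clustered bootstrap (subjects are the resampling
units, 10,000 resamples, percentile interval — scores from trials of one
participant are not independent); paired subject-level sign-flip
permutation test on per-subject macro-F1, exactly enumerated for ≤ 20
subjects (minimum two-sided p with 10 subjects is 2/1024 ≈ 0.002; the
observed pattern is counted in the null, the standard exact-test
convention). Both are validated against independent brute-force
enumerations on small inputs.

Ablations re-run training under: full randomization; all parameters fixed
at grid midpoints; direction fixed at 0°; linearized kinematics. The
regime suite runs real-only / real+augmentation / size-matched simulation
/ full simulation / simulation-pretraining+fine-tuning with
pseudo-measured data in the "real" role; fine-tuning is implemented as
joint continued training on simulation plus the real fold, and the
regime-suite augmentation uses the spectrogram-domain operators (time
shift, masking) since the normalization makes amplitude scaling a no-op
and fold waveforms are not retained.

## 10. Known limitations

* Single rigid plate: no articulated limbs, rotation, stumble recovery,
  furniture interaction or floor-contact mechanics.
* Gait and respiration are qualitative stand-ins; no claim of
  biomechanical fidelity.
* The pseudo-measured fixtures are themselves synthetic; transfer scores
  against them are a pipeline property, not evidence about real radar
  recordings.
* A single CW channel has no range/angle resolution; multi-person scenes,
  moving clutter and cross-environment generalization are out of scope.
* Near-orthogonal falls (φ ≈ ±90°) give small radial velocity and weak
  Doppler; this residual failure mode is inherent to the geometry.
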