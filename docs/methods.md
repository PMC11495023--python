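# Methods

## Measurement model

Cardiac-gated PC-MRI stores, for each of `n` cardiac phases, a 2-D frame of
raw pixel values proportional to through-plane velocity. The pipeline models
one acquisition by

* a linear velocity map `v = raw · VENC/raw_scale` (cm/s), where `raw_scale`
  is the stored value that maps to ±VENC;
* velocity aliasing: true velocities beyond ±VENC appear wrapped by multiples
  of 2·VENC;
* a static baseline velocity offset (eddy-current phase bias) shared by the
  CSF lumen and nearby static tissue;
* additive velocity noise, quantified from the reference ROI.

Frames are timestamped at midpoints `t_f = (f + ½)·T/n` of a cycle of
duration `T`; integration below depends only on uniform spacing, not on the
midpoint convention.

## Correction chain and its order

Corrections are applied as VENC scaling → aliasing correction → bias
subtraction. The order matters: 2·VENC wrap arithmetic is only valid before
the series is shifted by a bias that is not a multiple of 2·VENC.

**Aliasing correction** is per-pixel temporal unwrapping with period 2·VENC.
The anchor frame is the frame with the smallest ROI-mean absolute velocity
(`argmin mean|v|`): flow near its zero-crossing is least likely wrapped. The
mean of |v| is used rather than |mean v| deliberately — when noisy flow
straddles ±VENC, the wrapped pixel values split into a mixture near +VENC and
−VENC whose *signed* mean is deceptively close to zero, while mean |v| stays
near VENC and correctly disqualifies the frame. From the anchor the series is
unwrapped forward to the last frame and backward to the first (without
crossing the cycle boundary), which bounds every consecutive-frame jump by
VENC and makes the operation exactly idempotent. The anchor sample itself is
assumed unwrapped; a series whose *true* inter-frame jump exceeds VENC is
inherently ambiguous and cannot be detected — this is a documented limitation,
not an error. Spatial unwrapping is not attempted.

**Bias subtraction** defaults to `global` mode: a single scalar, the mean
over all reference-ROI pixels and frames, is subtracted everywhere —
appropriate for a static offset, and the configuration most consistent with
describing "the mean velocity in the reference ROI" as one number. A
`per_frame` mode (subtracting each frame's reference mean) is available by
configuration for acquisitions with frame-varying offsets. Double application
is rejected. The reference spread about its frame means (`noise_spread`, SD
with n−1) is the velocity noise floor.

**Low-SNR screening** flags (never rejects) an acquisition when the cycle
amplitude (max − min) of the ROI-mean velocity curve is below
`k · noise_spread/√n_pixels`, `k = 3` by default. Real studies excluded
subjects for noise, severe aliasing or unidentifiable anatomy without a
stated quantitative rule; this threshold is this package's own and
configurable. NaN pixels are a hard error — silent interpolation would bias
the flux sums.

## Integration

`Q(t) = (Σ v_i)·dx·dy` per frame; per-cycle volumes use the periodic
trapezoid with `Q(t_{n+1}) ≡ Q(t_1)`. For uniform periodic sampling this
reduces to `dt·ΣQ`, is exact for any constant-plus-sinusoid resolved by the
frame rate, and converges as O(n⁻²) for continuous waveforms with derivative
kinks. Periodic closure is the physically meaningful choice for a gated
cycle and makes the conservation identity

    antegrade_volume + retrograde_volume = net_per_cycle = stroke_volume

exact: the positive/negative split `q⁺ = max(q,0)`, `q⁻ = min(q,0)` happens
per frame *before* integration, so `q⁺ + q⁻ = q` pointwise. Splitting the
piecewise-linear interpolant at its zero-crossings instead would differ by
O(dt²); the per-frame choice is the documented decision. The "stroke volume"
produced by the trapezoid formula is the *signed net* cycle volume — not the
conventional bidirectional aqueduct stroke volume, which is exported
separately as `aux_conventional_stroke_volume = (|antegrade| +
|retrograde|)/2` to avoid ambiguity.

Direction labels come from the sign of the net volume with a configurable
`zero_tol = 1e-12` mL deadband (no measured subject is ever exactly zero;
the tolerance only guards floating-point noise). Heart rate defaults to
`60/T` and, when supplied independently, must agree with the cycle duration
to a relative 1e-6.

## Phantom simulator

The phantom states a world, with defaults chosen once to mirror a typical
aqueduct protocol: 30 frames, VENC 10 cm/s, 0.06 cm pixels, heart rate
70 bpm, a 26-pixel circular lumen (radius 2.8 px at a half-pixel-offset
centre — 26 pixels is the typical aqueduct ROI size), centreline pulsation
3 cm/s, net velocity offset 0.1 cm/s (≈ 0.56 mL/min, within the range
observed in vivo), baseline offset 0.3 cm/s, noise SD 0.5 cm/s.

Pixel velocity is `profile(p)·w(t)` with `w(t) = v₀ + a·sin(2πt/T + φ)` plus
optional harmonics; `profile ≡ 1` (plug) or `1 − (r/R)²` (parabolic, continuum
spatial mean ½). Because a pixelated disk does not realise the continuum mean
exactly, the actual mean of the profile over the mask is measured and stored
in the ground truth, so recovery tests are exact at any resolution:

    true_net_mL_per_cycle = factor · v₀ · n_pixels·dx·dy · T.

The reference ROI is a tissue annulus (2R to 2R+3 px) around the lumen, so
reference pixels carry baseline plus noise only. Wrapping uses
`((v + VENC) mod 2·VENC) − VENC`; a configuration whose peak |velocity|
reaches 2·VENC under wrapping is rejected as unresolvable.

What the phantom does *not* model: Rician noise on the complex MR signal
(noise is Gaussian on velocity — sufficient for velocity-domain testing and
keeps ground truth exact), respiratory modulation (which in vivo dominates
CSF displacement), bulk brain motion, and partial-volume effects at the lumen
edge. A green recovery test therefore establishes correctness of the
*processing*, not fidelity of the acquisition physics.

The repeat-measurement emulation (five same-subject scans differing only in
noise realisation) uses a healthy-subject-like configuration: offset
−0.025 cm/s giving a true net of ≈ −0.002 mL/cycle, and noise SD 0.7 cm/s
chosen from the propagation identity

    SD(net_per_cycle) ≈ dx·dy·T·σ·√(n_pixels/n_frames)
                      = 0.0036·0.857·√(26/30)·σ ≈ 0.0029·σ,

so σ = 0.7 cm/s yields a repeat SD of ≈ 0.002 mL/cycle — the magnitude of
published per-subject repeat tables. The σ was derived from this identity,
not tuned against test outcomes.

## Cohort reporting

Only descriptive shapes are produced: direction counts with exact rational
proportions (formatted to one decimal percent, round half away from zero),
per-group mean ± sample SD (n−1) or median with range, and Pearson
correlation of net flow against a covariate with listwise deletion and
reported n. Group summaries sort values before reducing so the result is
exactly permutation-invariant. Inferential statistics (ANOVA, chi-square,
t-tests) are routine external computations and deliberately out of scope.

## Numerical notes

* Metric CSVs serialise floats via `repr` and are read back with
  `float_precision="round_trip"`, so full-precision columns round-trip
  bit-for-bit.
* All derived unit conversions (`×HR`, `×1440/1000`) are exact chained
  multiplications; invariants are asserted at 1e-12.
* The trapezoid is kept in its two-point periodic form in code for clarity;
  algebraically it equals `dt·ΣQ`.

## Known limitations

* No DICOM vendor scaling tags; inputs are NIfTI/NumPy plus a YAML metadata
  file. 4-D multi-slice series are out of scope.
* Aliasing deeper than one wrap (|v| ≥ 2·VENC) and true inter-frame jumps
  above VENC are unrecoverable and undetectable by temporal unwrapping.
* Net flow per cardiac cycle is not total CSF production: respiratory and
  slower components are invisible to a cardiac-gated acquisition.
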