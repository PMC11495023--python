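"""Pixel-wise velocity processing for cardiac-gated PC-MRI.

The processing chain is

    stored pixel value --to_velocity--> cm/s
                       --correct_aliasing--> unwrapped cm/s
                       --subtract_bias--> bias-free cm/s

in that order: wrap arithmetic is only valid on the ±VENC scale, before
the series is shifted by a bias that is not a multiple of 2·VENC.

The reference ROI (static tissue near the lumen) serves two purposes:
its spread quantifies the velocity noise floor, and its mean estimates
the static baseline phase offset (eddy-current bias) that is subtracted
from the CSF velocities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import AcquisitionMeta, PhaseSeries, RoiMask

__all__ = [
    "CORRECTIONS",
    "VelocityField",
    "BiasEstimate",
    "to_velocity",
    "estimate_bias",
    "subtract_bias",
    "correct_aliasing",
    "mean_velocity_curve",
    "noise_flagged",
]

#: Canonical correction order.
CORRECTIONS = ("venc_scaling", "aliasing_correction", "bias_subtraction")


@dataclass(frozen=True)
class VelocityField:
    """Per-pixel velocity time series (cm/s) for the pixels of one ROI.

    ``velocities`` is indexed ``(frame, pixel)``; pixel order follows
    ``mask.pixels``.  ``times`` are the uniformly spaced frame midpoint
    times in seconds, spanning [0, cycle_duration).
    ``corrections_applied`` records, in order, which of
    :data:`CORRECTIONS` have been applied.
    """

    velocities: np.ndarray
    times: np.ndarray
    mask: RoiMask
    meta: AcquisitionMeta
    corrections_applied: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.velocities, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if v.ndim != 2:
            raise ValueError("velocities must be 2-D (frame, pixel)")
        if v.shape != (self.meta.n_frames, len(self.mask)):
            raise ValueError(
                f"velocities shape {v.shape} inconsistent with "
                f"({self.meta.n_frames} frames, {len(self.mask)} mask pixels)"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("velocity field contains non-finite values")
        if t.shape != (self.meta.n_frames,) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing, one per frame")
        object.__setattr__(self, "velocities", v)
        object.__setattr__(self, "times", t)

    @property
    def n_pixels(self) -> int:
        return len(self.mask)

    def has(self, correction: str) -> bool:
        return correction in self.corrections_applied


@dataclass(frozen=True)
class BiasEstimate:
    """Static velocity bias and noise level estimated from a reference ROI.

    ``value`` is the bias in cm/s (time-and-pixel mean of the reference
    field in global mode; time mean of the per-frame curve otherwise).
    ``noise_spread`` is the SD of the reference velocities about their
    frame means — the velocity noise floor used for SNR screening.
    """

    value: float
    mode: str
    reference_mean_curve: np.ndarray
    noise_spread: float

    def __post_init__(self) -> None:
        if self.mode not in ("global", "per_frame"):
            raise ValueError(f"mode must be 'global' or 'per_frame', got {self.mode!r}")
        if self.noise_spread < 0:
            raise ValueError("noise_spread must be >= 0")


def to_velocity(series: PhaseSeries, mask: RoiMask) -> VelocityField:
    """Linearly map stored pixel values to velocities in cm/s.

    The transform is ``v = raw * (venc / raw_scale)``: a stored value of
    ``+raw_scale`` maps to +VENC, 0 to 0, ``-raw_scale`` to −VENC.
    """
    meta = series.meta
    rows, cols = mask.index
    raw = series.frames[:, rows, cols]  # (n_frames, n_pixels)
    v = raw * (meta.venc / meta.raw_scale)
    return VelocityField(
        velocities=v,
        times=meta.frame_times(),
        mask=mask,
        meta=meta,
        corrections_applied=("venc_scaling",),
    )


def estimate_bias(reference_field: VelocityField, mode: str = "global") -> BiasEstimate:
    """Estimate the static velocity bias from a reference-ROI field.

    Parameters
    ----------
    reference_field : VelocityField
        Field built from a ``kind="reference"`` mask of the same
        acquisition.
    mode : {"global", "per_frame"}
        ``global`` (default): a single scalar, the mean over all frames
        and pixels — appropriate for a static eddy-current offset.
        ``per_frame``: each frame's pixel mean is subtracted separately.
    """
    if reference_field.mask.kind != "reference":
        raise ValueError(
            f"bias must be estimated from a reference ROI, got kind="
            f"{reference_field.mask.kind!r}"
        )
    v = reference_field.velocities
    frame_means = v.mean(axis=1)
    residuals = v - frame_means[:, None]
    if v.size > 1:
        noise_spread = float(np.sqrt((residuals**2).sum() / (v.size - 1)))
    else:
        noise_spread = 0.0
    if mode == "global":
        value = float(v.mean())
    elif mode == "per_frame":
        value = float(frame_means.mean())
    else:
        raise ValueError(f"unknown bias mode {mode!r}")
    return BiasEstimate(
        value=value,
        mode=mode,
        reference_mean_curve=frame_means.copy(),
        noise_spread=noise_spread,
    )


def subtract_bias(field: VelocityField, bias: BiasEstimate) -> VelocityField:
    """Subtract the reference-ROI bias from every CSF velocity sample.

    Global mode subtracts the scalar ``bias.value`` everywhere; per-frame
    mode subtracts each frame's reference mean.  Applying the correction
    twice is an error — the bias is a property of the acquisition, not of
    the field's current values.
    """
    if field.has("bias_subtraction"):
        raise ValueError("bias_subtraction already applied to this field")
    if bias.mode == "global":
        v = field.velocities - bias.value
    else:
        curve = np.asarray(bias.reference_mean_curve, dtype=float)
        if curve.shape != (field.meta.n_frames,):
            raise ValueError("reference_mean_curve length does not match n_frames")
        v = field.velocities - curve[:, None]
    return replace(
        field,
        velocities=v,
        corrections_applied=field.corrections_applied + ("bias_subtraction",),
    )


def correct_aliasing(field: VelocityField) -> VelocityField:
    """Unwrap velocities that exceeded ±VENC and aliased by 2·VENC.

    Per-pixel temporal unwrapping: the anchor frame is the frame whose
    ROI-mean absolute velocity is smallest (flow near its zero-crossing is
    least likely wrapped).  Walking the series in both directions from
    the anchor, any inter-frame jump beyond +VENC has 2·VENC subtracted
    from the samples beyond it, and any jump below −VENC has 2·VENC
    added, leaving every consecutive-frame jump ≤ VENC.  Idempotent;
    already-consistent series are returned unchanged in value.

    A series whose *true* dynamics jump by more than VENC between frames
    is inherently ambiguous and cannot be detected — documented
    limitation, no error raised.
    """
    venc = field.meta.venc
    v = field.velocities
    # anchor on the smallest mean |v|, not |mean v|: when the flow
    # straddles ±VENC, noisy wrapped pixels split into ±VENC values whose
    # signed mean is deceptively near zero while mean |v| stays ~VENC
    anchor = int(np.argmin(np.abs(v).mean(axis=1)))
    period = 2.0 * venc
    out = v.copy()
    # walk forward and backward from the anchor; the anchor sample itself
    # is taken as unwrapped.  Both walks leave out[anchor] untouched and
    # together bound every consecutive-frame jump by VENC, which makes a
    # second application a no-op.
    if anchor < v.shape[0] - 1:
        out[anchor:] = np.unwrap(v[anchor:], axis=0, period=period)
    if anchor > 0:
        out[: anchor + 1] = np.unwrap(v[anchor::-1], axis=0, period=period)[::-1]
    applied = field.corrections_applied
    if "aliasing_correction" not in applied:
        applied = applied + ("aliasing_correction",)
    return replace(field, velocities=out, corrections_applied=applied)


def mean_velocity_curve(field: VelocityField) -> np.ndarray:
    """ROI-mean velocity per frame (cm/s): the mean over mask pixels."""
    return field.velocities.mean(axis=1)


def noise_flagged(field: VelocityField, bias: BiasEstimate, k: float = 3.0) -> bool:
    """Flag a low-SNR acquisition (flag, not reject).

    True when the cycle amplitude (max − min) of the CSF ROI's mean
    velocity curve is below ``k × noise_spread / sqrt(n_pixels)``, i.e.
    the pulsatile signal does not clear the reference noise floor of the
    ROI-mean.  ``k`` defaults to 3.
    """
    curve = mean_velocity_curve(field)
    amplitude = float(curve.max() - curve.min())
    return amplitude < k * bias.noise_spread / np.sqrt(field.n_pixels)
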