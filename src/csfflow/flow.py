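"""Volumetric CSF flow quantification from a corrected velocity field.

The volumetric flow rate at frame t is the sum of the ROI pixel
velocities times the pixel area,

    Q(t) = (Σ_i v_i) · dx · dy        [cm³/s = mL/s],

and per-cycle volumes are periodic trapezoidal integrals of Q over one
cardiac cycle,

    V = (dt/2) Σ_{i=1..n} (Q(t_{i+1}) + Q(t_i)),   Q(t_{n+1}) ≡ Q(t_1),

which for uniform periodic sampling reduces to dt · Σ Q.  Directional
volumes split Q into its positive and negative parts per frame before
integration; their signed sum equals the net cycle integral exactly.

Sign convention: positive stored velocity = flow toward the head.  At the
aqueduct, negative net flow is antegrade (3rd → 4th ventricle, the
direction of classical ventricular CSF production) and positive net flow
is retrograde (4th → 3rd).  At the cranio-cervical junction, positive is
upward (thecal sac → intracranial) and negative is downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AcquisitionMeta, SITES
from .velocity import CORRECTIONS, VelocityField

__all__ = [
    "FlowCurve",
    "FlowMetrics",
    "flow_curve",
    "integrate_cycle",
    "directional_volumes",
    "net_flow_metrics",
    "classify_direction",
]


@dataclass(frozen=True)
class FlowCurve:
    """Volumetric flow rate Q(t) in mL/s over one gated cardiac cycle."""

    q: np.ndarray
    times: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (self.meta.n_frames,):
            raise ValueError(
                f"q must have length n_frames={self.meta.n_frames}, got {q.shape}"
            )
        if not np.all(np.isfinite(q)):
            raise ValueError("flow curve contains non-finite values")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))

    @property
    def dt(self) -> float:
        return self.meta.dt


@dataclass(frozen=True)
class FlowMetrics:
    """Cycle-integrated CSF flow metrics for one acquisition.

    ``stroke_volume`` is the signed net cycle integral of Q (the
    trapezoidal "stroke volume" formula) — NOT the conventional
    bidirectional aqueduct stroke volume, which is exported separately as
    ``aux_conventional_stroke_volume`` (mean of |antegrade| and
    |retrograde| volumes).  ``antegrade_volume`` ≤ 0 is the integral of
    the negative flux, ``retrograde_volume`` ≥ 0 the integral of the
    positive flux; their signed sum is ``net_per_cycle``.
    """

    stroke_volume: float  # mL/cycle, signed
    antegrade_volume: float  # mL/cycle, <= 0
    retrograde_volume: float  # mL/cycle, >= 0
    net_per_cycle: float  # mL/cycle
    net_per_min: float  # mL/min = net_per_cycle * HR
    net_per_day: float  # L/24h = net_per_min * 1440 / 1000
    direction: str
    n_pixels: int
    heart_rate: float
    site: str
    aux_conventional_stroke_volume: float  # mL, (|ante| + |retro|) / 2


def flow_curve(field: VelocityField, require_corrected: bool = True) -> FlowCurve:
    """Q(t) = (Σ_i v_i)·dx·dy per frame, in mL/s.

    By default the field must carry all three corrections
    (venc_scaling, aliasing_correction, bias_subtraction); pass
    ``require_corrected=False`` to override explicitly.
    """
    missing = [c for c in CORRECTIONS if not field.has(c)]
    if require_corrected and missing:
        raise ValueError(
            f"field is missing corrections {missing}; apply them or pass "
            "require_corrected=False"
        )
    meta = field.meta
    q = field.velocities.sum(axis=1) * meta.pixel_area
    return FlowCurve(q=q, times=field.times, meta=meta)


def _periodic_trapezoid(q: np.ndarray, dt: float) -> float:
    # (dt/2) Σ (q[i] + q[i+1]) with q[n+1] ≡ q[1]; exact = dt·Σq for
    # uniform periodic sampling, kept in the two-point form for clarity.
    if q.size < 2:
        raise ValueError("need at least 2 frames to integrate")
    return float(0.5 * dt * np.sum(q + np.roll(q, -1)))


def integrate_cycle(curve: FlowCurve) -> float:
    """Signed volume per cycle (mL): periodic trapezoidal integral of Q."""
    return _periodic_trapezoid(curve.q, curve.dt)


def directional_volumes(curve: FlowCurve) -> tuple[float, float]:
    """Split Q into negative and positive fluxes and integrate each.

    Returns ``(antegrade_volume, retrograde_volume)`` = (∫q⁻, ∫q⁺) in mL;
    antegrade ≤ 0, retrograde ≥ 0, and their signed sum equals
    :func:`integrate_cycle` exactly because q⁺ + q⁻ = q pointwise.
    Clipping happens per frame, before integration.
    """
    q = curve.q
    antegrade = _periodic_trapezoid(np.minimum(q, 0.0), curve.dt)
    retrograde = _periodic_trapezoid(np.maximum(q, 0.0), curve.dt)
    return antegrade, retrograde


def classify_direction(net_per_cycle: float, site: str, zero_tol: float = 1e-12) -> str:
    """Label the net flow direction from its sign and the site.

    Aqueduct: negative → ``antegrade`` (3rd→4th), positive → ``retrograde``
    (4th→3rd).  CCJ: positive → ``upward`` (thecal sac → intracranial),
    negative → ``downward``.  |net| < ``zero_tol`` (mL) → ``zero``.
    """
    if site not in SITES:
        raise ValueError(f"site must be one of {SITES}, got {site!r}")
    if abs(net_per_cycle) < zero_tol:
        return "zero"
    if site == "aqueduct":
        return "antegrade" if net_per_cycle < 0 else "retrograde"
    return "upward" if net_per_cycle > 0 else "downward"


def net_flow_metrics(
    curve: FlowCurve,
    heart_rate: float | None = None,
    site: str | None = None,
    *,
    n_pixels: int = 0,
    zero_tol: float = 1e-12,
) -> FlowMetrics:
    """All cycle-integrated metrics and rate conversions for one curve.

    ``net_per_min = net_per_cycle × HR`` and
    ``net_per_day [L] = net_per_min × 1440 / 1000``.  ``heart_rate``
    defaults to 60/cycle_duration; when supplied it must be consistent
    with the acquisition's cycle duration (relative error < 1e-6).
    """
    meta = curve.meta
    if heart_rate is None:
        heart_rate = 60.0 / meta.cycle_duration
    else:
        if heart_rate <= 0:
            raise ValueError("heart_rate must be > 0")
        implied = 60.0 / heart_rate
        if abs(implied - meta.cycle_duration) > 1e-6 * meta.cycle_duration:
            raise ValueError(
                f"heart_rate {heart_rate} bpm implies cycle duration "
                f"{implied:.6g} s, inconsistent with meta.cycle_duration "
                f"{meta.cycle_duration:.6g} s"
            )
    if site is None:
        site = meta.site
    stroke = integrate_cycle(curve)
    antegrade, retrograde = directional_volumes(curve)
    net_cycle = antegrade + retrograde
    net_min = net_cycle * heart_rate
    net_day = net_min * 1440.0 / 1000.0
    return FlowMetrics(
        stroke_volume=stroke,
        antegrade_volume=antegrade,
        retrograde_volume=retrograde,
        net_per_cycle=net_cycle,
        net_per_min=net_min,
        net_per_day=net_day,
        direction=classify_direction(net_cycle, site, zero_tol),
        n_pixels=int(n_pixels),
        heart_rate=float(heart_rate),
        site=site,
        aux_conventional_stroke_volume=0.5 * (abs(antegrade) + abs(retrograde)),
    )
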