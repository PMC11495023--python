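"""Reading and writing of cardiac-gated PC-MRI data.

File contracts
--------------
* Phase-image series: 3-D NIfTI (``.nii``/``.nii.gz``) or NumPy ``.npy``
  with frame-major layout ``(frame, row, col)``; stored values are raw
  (unscaled) phase pixel values — all velocity scaling happens in
  :mod:`csfflow.velocity`.
* ROI masks: 2-D binary images in the same formats.
* Acquisition metadata: YAML with keys ``venc_cm_s``, ``dx_cm``, ``dy_cm``,
  ``n_frames``, ``cycle_duration_s`` or ``heart_rate_bpm``, ``raw_scale``,
  ``site``.
* Per-subject metric tables: RFC 4180 CSV, UTF-8, '.' decimal separator.

Coordinate convention: ``(row, col)``, 0-based, row 0 at image top; masks
and frames share it.  Through-plane sign: positive stored value = flow
toward the head (caudocranial).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TYPE_CHECKING

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .flow import FlowMetrics

__all__ = [
    "SITES",
    "AcquisitionMeta",
    "PhaseSeries",
    "RoiMask",
    "read_phase_series",
    "write_phase_series",
    "read_roi_mask",
    "write_roi_mask",
    "read_meta",
    "write_meta",
    "write_metrics_table",
    "read_metrics_table",
]

#: Anatomical measurement sites: the Sylvian aqueduct (3rd ↔ 4th ventricle)
#: and the cranio-cervical junction (thecal sac ↔ intracranial compartment).
SITES = ("aqueduct", "ccj")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition parameters of one cardiac-gated PC-MRI series.

    Parameters
    ----------
    venc : float
        Velocity-encoding limit in cm/s (> 0).  True velocities beyond
        ±VENC wrap by multiples of 2·VENC (aliasing).
    dx, dy : float
        In-plane pixel width and height in cm (> 0).
    n_frames : int
        Number of reconstructed cardiac phases (≥ 4).
    cycle_duration : float, optional
        Seconds per (averaged) cardiac cycle.  Exactly one of
        ``cycle_duration`` and ``heart_rate`` may be omitted; the other is
        derived via ``heart_rate * cycle_duration = 60``.
    heart_rate : float, optional
        Beats per minute.
    raw_scale : float
        Maximum absolute stored pixel value mapping to ±VENC (> 0).
    site : str
        One of :data:`SITES`.
    """

    venc: float
    dx: float
    dy: float
    n_frames: int
    cycle_duration: float | None = None
    heart_rate: float | None = None
    raw_scale: float = 4096.0
    site: str = "aqueduct"

    def __post_init__(self) -> None:
        if self.cycle_duration is None and self.heart_rate is None:
            raise ValueError("one of cycle_duration or heart_rate is required")
        if self.cycle_duration is None:
            object.__setattr__(self, "cycle_duration", 60.0 / float(self.heart_rate))
        if self.heart_rate is None:
            object.__setattr__(self, "heart_rate", 60.0 / float(self.cycle_duration))
        for name in ("venc", "dx", "dy", "cycle_duration", "heart_rate", "raw_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if int(self.n_frames) != self.n_frames or self.n_frames < 4:
            raise ValueError(f"n_frames must be an integer >= 4, got {self.n_frames}")
        object.__setattr__(self, "n_frames", int(self.n_frames))
        if abs(self.heart_rate * self.cycle_duration - 60.0) > 1e-9:
            raise ValueError(
                "inconsistent timing: heart_rate * cycle_duration = "
                f"{self.heart_rate * self.cycle_duration!r}, expected 60"
            )
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")

    @property
    def dt(self) -> float:
        """Temporal resolution in seconds (cycle_duration / n_frames)."""
        return self.cycle_duration / self.n_frames

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area dx·dy in cm²."""
        return self.dx * self.dy

    def frame_times(self) -> np.ndarray:
        """Frame midpoint times in seconds, uniformly spaced in [0, T)."""
        return (np.arange(self.n_frames) + 0.5) * self.dt

    def to_dict(self) -> dict:
        return {
            "venc_cm_s": float(self.venc),
            "dx_cm": float(self.dx),
            "dy_cm": float(self.dy),
            "n_frames": int(self.n_frames),
            "cycle_duration_s": float(self.cycle_duration),
            "heart_rate_bpm": float(self.heart_rate),
            "raw_scale": float(self.raw_scale),
            "site": self.site,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(
            venc=d["venc_cm_s"],
            dx=d["dx_cm"],
            dy=d["dy_cm"],
            n_frames=d["n_frames"],
            cycle_duration=d.get("cycle_duration_s"),
            heart_rate=d.get("heart_rate_bpm"),
            raw_scale=d.get("raw_scale", 4096.0),
            site=d.get("site", "aqueduct"),
        )


@dataclass(frozen=True)
class PhaseSeries:
    """Raw gated phase frames with acquisition metadata.

    ``frames`` has shape ``(n_frames, rows, cols)`` and holds the stored
    (unscaled) pixel values.  ``allow_overrange`` marks a series whose
    values legitimately exceed ``raw_scale`` (e.g. a synthetic series
    generated without velocity wrapping).
    """

    frames: np.ndarray
    meta: AcquisitionMeta
    allow_overrange: bool = False

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError(f"expected 3-D gated series, got {frames.ndim}-D data")
        if frames.shape[0] != self.meta.n_frames:
            raise ValueError(
                f"frame count mismatch: file has {frames.shape[0]} frames, "
                f"metadata declares {self.meta.n_frames}"
            )
        if not np.all(np.isfinite(frames)):
            raise ValueError("phase series contains non-finite values")
        if not self.allow_overrange and np.max(np.abs(frames)) > self.meta.raw_scale * (1 + 1e-12):
            raise ValueError(
                "stored values exceed raw_scale; pass allow_overrange=True for "
                "known-unwrapped input"
            )
        object.__setattr__(self, "frames", frames)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass(frozen=True)
class RoiMask:
    """A region of interest as a set of (row, col) pixel coordinates.

    ``kind`` is ``"target"`` for the CSF lumen (aqueduct or CCJ) and
    ``"reference"`` for the nearby static-tissue region used for noise
    assessment and bias estimation.
    """

    pixels: tuple[tuple[int, int], ...]
    kind: str
    shape: tuple[int, int]
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("target", "reference"):
            raise ValueError(f"kind must be 'target' or 'reference', got {self.kind!r}")
        pixels = tuple(sorted((int(r), int(c)) for r, c in self.pixels))
        if not pixels:
            raise ValueError("empty ROI: mask has no pixels")
        rows, cols = self.shape
        for r, c in pixels:
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"pixel ({r}, {c}) outside frame bounds {self.shape}")
        object.__setattr__(self, "pixels", pixels)

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def index(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) integer arrays for fancy indexing into frames."""
        arr = np.asarray(self.pixels)
        return arr[:, 0], arr[:, 1]

    def to_array(self) -> np.ndarray:
        """Boolean mask image of shape ``self.shape``."""
        out = np.zeros(self.shape, dtype=bool)
        out[self.index] = True
        return out

    def disjoint(self, other: "RoiMask") -> bool:
        return not set(self.pixels) & set(other.pixels)


# ---------------------------------------------------------------------------
# file I/O


def _load_array(path: str | os.PathLike) -> np.ndarray:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    if path.endswith(".npy"):
        return np.load(path)
    img = nib.load(path)
    return np.asarray(img.get_fdata(dtype=np.float64))


def _save_array(arr: np.ndarray, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    if path.endswith(".npy"):
        np.save(path, arr)
    else:
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), np.eye(4)), path)


def read_phase_series(
    path: str | os.PathLike,
    meta: AcquisitionMeta,
    allow_overrange: bool = False,
) -> PhaseSeries:
    """Read a gated phase series (NIfTI or .npy) with frame-major layout.

    Frames must be ordered by cardiac phase; no rescaling is applied —
    stored values stay raw until :func:`csfflow.velocity.to_velocity`.
    """
    data = _load_array(path)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D gated series in {path}, got {data.ndim}-D data")
    return PhaseSeries(frames=data, meta=meta, allow_overrange=allow_overrange)


def write_phase_series(series: PhaseSeries, path: str | os.PathLike) -> None:
    _save_array(series.frames, path)


def read_roi_mask(
    path: str | os.PathLike,
    shape: tuple[int, int],
    kind: str,
    label: str = "",
) -> RoiMask:
    """Read a 2-D binary mask; pixels are the coordinates of nonzero entries."""
    data = _load_array(path)
    if data.ndim != 2:
        raise ValueError(f"expected 2-D mask in {path}, got {data.ndim}-D data")
    if data.shape != tuple(shape):
        raise ValueError(
            f"mask shape {data.shape} does not match frame shape {tuple(shape)}"
        )
    rows, cols = np.nonzero(data)
    if rows.size == 0:
        raise ValueError(f"empty ROI: mask {path} has no nonzero pixels")
    return RoiMask(
        pixels=tuple(zip(rows.tolist(), cols.tolist())),
        kind=kind,
        shape=tuple(shape),
        label=label,
    )


def write_roi_mask(mask: RoiMask, path: str | os.PathLike) -> None:
    _save_array(mask.to_array().astype(np.uint8), path)


def read_meta(path: str | os.PathLike) -> AcquisitionMeta:
    with open(path, "r", encoding="utf-8") as fh:
        return AcquisitionMeta.from_dict(yaml.safe_load(fh))


def write_meta(meta: AcquisitionMeta, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# metrics tables

#: Deterministic column order of the per-subject metrics CSV.
METRICS_COLUMNS = [
    "id",
    "site",
    "n_pixels",
    "heart_rate_bpm",
    "stroke_volume_mL",
    "antegrade_volume_mL",
    "retrograde_volume_mL",
    "net_mL_per_cycle",
    "net_mL_per_min",
    "net_L_per_day",
    "direction",
    "aux_conventional_stroke_volume_mL",
    "net_mL_per_cycle_3dp",
    "net_mL_per_min_2dp",
]


def write_metrics_table(
    records: Sequence[tuple[str, "FlowMetrics"]],
    path: str | os.PathLike,
) -> pd.DataFrame:
    """Write one CSV row per subject: identifiers, volumes and rates.

    ``records`` is a non-empty sequence of ``(subject_id, FlowMetrics)``
    pairs.  Full-precision columns round-trip bit-for-bit (floats are
    serialised with ``repr``); ``*_3dp``/``*_2dp`` are rounded display
    copies of the per-cycle and per-minute net flow.
    """
    if not records:
        raise ValueError("records must be non-empty")
    rows = []
    for subject_id, m in records:
        rows.append(
            {
                "id": subject_id,
                "site": m.site,
                "n_pixels": m.n_pixels,
                "heart_rate_bpm": m.heart_rate,
                "stroke_volume_mL": m.stroke_volume,
                "antegrade_volume_mL": m.antegrade_volume,
                "retrograde_volume_mL": m.retrograde_volume,
                "net_mL_per_cycle": m.net_per_cycle,
                "net_mL_per_min": m.net_per_min,
                "net_L_per_day": m.net_per_day,
                "direction": m.direction,
                "aux_conventional_stroke_volume_mL": m.aux_conventional_stroke_volume,
                "net_mL_per_cycle_3dp": round(m.net_per_cycle, 3),
                "net_mL_per_min_2dp": round(m.net_per_min, 2),
            }
        )
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    # serialise floats via repr: shortest string that round-trips the double
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == float:
            out[col] = out[col].map(lambda x: repr(float(x)))
    out.to_csv(path, index=False)
    return df


def read_metrics_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
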