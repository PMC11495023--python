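import numpy as np
import pytest

from csfflow import AcquisitionMeta, RoiMask, VelocityField
from csfflow.flow import classify_direction, FlowMetrics
from csfflow.velocity import CORRECTIONS


@pytest.fixture
def meta():
    """Small, exactly-timed acquisition: 8 frames over a 1 s cycle."""
    return AcquisitionMeta(
        venc=10.0, dx=0.05, dy=0.05, n_frames=8, cycle_duration=1.0, raw_scale=100.0
    )


def make_field(values, meta, kind="target", corrected=True, shape=(64, 64)):
    """VelocityField from a (n_frames, n_pixels) array on arbitrary pixels."""
    values = np.asarray(values, dtype=float)
    n_pix = values.shape[1]
    pixels = tuple((i // shape[1], i % shape[1]) for i in range(n_pix))
    mask = RoiMask(pixels=pixels, kind=kind, shape=shape)
    return VelocityField(
        velocities=values,
        times=meta.frame_times(),
        mask=mask,
        meta=meta,
        corrections_applied=CORRECTIONS if corrected else ("venc_scaling",),
    )


def make_metrics(net_per_cycle, site="aqueduct", heart_rate=60.0, n_pixels=26):
    """Internally consistent FlowMetrics with the given net volume."""
    ante = min(net_per_cycle, 0.0)
    retro = max(net_per_cycle, 0.0)
    return FlowMetrics(
        stroke_volume=net_per_cycle,
        antegrade_volume=ante,
        retrograde_volume=retro,
        net_per_cycle=net_per_cycle,
        net_per_min=net_per_cycle * heart_rate,
        net_per_day=net_per_cycle * heart_rate * 1.44,
        direction=classify_direction(net_per_cycle, site),
        n_pixels=n_pixels,
        heart_rate=heart_rate,
        site=site,
        aux_conventional_stroke_volume=0.5 * (abs(ante) + abs(retro)),
    )
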