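import matplotlib
matplotlib.use("Agg")

from dataclasses import replace

import numpy as np
import pytest

from ovotrace import RecordingSchedule, SyntheticSpec, generate_sequence
from ovotrace.segmentation import locate_egg


@pytest.fixture(scope="session")
def short_schedule():
    """Desk-scale schedule: 40 frames at 20 fps, hourly, 6 recordings."""
    return RecordingSchedule(
        frames_per_sequence=40,
        frame_rate=20.0,
        repeat_interval_min=60.0,
        n_timepoints=6,
    )


@pytest.fixture(scope="session")
def default_sequence():
    """One full-length (600 frame, 20 fps) recording plus its ground truth."""
    spec = SyntheticSpec(seed=7)
    return generate_sequence(spec, 0)


@pytest.fixture(scope="session")
def default_roi(default_sequence):
    seq, _ = default_sequence
    return locate_egg(seq)


@pytest.fixture(scope="session")
def clean_sequence():
    """Noise-free, motion-free scene: only the heart phase varies."""
    spec = SyntheticSpec(
        seed=3,
        noise_sigma=0.0,
        rotation_deg_s=0.0,
        rw_step_px=0.0,
        orbit_radius_px=0.0,
        growth_rate_px2_h=0.0,
    )
    return generate_sequence(spec, 0), spec
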