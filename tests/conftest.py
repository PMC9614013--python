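"""Shared fixtures: rendered synthetic scenes run through the full pipeline.

The two video fixtures are expensive (about a minute each), so they are
session-scoped and shared between the feature tests and the acceptance
suite.  Both are noise-free so that planted rhythms can be recovered
against ground truth.
"""

from __future__ import annotations

import numpy as np
import pytest

from infantmotion.config import RunConfig
from infantmotion.features import extract_all
from infantmotion.kinematics import compute_motion_series
from infantmotion.preprocessing import FrameStack, split_subsegments
from infantmotion.regions import compute_regions
from infantmotion.synthetic_data import (DriftSpec, LimbSpec, VideoSimParams,
                                         render_infant_video)

#: planted rhythms of the limb scene
LIMB_FREQ_UPPER = 2.2
LIMB_FREQ_LOWER = 2.8
#: planted body-center drift of the drift scene
DRIFT_FREQ_X = 0.3
DRIFT_FREQ_Y = 0.5


def run_video_pipeline(params: VideoSimParams, config: RunConfig):
    frames, background, truth = render_infant_video(params)
    stack = FrameStack(frames=frames, fps=params.fps, background=background)
    masks = split_subsegments(stack, config)
    regions = compute_regions(masks, config)
    motion = compute_motion_series(masks, regions, config)
    fv = extract_all(motion, config)
    return {"frames": frames, "background": background, "truth": truth,
            "masks": masks, "regions": regions, "motion": motion,
            "features": fv, "params": params}


@pytest.fixture(scope="session")
def limb_scene():
    """Noise-free scene with rhythmic limbs (upper 2.2 Hz, lower 2.8 Hz)."""
    params = VideoSimParams(
        width=480, height=360, fps=30.0, duration_s=48.0,
        body_center=(180.0, 240.0), body_axes=(62.0, 36.0),
        limb_specs=[
            LimbSpec(1, LIMB_FREQ_UPPER, 24.0, 1.0, size_px=11, speed_mod=0.15),
            LimbSpec(2, LIMB_FREQ_UPPER, 24.0, 1.0, size_px=11, speed_mod=0.15),
            LimbSpec(3, LIMB_FREQ_LOWER, 24.0, 1.0, size_px=11, speed_mod=0.15),
            LimbSpec(4, LIMB_FREQ_LOWER, 24.0, 1.0, size_px=11, speed_mod=0.15),
        ],
        drift_spec=DriftSpec(sinusoids_y=[(0.5, 8.0)]),
        noise_gauss_sd=0.0, noise_salt_pepper=0.0, seed=11)
    return run_video_pipeline(params, RunConfig())


@pytest.fixture(scope="session")
def drift_scene():
    """Noise-free limbless scene with planted body-center drift."""
    params = VideoSimParams(
        width=320, height=240, fps=30.0, duration_s=48.0,
        body_center=(120.0, 160.0), body_axes=(55.0, 30.0),
        limb_specs=[],
        drift_spec=DriftSpec(sinusoids_x=[(DRIFT_FREQ_X, 6.0)],
                             sinusoids_y=[(DRIFT_FREQ_Y, 8.0)]),
        noise_gauss_sd=0.0, noise_salt_pepper=0.0, seed=12)
    return run_video_pipeline(params, RunConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
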