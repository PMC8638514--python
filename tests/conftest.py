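"""Shared fixtures: small rendered phantoms and the session benchmark."""

from __future__ import annotations

import numpy as np
import pytest

from mvtrack import MotionProfileParams, RenderParams, render_cine


@pytest.fixture(scope="session")
def default_motion() -> MotionProfileParams:
    return MotionProfileParams(mapse_mm=15.0, hr_bpm=60.0, n_frames=30)


@pytest.fixture(scope="session")
def rendered_pair(default_motion):
    """One noise-free upright two-chamber phantom with its annotation."""
    cine, ann = render_cine(
        MotionProfileParams(mapse_mm=15.0, hr_bpm=60.0, n_frames=30, noise_sd=0.0),
        RenderParams(),
        seed=42,
    )
    return cine, ann


@pytest.fixture(scope="session")
def rotated_pair():
    """A rotated, anisotropic-spacing four-chamber phantom."""
    cine, ann = render_cine(
        MotionProfileParams(mapse_mm=12.0, hr_bpm=75.0, n_frames=28, noise_sd=0.02),
        RenderParams(
            pixel_spacing_mm=(1.3, 1.7),
            image_size=(190, 170),
            heart_rotation_deg=147.0,
            view="four_chamber",
        ),
        seed=7,
    )
    return cine, ann


@pytest.fixture(scope="session")
def trained_benchmark():
    """The full desk-scale synthetic study (simulate, train, track).

    Session-scoped because training the two tiny regressors dominates the
    suite's runtime; every consumer reads from the same frozen run.
    """
    from mvtrack.benchmark import run_benchmark

    return run_benchmark(seed=20240317 % 2**31)
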