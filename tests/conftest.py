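"""Shared fixtures: synthetic plates at desk scale (12 px/mm).

The heavy 64-seed, 96-frame plates are generated once per session and
shared between the recovery/germination tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from rhizolapse.pipeline import PipelineParams, run_pipeline
from rhizolapse.synthetic import SyntheticConfig, generate_plate_series

DESK_SCALE = 12.0  # px/mm used for synthetic runs


@pytest.fixture(scope="session")
def small_plate():
    """2x2 plate, 10 hourly frames, constant 0.15 mm/h, with truth masks."""
    cfg = SyntheticConfig(
        rows=2,
        cols=2,
        scale_px_per_mm=DESK_SCALE,
        n_frames=10,
        rng_seed=7,
        germ_delay_h=(0.0, 4.0),
        rate_mm_per_h=0.15,
        germ_prob=1.0,
    )
    series, records, masks = generate_plate_series(cfg, return_masks=True)
    return cfg, series, records, masks


@pytest.fixture(scope="session")
def noiseless_plate():
    """2x2 noiseless plate for oracle-grade segmentation checks."""
    cfg = SyntheticConfig(
        rows=2,
        cols=2,
        scale_px_per_mm=DESK_SCALE,
        n_frames=5,
        rng_seed=8,
        noise_sd=0.0,
        germ_delay_h=0.0,
        rate_mm_per_h=0.15,
        germ_prob=1.0,
    )
    series, records, masks = generate_plate_series(cfg, return_masks=True)
    return cfg, series, records, masks


@pytest.fixture(scope="session")
def rate_recovery_run():
    """64 seeds, true rates U(0.03, 0.17) mm/h, 96 hourly frames, analyzed."""
    cfg = SyntheticConfig(
        rows=8,
        cols=8,
        scale_px_per_mm=DESK_SCALE,
        n_frames=96,
        rng_seed=11,
        germ_delay_h=(0.0, 24.0),
        rate_mm_per_h=(0.03, 0.17),
        germ_prob=1.0,
    )
    series, records = generate_plate_series(cfg)
    result = run_pipeline(series, params=PipelineParams())
    return cfg, records, result


@pytest.fixture(scope="session")
def germination_run():
    """64 seeds at default (wild-type-like) conditions, 10% never germinate."""
    cfg = SyntheticConfig(
        rows=8,
        cols=8,
        scale_px_per_mm=DESK_SCALE,
        n_frames=96,
        rng_seed=13,
        germ_prob=0.9,
    )
    series, records = generate_plate_series(cfg)
    result = run_pipeline(series, params=PipelineParams())
    return cfg, records, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
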