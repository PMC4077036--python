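"""Shared fixtures: small synthetic recordings rendered once per session."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from nucseg.dogfilter import DoGSpec, filter_frame
from nucseg.imgdata import ImageStack, VoxelSpacing
from nucseg.segmenters import default_params_for_diameter
from nucseg.synthgen import SynthConfig, generate_series


@pytest.fixture(scope="session")
def easy_series():
    """Three frames, 8 well-separated bright nuclei: every method should
    detect all of them."""
    cfg = SynthConfig(
        shape=(30, 128, 128),
        schedule=[(0, 8)],
        n_frames=3,
        diameter_um=4.5,
        min_separation_um=9.0,
        peak_intensity=0.7,
        background=0.1,
        noise_sigma=0.01,
        seed=11,
    )
    series, gt = generate_series(cfg)
    return cfg, series, gt


@pytest.fixture(scope="session")
def easy_filtered(easy_series):
    """DoG-filtered middle frame of the easy series."""
    cfg, series, gt = easy_series
    spec = DoGSpec(l_xy=4.0, dim="3D")
    resp = filter_frame(series, spec, 1)
    return ImageStack(resp, series.spacing), gt


@pytest.fixture(scope="session")
def screened_params():
    """Parameters appropriate for 4.5-um nuclei at 0.6 contrast."""
    return default_params_for_diameter(4.5, VoxelSpacing(), contrast=0.6)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
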