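import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from projep import analysis, synth

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params() -> synth.SynthesisParams:
    return synth.SynthesisParams(seed=11)


@pytest.fixture(scope="session")
def default_layout(default_params):
    return synth.make_layout(default_params)


@pytest.fixture(scope="session")
def default_stack(default_layout, default_params):
    return synth.render_stack(default_layout, default_params)


@pytest.fixture(scope="session")
def default_records(default_stack):
    return analysis.analyze_stack(default_stack)


@pytest.fixture(scope="session")
def clean_single_band():
    """Noise-free single-species gel: every well occupied, fixed abundance."""
    params = synth.SynthesisParams(
        wells_per_side=2,
        seed=3,
        voxel_dxy_um=4.0,
        species=(synth.SynthSpecies("GAPDH", 8.65e-5, 16.8, "ch_gapdh"),),
        occupancy_p=1.0,
        doublet_p=0.0,
        abundance_cv=0.0,
        noise_sd_frac=0.0,
        background_frac=0.0,
    )
    layout = synth.make_layout(params)
    stack = synth.render_stack(layout, params)
    return params, layout, stack


def match_band(layout, x_um, y_um, channel):
    """Ground-truth band row nearest an (x, y) anchor for one channel."""
    b = layout.bands[layout.bands.channel == channel]
    d = np.hypot(b.x_um - x_um, b.y_um - y_um)
    return b.loc[d.idxmin()]
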