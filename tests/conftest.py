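import numpy as np
import pytest

from calsig import defaults as dflt
from calsig import synth

STIM = dflt.DEFAULT_PRESTIM_S


@pytest.fixture(scope="session")
def atp_grid():
    return synth.default_time_grid("ATP")


@pytest.fixture(scope="session")
def wound_grid():
    return synth.default_time_grid("wound")


@pytest.fixture(scope="session")
def rendered_monolayer():
    """A small rendered ATP monolayer shared across segmentation tests."""
    import warnings
    layout = synth.make_monolayer_layout(n_cells=121, rng_seed=4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seq, _ = synth.render_sequence(layout, frame_interval_s=300.0,
                                       duration_s=2220.0, rng_seed=104)
    return seq, layout


def canonical_params(secondary: str, noise_sd: float = 0.0):
    """One representative TransientParams per taxonomy class."""
    rng = np.random.default_rng(0)
    if secondary in synth.ATP_CLASSES:
        return synth.atp_shape_priors(noise_sd)[secondary](rng)
    return synth.wound_shape_priors("proximal", noise_sd)[secondary](rng)
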