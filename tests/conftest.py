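import numpy as np
import pytest

from ochip_loop.plant import Droplet, LDPlantState


def droplet_state(droplets, frame_shape=(256, 256), **kwargs):
    """LDPlantState around an explicit droplet list (y, x order in shape)."""
    return LDPlantState(
        droplets=tuple(Droplet(x=x, y=y, radius=r) for (x, y, r) in droplets),
        frame_shape=frame_shape,
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def single_droplet_frame():
    """One droplet of radius 20 centered in a 256x256 frame."""
    from ochip_loop.plant import render_frame

    state = droplet_state([(128.0, 128.0, 20.0)])
    return render_frame(state), state
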