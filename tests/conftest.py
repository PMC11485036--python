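import numpy as np
import pytest

from avicontrast.excitation import (
    adapt_to_background,
    naka_rushton,
    subtract_dark,
)
from avicontrast.scene import SceneSpec, render_scene
from avicontrast.spectral import build_cone_system


@pytest.fixture(scope="session")
def system():
    return build_cone_system()


@pytest.fixture(scope="session")
def noiseless_spec():
    """Scene with sensor noise and background texture both disabled: every
    material region is exactly piecewise constant."""
    return SceneSpec(noise_sd=0.0, block_texture_sd=0.0, block_tilt_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_spec, system):
    return render_scene(noiseless_spec, system)


@pytest.fixture(scope="session")
def noiseless_excitation(noiseless_scene):
    """Dark-subtracted, background-adapted, Naka-Rushton excitations."""
    stack, rois = noiseless_scene
    return naka_rushton(adapt_to_background(subtract_dark(stack))), rois
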