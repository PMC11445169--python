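import numpy as np
import pytest

from dropclass import SyntheticSceneConfig, render_droplet


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, beadline-free scene with no neighbor intrusions."""
    return SyntheticSceneConfig(
        noise_sd=0.0, beadline=False, beadline_irregularity=0.0, neighbor_fragments=0
    )


@pytest.fixture(scope="session")
def single_cell_droplet(clean_scene):
    from dataclasses import replace

    return render_droplet(replace(clean_scene, n_cells=1, seed=8))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
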