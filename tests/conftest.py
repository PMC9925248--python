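import numpy as np
import pytest

from lesionseg.synthetic_data import SceneSpec, make_scene


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_scene():
    """A deterministic 64x64 scene with a clean lesion."""
    return make_scene(SceneSpec(size=64, seed=3))


@pytest.fixture
def dataset_dir(tmp_path):
    """A tiny on-disk dataset with the images/ + masks/ layout."""
    from lesionseg import cli_io
    from lesionseg.synthetic_data import make_dataset

    for i, (image, mask) in enumerate(make_dataset(3, SceneSpec(size=32), seed=5)):
        cli_io.write_image(tmp_path / "images" / f"s{i}.png", image)
        cli_io.write_mask(tmp_path / "masks" / f"s{i}.png", mask)
    return tmp_path
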