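import numpy as np
import pytest

from ewenet.model import ArchitectureSpec
from ewenet.synthetic import SceneConfig, generate_scene

#: Event-shape prototypes sized for 64-pixel-input experiments: one per
#: detection head (strides 4/8/16/32).
TINY_PROTOTYPES = ((0.09, 0.12), (0.18, 0.22), (0.35, 0.40), (0.60, 0.65))


@pytest.fixture(scope="session")
def tiny_scene_config() -> SceneConfig:
    return SceneConfig(
        canvas=(128, 128),
        n_events=2,
        n_distractors=3,
        input_size=64,
        prototypes=TINY_PROTOTYPES,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_scenes(tiny_scene_config):
    """Eight deterministic scenes: (images, per-image box lists)."""
    images, boxes = [], []
    for i in range(8):
        img, ann = generate_scene(tiny_scene_config, i)
        images.append(img)
        boxes.append(ann.boxes())
    return images, boxes


@pytest.fixture(scope="session")
def tiny_spec() -> ArchitectureSpec:
    return ArchitectureSpec.tiny(64)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
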