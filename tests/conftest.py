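import numpy as np
import pytest

from portnet.config import ArchitectureConfig, BlockSpec
from portnet.synthetic import ClassRecipe, SyntheticSpec, generate


def random_valid_config(rng: np.random.Generator) -> ArchitectureConfig:
    """A random architecture within the family: random widths in [8, 256],
    random SE hidden widths in [1, C_out], depth 3-8 blocks."""
    depth = rng.integers(3, 9)
    widths = [int(rng.integers(8, 257)) for _ in range(depth)]
    blocks = [BlockSpec("stem", 3, widths[0], int(rng.choice([1, 2])))]
    for i in range(1, depth):
        ci, co = widths[i - 1], widths[i]
        h = int(rng.integers(1, co + 1))
        if ci == co and rng.random() < 0.5:
            blocks.append(BlockSpec("id_block", ci, co, 1, h))
        else:
            stride = 2 if ci == co else int(rng.choice([1, 2]))
            blocks.append(BlockSpec("proj_block", ci, co, stride, h))
    nc = int(rng.integers(2, 11))
    blocks.append(BlockSpec("head", widths[-1], nc))
    stride_prod = int(np.prod([b.stride for b in blocks[:-1]]))
    cfg = ArchitectureConfig(blocks=blocks, num_classes=nc,
                             input_size=32 * stride_prod)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_synthetic():
    """15 images (5/class) with masks, 96x96, fixed seed."""
    return generate(SyntheticSpec(n_per_class=5, size=96, seed=3))


@pytest.fixture(scope="session")
def blob_recipes():
    """Blob-vs-background classes with large round objects and distinct
    palettes; used for the localization checks."""
    return [
        ClassRecipe("c0", 6, 14, 2, (0.8, 1.0), (150, 60, 150)),
        ClassRecipe("c1", 6, 14, 2, (0.8, 1.0), (220, 150, 160)),
        ClassRecipe("c2", 6, 14, 2, (0.8, 1.0), (90, 120, 190)),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
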