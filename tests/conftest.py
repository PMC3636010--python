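import numpy as np
import pytest

from phytoscope import synthetic as syn
from phytoscope.frames import FrameSet


@pytest.fixture(scope="session")
def default_templates():
    return syn.default_taxon_templates()


@pytest.fixture(scope="session")
def rendered_scene(default_templates):
    """One 512x512 scene with two particles of every default template."""
    spec = syn.SceneSpec(
        image_size=(512, 512),
        templates=[(t, 2) for t in default_templates],
        rng_seed=7,
    )
    frame, truth = syn.render_scene(spec)
    return spec, frame, truth


@pytest.fixture
def flat_frame():
    """A particle-free frame whose bright-field equals its blank."""
    img = np.full((64, 64, 3), 200, dtype=np.uint8)
    zero = np.zeros((64, 64), dtype=np.uint8)
    return FrameSet(brightfield=img.copy(), blank=img.copy(),
                    fluor_chl=zero.copy(), fluor_pe=zero.copy(),
                    fluor_pc=zero.copy(), frame_id="flat")


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
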