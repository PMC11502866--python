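import numpy as np
import pytest

from ciliamorph import synthetic
from ciliamorph.core import Polyline3D


@pytest.fixture(scope="session")
def mouse_scene():
    """One full mouse-preset scene, shared by profile/interaction tests."""
    return synthetic.generate_scene("mouse-fibsem", seed=11)


@pytest.fixture(scope="session")
def small_scene():
    """A short straight cilium with two in-range neighbours and one distant
    one; cheap enough for repeated contact/pocket assertions."""
    axo = synthetic.AxonemeSpec(
        n_doublets=9,
        triplet_length=0.0,
        a_lengths=(800.0,) * 9,
        b_lengths=(500.0,) * 9,
        wiggle_amplitude=0.0,
    )
    scene_spec = synthetic.SceneSpec(
        pocket_length=300.0,
        neighbor_gaps=(
            ("neighbor:beta", 10.0),
            ("neighbor:acinar", 50.0),
            ("neighbor:endothelial", 10.0),
        ),
        axon_present=False,
        seed=0,
    )
    skeletons, truth = synthetic.generate_axoneme(axo, seed=0)
    return synthetic.voxelize_scene(skeletons, scene_spec, truth=truth)


def straight_polyline(n=11, step=10.0, source_id=0, tubule_class="A"):
    pts = np.zeros((n, 3))
    pts[:, 0] = np.arange(n) * step
    return Polyline3D(pts, tubule_class=tubule_class, source_id=source_id)
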