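import numpy as np
import pytest

from pancmorph import PhantomSpec, generate_organ_phantom
from pancmorph.cli import make_demo_dataset


@pytest.fixture(scope="session")
def small_ellipsoid():
    """Exact digitised ellipsoid, radii (30, 20, 15) mm at 1 mm isotropic."""
    spec = PhantomSpec(
        base_radii=(30.0, 20.0, 15.0),
        serration_amplitude=0.0,
        voxel_spacing=(1.0, 1.0, 1.0),
        grid_shape=(64, 48, 40),
        seed=0,
    )
    return generate_organ_phantom(spec)


@pytest.fixture(scope="session")
def serrated_phantom():
    """Moderately serrated phantom at the default study resolution."""
    return generate_organ_phantom(PhantomSpec(serration_amplitude=0.2, seed=3))


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """The simulated demo dataset (4 participants x 3 timepoints)."""
    out = tmp_path_factory.mktemp("demo")
    make_demo_dataset(str(out), seed=5, n_participants=4)
    return out


def brute_force_box_count(img: np.ndarray, size: int) -> int:
    """Independent double-loop occupied-box counter (zero grid origin)."""
    img = np.asarray(img, dtype=bool)
    n = 0
    for r0 in range(0, img.shape[0], size):
        for c0 in range(0, img.shape[1], size):
            if img[r0 : r0 + size, c0 : c0 + size].any():
                n += 1
    return n
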