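import numpy as np
import pytest

from rhizoct.phantom import PhantomSpec, generate_phantom
from rhizoct.volume_io import LabelVolume, ROOT, SOLID


def desk_phantom_spec(seed: int = 1, **overrides) -> PhantomSpec:
    """Desk-scale rooted phantom: 0-3 mm shells fit at 64 µm voxels."""
    kwargs = dict(
        shape=(64, 112, 112),
        voxel_size=64.0,
        root_radius=500.0,
        porosity_profile=[(0.0, 1.0, 0.28)],
        far_porosity=0.24,
        pore_radius_range=(128.0, 256.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def rooted_phantom():
    """One generated rooted phantom shared by segmentation/geometry tests."""
    spec = desk_phantom_spec(seed=1)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


def make_cylinder_labels(
    shape=(32, 224, 224), voxel_size=25.0, radius_um=500.0
) -> LabelVolume:
    """Straight solid cylinder root along z, centred laterally; rest solid."""
    nz, ny, nx = shape
    yy, xx = np.meshgrid(
        np.arange(ny) - (ny - 1) / 2.0, np.arange(nx) - (nx - 1) / 2.0, indexing="ij"
    )
    r_vox = radius_um / voxel_size
    disc = yy**2 + xx**2 <= r_vox**2
    labels = np.full(shape, SOLID, dtype=np.uint8)
    labels[:, disc] = ROOT
    return LabelVolume(data=labels, voxel_size=voxel_size)


@pytest.fixture(scope="session")
def cylinder_labels():
    return make_cylinder_labels()
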