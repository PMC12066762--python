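import numpy as np
import pytest

from seedtrack import shape3d, synthdata


@pytest.fixture(scope="session")
def sphere_carve():
    """Rendered + carved 0.25 mm-radius sphere at 5 µm voxels, with truth."""
    spec = synthdata.ShapeSpec(kind="sphere", semi_axes=(0.25, 0.25, 0.25))
    stack, truth = synthdata.render_silhouettes(spec, pixel_size=5.0)
    hull = shape3d.carve_hull(stack, voxel_size=5.0)
    return stack, hull, truth


@pytest.fixture(scope="session")
def triaxial_carve():
    """Triaxial ellipsoid (0.25/0.155/0.135 mm semi-axes), carved."""
    spec = synthdata.ShapeSpec(kind="ellipsoid", semi_axes=(0.25, 0.155, 0.135))
    stack, truth = synthdata.render_silhouettes(spec, pixel_size=5.0)
    hull = shape3d.carve_hull(stack, voxel_size=5.0)
    return stack, hull, truth


def disk_image(shape=(80, 80), center=(40, 40), radius=15.0, fg=30, bg=220):
    """Backlit-style greyscale disk: dark foreground on bright background."""
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    img = np.full(shape, bg, dtype=np.uint8)
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2] = fg
    return img
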