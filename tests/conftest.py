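import numpy as np
import pytest

from pancmri.imaging import Contour, ContourStack, GridSpec, ImageVolume


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec((20, 20, 6), (3.0, 3.0), 4.0)


@pytest.fixture
def square_stack() -> ContourStack:
    """One 30x30 mm square contour centered on slice 2 of a 3 mm grid."""
    # grid voxel centers run 0..57 mm; center the square at 28.4 mm so its
    # edges fall strictly between voxel centers at both 3 and 1.5 mm
    half = 15.0
    cx = cy = 28.4
    verts = np.array(
        [[cx - half, cy - half], [cx + half, cy - half], [cx + half, cy + half], [cx - half, cy + half]]
    )
    return ContourStack([Contour(2, verts)], frame_spacing=4.0)


def constant_volume(grid: GridSpec, value: float, description: str = "") -> ImageVolume:
    return ImageVolume(
        np.full(grid.shape, value), grid.in_plane_spacing, grid.slice_spacing, grid.origin, description
    )
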