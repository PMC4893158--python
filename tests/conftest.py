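import numpy as np
import pytest

from nanoclust.clustermap import Cluster
from nanoclust.io_formats import RegionOfInterest


@pytest.fixture
def window():
    """Standard 3 x 3 um analysis window."""
    return RegionOfInterest(0.0, 0.0, 3000.0, 3000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_disc_cluster(cid, cx, cy, radius, pixel_size=20.0, shape=(256, 256)):
    """Cluster whose pixel footprint is the disc of the given radius (nm)."""
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    px = (xs + 0.5) * pixel_size
    py = (ys + 0.5) * pixel_size
    sel = (px - cx) ** 2 + (py - cy) ** 2 <= radius**2
    pix = np.argwhere(sel)
    assert len(pix) > 0
    return Cluster(
        id=cid,
        pixels=pix,
        pixel_size=pixel_size,
        area=len(pix) * pixel_size**2,
        centroid=(float(cx), float(cy)),
    )


def make_point_cluster(cid, iy, ix, pixel_size=10.0):
    """Single-pixel ("point-like") cluster."""
    return Cluster(
        id=cid,
        pixels=np.array([[iy, ix]]),
        pixel_size=pixel_size,
        area=pixel_size**2,
        centroid=((ix + 0.5) * pixel_size, (iy + 0.5) * pixel_size),
    )
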