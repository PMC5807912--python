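import math

import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from angioquant import SampleSpec


def disk_mask(shape, center_rc, radius_px):
    """Boolean mask of a filled disk (pixel units)."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(center_rc[0], center_rc[1], radius_px, radius_px, shape=shape)
    mask[rr, cc] = True
    return mask


def ellipse_mask(shape, center_rc, semi_minor_px, semi_major_px, rotation=0.0):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(
        center_rc[0], center_rc[1], semi_minor_px, semi_major_px,
        shape=shape, rotation=rotation,
    )
    mask[rr, cc] = True
    return mask


def lens_area(R, d):
    """Overlap area of two disks of radius R with center distance d < 2R."""
    return 2 * R * R * math.acos(d / (2 * R)) - d / 2 * math.sqrt(4 * R * R - d * d)


@pytest.fixture
def small_spec():
    """A quick-to-render sample: 600 px at 4 um/px (2.4 mm field)."""
    return SampleSpec(
        image_px=600,
        scale=4.0,
        n_capillaries=25,
        radial_distribution=("uniform", {"low": 200.0, "high": 900.0}),
        seed=11,
    )
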