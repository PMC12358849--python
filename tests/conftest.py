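import numpy as np
import pytest

from fiberorder import (
    FiberPatternSpec,
    Mask,
    OrientationField,
    estimate_orientation,
    render_fibers,
)


@pytest.fixture
def full_mask():
    def make(shape, pixel_size_um=1.0):
        return Mask.full(shape, pixel_size_um)

    return make


@pytest.fixture
def angle_field():
    """OrientationField built directly from a ground-truth angle map."""

    def make(theta_deg, pixel_size_um=1.0):
        theta_deg = np.asarray(theta_deg, dtype=float)
        ones = np.ones_like(theta_deg)
        return OrientationField(
            theta_deg=theta_deg,
            coherency=ones,
            energy=ones,
            pixel_size_um=pixel_size_um,
        )

    return make


@pytest.fixture
def aligned_fibers():
    """Rendered noiseless aligned fiber image + estimated orientation."""

    def make(base_angle_deg=30.0, shape=(192, 192), pixel_size_um=0.5, **kw):
        spec = FiberPatternSpec(
            image_shape=shape,
            pixel_size_um=pixel_size_um,
            base_angle_deg=base_angle_deg,
            **kw,
        )
        img, gt = render_fibers(spec)
        return img, gt, estimate_orientation(img)

    return make
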