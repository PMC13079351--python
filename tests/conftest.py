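import numpy as np
import pytest

from fibernuc import Detection, InstanceMask


def random_mask(rng, frame=64, max_blob=12, frame_tag="global"):
    """Random connected-ish blob mask inside a frame, for oracle tests."""
    while True:
        canvas = np.zeros((frame, frame), dtype=bool)
        n_seeds = rng.integers(1, 4)
        for _ in range(n_seeds):
            cx = int(rng.integers(max_blob, frame - max_blob))
            cy = int(rng.integers(max_blob, frame - max_blob))
            r = int(rng.integers(2, max_blob // 2 + 1))
            yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
            blob = xx**2 + yy**2 <= r**2
            canvas[cy - r : cy + r + 1, cx - r : cx + r + 1] |= blob
        if canvas.any():
            return InstanceMask.from_raster(canvas, frame=frame_tag)


def disk_mask(cx, cy, r, frame_tag="global"):
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return InstanceMask.from_raster(
        xx**2 + yy**2 <= r**2, cx - r, cy - r, frame=frame_tag
    )


def square_det(x0, y0, side, score=1.0, instance_id=0, frame_tag="global"):
    mask = InstanceMask(np.ones((side, side), dtype=bool), x0, y0, frame_tag)
    return Detection(mask, score, instance_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
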