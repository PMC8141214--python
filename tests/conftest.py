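import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from nucledit import ImageVolume, LabelVolume  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_fixture():
    """A 1x5x5 scene: intensity ramp 100,90,80,70 along row 2, region on the 100."""
    img = np.zeros((1, 5, 5), dtype=np.uint8)
    img[0, 2, 0:4] = [100, 90, 80, 70]
    labels = np.zeros((1, 5, 5), dtype=np.int32)
    labels[0, 2, 0] = 1
    return ImageVolume(img), LabelVolume(labels)


@pytest.fixture
def dumbbell():
    """Two bright 5x5x3 cores joined by a dim 1-voxel bridge: one region, two nuclei.

    Returns (image, labels, ground_truth_halves) where labels holds the single
    joined region produced by thresholding at 50.
    """
    img = np.zeros((3, 7, 13), dtype=np.uint16)
    # cores occupy x 0..4 and x 8..12, all z, y 1..5; brighter toward center
    for cx in (2, 10):
        for z in range(3):
            for y in range(1, 6):
                for x in range(cx - 2, cx + 3):
                    d2 = (z - 1) ** 2 + (y - 3) ** 2 + ((x - cx) / 1.5) ** 2
                    img[z, y, x] = max(60, int(200 - 25 * d2))
    img[1, 3, 5:8] = 80  # bridge
    fg = img >= 50
    labels = np.where(fg, 1, 0).astype(np.int32)
    gt = np.zeros_like(labels)
    gt[fg & (np.arange(13)[None, None, :] <= 6)] = 1
    gt[fg & (np.arange(13)[None, None, :] > 6)] = 2
    return ImageVolume(img), LabelVolume(labels), LabelVolume(gt)
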