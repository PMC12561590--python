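"""Shared fixtures: random fat blobs and brute-force geometry oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage
from skimage import draw


def random_blob(rng: np.random.Generator, shape=(48, 48), n_disks=8, r_range=(3, 6)) -> np.ndarray:
    """A fat, hole-free, single-component binary blob with a 1-px border.

    Built as the union of disks along a random walk (overlapping radii keep
    it connected and smooth), hole-filled, largest component kept.
    """
    img = np.zeros(shape, dtype=np.uint8)
    y = int(rng.integers(14, shape[0] - 14))
    x = int(rng.integers(14, shape[1] - 14))
    for _ in range(n_disks):
        r = int(rng.integers(*r_range))
        rr, cc = draw.disk((y, x), r, shape=shape)
        img[rr, cc] = 1
        y = int(np.clip(y + rng.integers(-4, 5), 8, shape[0] - 9))
        x = int(np.clip(x + rng.integers(-4, 5), 8, shape[1] - 9))
    img = ndimage.binary_fill_holes(img)
    labels, n = ndimage.label(img, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        img = labels == int(np.argmax(counts)) + 1
    img = img.astype(np.uint8)
    img[0, :] = img[-1, :] = 0
    img[:, 0] = img[:, -1] = 0
    return img


def boundary_set(mask: np.ndarray) -> set[tuple[int, int]]:
    """Brute-force boundary: foreground pixels with a background 8-neighbor."""
    padded = np.pad(mask.astype(bool), 1)
    out = set()
    h, w = mask.shape
    for yy in range(h):
        for xx in range(w):
            if mask[yy, xx] and not padded[yy : yy + 3, xx : xx + 3].all():
                out.add((xx, yy))
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
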