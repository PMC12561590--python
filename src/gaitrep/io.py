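"""Reading, writing and validation of silhouette sequences and gait maps.

Coordinate convention used throughout the package: arrays are row-major,
``x`` is the column index and ``y`` is the row index, both 0-based, so the
silhouette value at spatial position (x, y) lives in ``mask[y, x]``.

Silhouette sequences are directories of numbered single-channel image files
(PNG or TIFF); RGB inputs are converted to luminance before binarization.
Gait maps are written twice: a lossless float32 TIFF (the canonical
artifact) plus an 8-bit PNG preview rescaled per image, with a JSON sidecar
recording the map kind and the rescale bounds.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "SilhouetteSequence",
    "binarize",
    "load_sequence",
    "save_map",
    "load_map",
    "GAIT_CLASSES",
]

#: Impairment taxonomy: normal walking, left/right leg, left/right arm, full body.
GAIT_CLASSES = ("NM", "LL", "RL", "LA", "RA", "FB")

# ITU-R BT.709 luminance weights, matching skimage.color.rgb2gray.
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class SilhouetteSequence:
    """Ordered binary masks for one recording (or one gait cycle).

    Each frame is a 2-D uint8 array of {0, 1}; frames may have different
    shapes at load time (they are standardized later by preprocessing).
    """

    frames: list[np.ndarray] = field(default_factory=list)
    source_id: str = ""
    class_label: Optional[str] = None

    def __len__(self) -> int:
        return len(self.frames)

    def validate(self) -> None:
        """Raise ``ValueError`` unless every frame is binary and nonempty."""
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not a 2-D mask")
            vals = np.unique(f)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"frame {i} contains values other than 0/1")
            if not f.any():
                raise ValueError(f"frame {i} is empty")


def binarize(image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize an intensity image against ``threshold`` × its maximum.

    Pixels strictly greater than ``threshold * image.max()`` map to 1. Using
    the per-image maximum makes the operation idempotent on {0, 1} masks
    while still cutting antialiased {0..255} PNGs at mid-intensity. RGB
    inputs are reduced to luminance first.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3].astype(float) @ _LUMA
    img = img.astype(float)
    peak = img.max() if img.size else 0.0
    if peak <= 0:
        return np.zeros(img.shape, dtype=np.uint8)
    return (img > threshold * peak).astype(np.uint8)


def _numeric_key(path: Path):
    """Sort key: first integer embedded in the stem, then the name itself."""
    m = re.search(r"\d+", path.stem)
    return (int(m.group()) if m else -1, path.name)


def load_sequence(
    path: str | Path,
    binarize_threshold: float = 0.5,
    source_id: Optional[str] = None,
    class_label: Optional[str] = None,
) -> SilhouetteSequence:
    """Load a directory of numbered image frames as a binary sequence.

    Frames are ordered by the numeric part of their filenames. All-zero
    frames are dropped with a warning (empty silhouettes carry no shape
    information and break downstream geometry).

    Raises
    ------
    FileNotFoundError
        If the directory does not exist or contains no readable frames.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"no such directory: {path}")
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}),
        key=_numeric_key,
    )
    if not files:
        raise FileNotFoundError(f"no frames found in {path}")
    frames = []
    for f in files:
        try:
            img = iio.imread(f)
        except Exception as exc:  # pragma: no cover - backend specific
            raise IOError(f"could not read frame {f}") from exc
        mask = binarize(img, binarize_threshold)
        if not mask.any():
            warnings.warn(f"dropping all-zero frame {f.name}", stacklevel=2)
            continue
        frames.append(mask)
    if not frames:
        raise FileNotFoundError(f"no nonzero frames in {path}")
    return SilhouetteSequence(
        frames=frames,
        source_id=source_id if source_id is not None else path.name,
        class_label=class_label,
    )


def save_map(gait_map, path_png: str | Path, path_float: str | Path) -> dict:
    """Write a gait map as lossless float TIFF plus 8-bit PNG preview.

    The PNG is linearly rescaled per channel so min→0 and max→255; a
    degenerate channel (min == max) renders as all zeros. The rescale
    bounds and map kind go into a JSON sidecar next to the PNG so the
    preview remains interpretable. Returns the sidecar metadata.
    """
    from PIL import Image

    pixels = np.asarray(gait_map.pixels, dtype=np.float32)
    if not np.isfinite(pixels).all():
        raise ValueError("gait map contains non-finite values")
    path_png, path_float = Path(path_png), Path(path_float)

    tifffile.imwrite(path_float, pixels)

    chans = pixels if pixels.ndim == 3 else pixels[..., None]
    lo = chans.reshape(-1, chans.shape[-1]).min(axis=0)
    hi = chans.reshape(-1, chans.shape[-1]).max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    preview = np.where(hi > lo, (chans - lo) / span * 255.0, 0.0)
    preview = np.clip(np.rint(preview), 0, 255).astype(np.uint8)
    if pixels.ndim == 2:
        preview = preview[..., 0]
    Image.fromarray(preview).save(path_png)

    meta = {
        "kind": getattr(gait_map, "kind", "unknown"),
        "n_frames": int(getattr(gait_map, "n_frames", 0)),
        "rescale_min": [float(v) for v in lo],
        "rescale_max": [float(v) for v in hi],
    }
    path_png.with_suffix(path_png.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return meta


def load_map(path_float: str | Path) -> np.ndarray:
    """Read back the lossless float TIFF written by :func:`save_map`."""
    return tifffile.imread(path_float)
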