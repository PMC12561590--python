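"""Silhouette geometry: projections, cropping, common padding, centroid and
ordered boundary tracing.

The preprocessing chain standardizes a silhouette sequence for map
construction: each frame is cropped to the bounding box of its foreground
support, all cropped frames are zero-padded equally on both sides to the
sequence-wide maximum height and width, and each padded frame is
characterized by its center of mass and an ordered, closed boundary trace
obtained with the Moore-Neighbor contour-following algorithm (Jacob's
stopping criterion).

Cropping note: selecting only rows/columns with nonzero projection would
delete interior empty columns for silhouettes with detached parts and
deform the shape, so the crop keeps the full start..end span. The 0-norm
support sizes (count of nonzero projection entries) are computed and
recorded alongside the bounding-box extents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CropSizes",
    "CroppedPaddedSequence",
    "Centroid",
    "BoundaryTrace",
    "project",
    "crop",
    "pad_to_common",
    "centroid",
    "trace_boundary",
    "preprocess_sequence",
]


@dataclass(frozen=True)
class CropSizes:
    """Pre-padding frame sizes: bounding-box extents and 0-norm support."""

    width: int          # bounding-box span of nonzero columns
    height: int         # bounding-box span of nonzero rows
    support_width: int  # number of columns with any foreground (0-norm)
    support_height: int  # number of rows with any foreground (0-norm)


@dataclass
class CroppedPaddedSequence:
    """Cropped silhouettes zero-padded to a common ``Ny`` × ``Nx`` canvas."""

    frames: np.ndarray  # (N, Ny, Nx) uint8
    per_frame_sizes: list[CropSizes]
    source_id: str = ""
    class_label: str | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]  # (Ny, Nx)

    def slice(self, start: int, end: int) -> "CroppedPaddedSequence":
        """Sub-sequence covering frames ``start..end`` inclusive."""
        return CroppedPaddedSequence(
            frames=self.frames[start : end + 1],
            per_frame_sizes=self.per_frame_sizes[start : end + 1],
            source_id=self.source_id,
            class_label=self.class_label,
        )


@dataclass(frozen=True)
class Centroid:
    cx: float
    cy: float


@dataclass
class BoundaryTrace:
    """Ordered, closed walk along the outer silhouette boundary.

    ``xs[i], ys[i]`` is the i-th boundary pixel; consecutive points (and
    last→first) are 8-connected. Pixels may repeat where the contour is one
    pixel wide.
    """

    xs: np.ndarray
    ys: np.ndarray

    def __len__(self) -> int:
        return len(self.xs)

    @property
    def points(self) -> np.ndarray:
        """(L, 2) array of (x, y) pairs."""
        return np.stack([self.xs, self.ys], axis=1)


def project(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axis projections of a binary mask.

    Returns ``(col_profile, row_profile)`` where ``col_profile[y]`` sums the
    mask over x (per-row counts) and ``row_profile[x]`` sums over y
    (per-column counts).
    """
    mask = np.asarray(mask)
    return mask.sum(axis=1), mask.sum(axis=0)


def crop(mask: np.ndarray) -> tuple[np.ndarray, CropSizes]:
    """Crop a mask to the bounding box of its foreground support.

    Returns the cropped mask together with :class:`CropSizes` holding both
    the bounding-box extents and the 0-norm support counts (which differ
    when the silhouette has interior all-zero rows or columns).
    """
    mask = np.asarray(mask)
    col_profile, row_profile = project(mask)
    ys = np.flatnonzero(col_profile)
    xs = np.flatnonzero(row_profile)
    if ys.size == 0:
        raise ValueError("empty silhouette: nothing to crop")
    y0, y1 = ys[0], ys[-1]
    x0, x1 = xs[0], xs[-1]
    cropped = mask[y0 : y1 + 1, x0 : x1 + 1]
    sizes = CropSizes(
        width=int(x1 - x0 + 1),
        height=int(y1 - y0 + 1),
        support_width=int(xs.size),
        support_height=int(ys.size),
    )
    return cropped, sizes


def pad_to_common(
    cropped: list[np.ndarray],
    sizes: list[CropSizes] | None = None,
    **seq_kwargs,
) -> CroppedPaddedSequence:
    """Zero-pad cropped frames equally from both sides to a common canvas.

    The canvas is the maximum bounding-box height and width over the
    frames. An odd padding remainder goes to the right/bottom.
    """
    if not cropped:
        raise ValueError("no frames to pad")
    if sizes is None:
        sizes = [
            CropSizes(f.shape[1], f.shape[0], f.shape[1], f.shape[0]) for f in cropped
        ]
    ny = max(f.shape[0] for f in cropped)
    nx = max(f.shape[1] for f in cropped)
    out = np.zeros((len(cropped), ny, nx), dtype=np.uint8)
    for i, f in enumerate(cropped):
        h, w = f.shape
        top = (ny - h) // 2
        left = (nx - w) // 2
        out[i, top : top + h, left : left + w] = f
    return CroppedPaddedSequence(frames=out, per_frame_sizes=list(sizes), **seq_kwargs)


def centroid(mask: np.ndarray) -> Centroid:
    """Center of mass of the silhouette region (uniform density).

    Coordinates are sub-pixel, 0-based, with pixel centers at integers.
    """
    mask = np.asarray(mask, dtype=float)
    total = mask.sum()
    if total == 0:
        raise ValueError("empty silhouette: centroid undefined")
    ys, xs = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    return Centroid(cx=float((xs * mask).sum() / total), cy=float((ys * mask).sum() / total))


# Moore neighborhood in clockwise screen order (y grows downward):
# N, NE, E, SE, S, SW, W, NW as (dx, dy) offsets.
_MOORE = ((0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1))
_MOORE_INDEX = {d: i for i, d in enumerate(_MOORE)}


def trace_boundary(mask: np.ndarray) -> BoundaryTrace:
    """Trace the outer boundary of the largest connected component.

    Moore-Neighbor tracing: starting at the uppermost-leftmost foreground
    pixel (entered travelling east, i.e. backtrack = its west neighbor),
    repeatedly scan the 8-neighborhood clockwise beginning just after the
    backtrack pixel and move to the first foreground neighbor found. The
    walk stops when a (pixel, backtrack) state repeats, which includes
    Jacob's criterion (re-entering the start pixel from the initial
    direction) and also terminates on one-pixel-wide shapes where the start
    is only ever re-entered from the opposite direction.

    Corner completion: when the walk steps diagonally it additionally emits
    the foreground pixel shared by the two 4-neighborhoods (the inside of
    the corner being turned). A plain Moore walk skips pixels whose only
    background contact is diagonal; with this rule the trace's point set is
    exactly the 8-neighborhood boundary — every foreground pixel with a
    background 8-neighbor — while consecutive points stay 8-connected.

    A temporary one-pixel guard border is added internally so foreground
    never touches the canvas edge; output coordinates are in the original
    frame. Holes are ignored (outer contour only); if several 8-connected
    components exist, the largest is traced and a warning is emitted.
    """
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("empty silhouette: no boundary")

    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        warnings.warn(f"{n} connected components; tracing the largest", stacklevel=2)
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(counts)) + 1)

    padded = np.pad(mask.astype(bool), 1)
    ys, xs = np.nonzero(padded)
    row = ys.min()  # uppermost row, leftmost pixel within it
    start = (int(xs[ys == row].min()), int(row))

    def next_foreground(p, b):
        """First clockwise foreground neighbor of p after backtrack b.

        Returns (neighbor, new_backtrack) or (None, None) for an isolated
        pixel. ``new_backtrack`` is the background pixel examined just
        before the neighbor was found.
        """
        px, py = p
        bi = _MOORE_INDEX[(b[0] - px, b[1] - py)]
        prev_bg = b
        for step in range(1, 9):
            dx, dy = _MOORE[(bi + step) % 8]
            q = (px + dx, py + dy)
            if padded[q[1], q[0]]:
                return q, prev_bg
            prev_bg = q
        return None, None

    b0 = (start[0] - 1, start[1])  # entered from the west during the raster scan
    trace = [start]
    seen = {(start, b0)}
    p, b = start, b0
    max_steps = 8 * int(padded.sum()) + 8
    for _ in range(max_steps):
        c, b2 = next_foreground(p, b)
        if c is None:
            break
        closing = (c, b2) in seen
        if abs(c[0] - p[0]) == 1 and abs(c[1] - p[1]) == 1:
            # diagonal step: emit the inside corner pixel if foreground
            # (also on the closing step back into a visited state)
            for o in ((p[0], c[1]), (c[0], p[1])):
                if o != b2 and padded[o[1], o[0]]:
                    trace.append(o)
        if closing:
            break
        seen.add((c, b2))
        trace.append(c)
        p, b = c, b2
    if len(trace) > 1 and trace[-1] == trace[0]:
        trace.pop()

    pts = np.asarray(trace, dtype=int) - 1  # remove guard border offset
    return BoundaryTrace(xs=pts[:, 0], ys=pts[:, 1])


def preprocess_sequence(seq, **kwargs) -> CroppedPaddedSequence:
    """Crop every frame of a :class:`~gaitrep.io.SilhouetteSequence` and pad
    the results to the common canvas."""
    cropped, sizes = [], []
    for f in seq.frames:
        c, s = crop(f)
        cropped.append(c)
        sizes.append(s)
    return pad_to_common(
        cropped, sizes, source_id=seq.source_id, class_label=seq.class_label, **kwargs
    )
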