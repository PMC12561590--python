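"""The five gait-cycle representation maps.

Given a gait cycle of N cropped, zero-padded binary silhouettes S_n (n =
1..N, canvas Ny × Nx) and their ordered boundary traces, this module builds:

GEI
    Gait Energy Image — the per-pixel temporal mean (1/N) Σ S_n. Grayscale,
    values in [0, 1].
tGBI
    time-coded Gait Boundary Image — boundary images B_n (1 on the traced
    boundary of frame n) accumulated with their 1-based time index:
    (1/N) Σ n·B_n. Later boundaries are brighter; overlapping boundary
    pixels accumulate additively.
cGEI
    color-coded GEI — the cycle is split into three temporal thirds and the
    partial sums (each still normalized by 1/N) are assigned to the red,
    green and blue channels. When N is divisible by 3 the channels sum
    exactly to the GEI.
tGDI
    time-coded Gait Delta Image — consecutive-frame differences
    d_n = S_{n+1} − S_n. Pixels newly covered by the silhouette (d_n > 0)
    go to the red channel, vacated pixels (d_n < 0) to blue, each weighted
    by the time index n and normalized by 1/N. N−1 delta images exist, so
    the accumulation runs to N−1. Green is identically zero.
cBIT
    color-coded Boundary-to-Image Transform — column n of an N_B × N color
    image stores the ordered boundary coordinates of frame n, x in red and
    y in blue, normalized by the canvas extents to [0, 1]. All traces are
    resampled (piecewise-linearly along the trace index) to the maximum
    trace length N_B. For hole-free single-component silhouettes with
    equal-length traces the transform is invertible: :func:`decode_cbit`
    recovers the masks via rasterization and flood fill.

All five constructions are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import BoundaryTrace, CroppedPaddedSequence

__all__ = [
    "GaitMap",
    "MAP_KINDS",
    "gei",
    "tgbi",
    "cgei",
    "tgdi",
    "cbit",
    "decode_cbit",
    "build_all",
]

MAP_KINDS = ("GEI", "tGBI", "cGEI", "tGDI", "cBIT")


@dataclass
class GaitMap:
    """A gait representation map: float pixels plus its kind tag.

    ``pixels`` is (Ny, Nx) for single-channel kinds (GEI, tGBI) and
    (Ny, Nx, 3) / (N_B, N, 3) for color kinds. ``meta`` carries whatever a
    kind needs for exact inversion (e.g. the cBIT canvas size).
    """

    kind: str
    pixels: np.ndarray
    n_frames: int
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[-1]


def gei(cycle: CroppedPaddedSequence) -> GaitMap:
    """Gait Energy Image: temporal mean of the silhouettes."""
    frames = np.asarray(cycle.frames, dtype=float)
    if frames.shape[0] == 0:
        raise ValueError("empty cycle")
    return GaitMap(kind="GEI", pixels=frames.mean(axis=0), n_frames=frames.shape[0])


def boundary_image(trace: BoundaryTrace, shape: tuple[int, int]) -> np.ndarray:
    """Binary image with 1 on the trace points (shape = (Ny, Nx))."""
    img = np.zeros(shape, dtype=np.uint8)
    img[trace.ys, trace.xs] = 1
    return img


def tgbi(cycle: CroppedPaddedSequence, traces: list[BoundaryTrace]) -> GaitMap:
    """time-coded Gait Boundary Image: (1/N) Σ_n n · B_n, n = 1..N."""
    n_frames = cycle.n_frames
    if len(traces) != n_frames:
        raise ValueError(
            f"trace/frame mismatch: {len(traces)} traces for {n_frames} frames"
        )
    shape = cycle.shape
    acc = np.zeros(shape, dtype=float)
    for n, trace in enumerate(traces, start=1):
        acc += n * boundary_image(trace, shape)
    return GaitMap(kind="tGBI", pixels=acc / n_frames, n_frames=n_frames)


def cgei(cycle: CroppedPaddedSequence) -> GaitMap:
    """color-coded GEI: temporal thirds of the cycle in R, G, B.

    Segment boundaries fall at ⌊N/3⌋ and ⌊2N/3⌋; remainder frames join the
    blue (final) segment. Each channel keeps the 1/N normalization so the
    channel sum reproduces the GEI (exactly when 3 divides N).
    """
    frames = np.asarray(cycle.frames, dtype=float)
    n = frames.shape[0]
    if n < 3:
        raise ValueError("cGEI needs at least 3 frames")
    b1, b2 = n // 3, (2 * n) // 3
    channels = [
        frames[:b1].sum(axis=0) / n,
        frames[b1:b2].sum(axis=0) / n,
        frames[b2:].sum(axis=0) / n,
    ]
    return GaitMap(kind="cGEI", pixels=np.stack(channels, axis=-1), n_frames=n)


def tgdi(cycle: CroppedPaddedSequence) -> GaitMap:
    """time-coded Gait Delta Image: index-weighted frame differences.

    Red accumulates pixels the silhouette moves into, blue pixels it moves
    out of; green stays zero.
    """
    frames = np.asarray(cycle.frames, dtype=np.int16)
    n = frames.shape[0]
    if n < 2:
        raise ValueError("tGDI needs at least 2 frames")
    out = np.zeros((*cycle.shape, 3), dtype=float)
    for i in range(n - 1):  # delta index n = i + 1, runs 1..N-1
        d = frames[i + 1] - frames[i]
        out[..., 0] += (i + 1) * (d > 0)
        out[..., 2] += (i + 1) * (d < 0)
    out /= n
    return GaitMap(kind="tGDI", pixels=out, n_frames=n)


def _resample_trace(coords: np.ndarray, length: int) -> np.ndarray:
    """Piecewise-linear resampling along the trace index, endpoints kept."""
    src = np.arange(len(coords), dtype=float)
    if len(coords) == 1:
        return np.repeat(coords.astype(float), length)
    tgt = np.linspace(0.0, len(coords) - 1.0, length)
    return np.interp(tgt, src, coords.astype(float))


def cbit(traces: list[BoundaryTrace], canvas: tuple[int, int]) -> GaitMap:
    """color-coded Boundary-to-Image Transform.

    ``canvas`` is the (Ny, Nx) silhouette canvas used to normalize the
    coordinates into [0, 1] (recorded in ``meta`` for inversion). Column n
    of the (N_B, N, 3) output holds frame n's resampled boundary: x/(Nx−1)
    in red, y/(Ny−1) in blue.
    """
    if not traces:
        raise ValueError("no boundary traces")
    ny, nx = canvas
    n_b = max(len(t) for t in traces)
    out = np.zeros((n_b, len(traces), 3), dtype=float)
    sx = float(nx - 1) if nx > 1 else 1.0
    sy = float(ny - 1) if ny > 1 else 1.0
    for j, t in enumerate(traces):
        out[:, j, 0] = _resample_trace(np.asarray(t.xs), n_b) / sx
        out[:, j, 2] = _resample_trace(np.asarray(t.ys), n_b) / sy
    return GaitMap(
        kind="cBIT",
        pixels=out,
        n_frames=len(traces),
        meta={"canvas": (int(ny), int(nx)), "n_boundary": int(n_b)},
    )


def decode_cbit(gait_map: GaitMap, canvas: tuple[int, int] | None = None) -> list[np.ndarray]:
    """Invert a cBIT map back to binary masks.

    De-normalizes each column to pixel coordinates, rasterizes the boundary
    walk and flood-fills its interior. Exact recovery holds for hole-free,
    single-component silhouettes whose traces required no resampling.
    """
    if canvas is None:
        canvas = gait_map.meta["canvas"]
    ny, nx = canvas
    sx = float(nx - 1) if nx > 1 else 1.0
    sy = float(ny - 1) if ny > 1 else 1.0
    masks = []
    for j in range(gait_map.pixels.shape[1]):
        xs = np.rint(gait_map.pixels[:, j, 0] * sx).astype(int)
        ys = np.rint(gait_map.pixels[:, j, 2] * sy).astype(int)
        img = np.zeros((ny, nx), dtype=bool)
        img[np.clip(ys, 0, ny - 1), np.clip(xs, 0, nx - 1)] = True
        masks.append(ndimage.binary_fill_holes(img).astype(np.uint8))
    return masks


def build_all(
    cycle: CroppedPaddedSequence,
    traces: list[BoundaryTrace],
    kinds: tuple[str, ...] = MAP_KINDS,
) -> list[GaitMap]:
    """Build the requested maps for one cycle, tagged by kind."""
    builders = {
        "GEI": lambda: gei(cycle),
        "tGBI": lambda: tgbi(cycle, traces),
        "cGEI": lambda: cgei(cycle),
        "tGDI": lambda: tgdi(cycle),
        "cBIT": lambda: cbit(traces, cycle.shape),
    }
    unknown = set(kinds) - set(builders)
    if unknown:
        raise ValueError(f"unknown map kinds: {sorted(unknown)}")
    return [builders[k]() for k in kinds]
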