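"""Gait-cycle detection from correlation-coefficient signals.

A gait sequence is compared frame-by-frame against a fixed reference frame
(by default the first) using the 2-D Pearson correlation coefficient,
either of the binary silhouettes themselves (``CorrI``) or of their Fourier
transform magnitudes (``CorrF``; insensitive to residual translation within
the canvas). The resulting signal oscillates with the gait and its valleys
— local minima filtered by topographic prominence — mark cycle boundaries.

Prominence of a valley: find the nearest points left and right with the
same signal value (or the data ends), take the highest peak within each
flanking interval, and subtract the valley value from the lower of the two
peaks. A valley is kept when its prominence reaches a fraction (default
0.1) of the overall signal range, making detection invariant to affine
rescaling of the signal.

Note that for bilaterally symmetric gaits the silhouette nearly repeats
every half limb period (left and right limbs swap roles), so a
fixed-reference similarity signal can dip twice per anatomical stride;
``segment_cycles`` accepts ``pair_valleys=2`` to merge alternate valleys
when full strides are wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "CorrelationSignal",
    "GaitCycle",
    "correlation_signal",
    "detect_valleys",
    "segment_cycles",
]


@dataclass
class CorrelationSignal:
    values: np.ndarray          # per-frame correlation with the reference, in [-1, 1]
    kind: str                   # "image" or "fourier_magnitude"
    reference_index: int = 0

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GaitCycle:
    """One detected cycle: frames ``start_frame..end_frame`` inclusive."""

    start_frame: int
    end_frame: int

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def _pearson2d(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da * da).sum() * (db * db).sum())
    if denom == 0:
        warnings.warn("zero-variance frame in correlation; returning 0", stacklevel=3)
        return 0.0
    return float((da * db).sum() / denom)


def correlation_signal(
    seq, kind: str = "image", reference_index: int = 0
) -> CorrelationSignal:
    """2-D correlation of every frame against a fixed reference frame.

    ``kind="image"`` correlates the padded binary silhouettes directly;
    ``kind="fourier_magnitude"`` correlates the magnitudes of their 2-D
    discrete Fourier transforms.
    """
    frames = np.asarray(seq.frames, dtype=float)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames for a correlation signal")
    if kind == "fourier_magnitude":
        frames = np.abs(np.fft.fft2(frames, axes=(-2, -1)))
    elif kind != "image":
        raise ValueError(f"unknown signal kind: {kind!r}")
    ref = frames[reference_index]
    values = np.array([_pearson2d(f, ref) for f in frames])
    return CorrelationSignal(values=values, kind=kind, reference_index=reference_index)


def detect_valleys(
    signal: CorrelationSignal | np.ndarray, min_prominence_fraction: float = 0.1
) -> np.ndarray:
    """Indices of local minima with prominence ≥ fraction × signal range.

    Endpoints are never valleys; a flat signal yields an empty result.
    """
    values = np.asarray(getattr(signal, "values", signal), dtype=float)
    if values.size < 3:
        raise ValueError("signal too short for valley detection")
    vrange = values.max() - values.min()
    if vrange == 0:
        return np.array([], dtype=int)
    idx, _ = sps.find_peaks(-values, prominence=min_prominence_fraction * vrange)
    return idx


def valley_prominences(signal: CorrelationSignal | np.ndarray, valleys) -> np.ndarray:
    """Topographic prominence of each valley (depth below the lower of the
    highest flanking peaks)."""
    values = np.asarray(getattr(signal, "values", signal), dtype=float)
    prom, _, _ = sps.peak_prominences(-values, np.asarray(valleys, dtype=int))
    return prom


def segment_cycles(
    seq,
    valleys,
    min_frames: int = 4,
    pair_valleys: int = 1,
) -> list[GaitCycle]:
    """Pair consecutive valleys into gait cycles.

    ``pair_valleys=2`` uses every other valley as a cycle boundary (full
    strides for bilaterally symmetric gaits). Cycles shorter than
    ``min_frames`` are discarded with a warning.
    """
    valleys = np.asarray(valleys, dtype=int)
    if valleys.size < 2:
        raise ValueError("no complete cycle: fewer than 2 valleys")
    bounds = valleys[::pair_valleys]
    cycles = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        cyc = GaitCycle(start_frame=int(a), end_frame=int(b))
        if cyc.n_frames < min_frames:
            warnings.warn(
                f"discarding {cyc.n_frames}-frame cycle at {a}..{b} "
                f"(minimum {min_frames})",
                stacklevel=2,
            )
            continue
        cycles.append(cyc)
    return cycles
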