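"""Synthetic lateral-view walker: class-labeled binary silhouette sequences.

The generator renders a 2-D articulated stick figure (filled ellipse torso,
circular head, two-segment arms and legs rasterized with thickness) walking
in place, viewed from the side. Joint angles follow sinusoids of the cycle
phase with contralateral limbs in antiphase; a sequence starts at the
maximum-spread posture. Far-side (left) limbs are attached slightly
higher/behind and drawn shorter and thinner than near-side (right) limbs,
mimicking the depth offset and partial occlusion of a lateral projection.

The far-side geometry serves two purposes: it makes left- and right-sided
impairments distinguishable in a silhouette (as the depth offset does in
real lateral recordings), and it breaks the half-period left/right swap
symmetry of a bilateral sinusoidal gait, so the fixed-reference correlation
signal used for cycle detection has a single dissimilarity maximum per
period instead of the two shallow dips a perfectly symmetric walker would
produce. A small constant phase lag of the arm swing relative to the legs
removes the remaining time-mirror symmetry of the cycle for the same
reason.

Impairment classes modulate the kinematics:

====  =========================================================
NM    full swing amplitudes on all four limbs
LL    left-leg swing nearly abolished, slightly shortened stride
RL    right-leg swing nearly abolished, slightly shortened stride
LA    left-arm swing nearly abolished
RA    right-arm swing nearly abolished
FB    all amplitudes reduced, short shuffling stride, bent knees
====  =========================================================

Ground truth for cycle detection: a noise-free sequence is exactly
periodic with ``frames_per_cycle`` frames, and consecutive correlation
valleys are expected at that spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw

from .io import GAIT_CLASSES, SilhouetteSequence

__all__ = [
    "WalkerConfig",
    "default_config",
    "render_walker",
    "make_dataset",
    "write_dataset",
]

_LEG_SWING = 0.45  # base thigh amplitude, radians from vertical
_ARM_SWING = 0.30  # base upper-arm amplitude, radians
_ARM_LAG = 0.35    # arm-swing phase lag behind the legs, radians


@dataclass
class WalkerConfig:
    """Kinematic parameters of one synthetic walking sequence."""

    class_label: str = "NM"
    frames_per_cycle: int = 14
    n_cycles: int = 3
    canvas: tuple[int, int] = (200, 100)  # (height, width) pixels
    limb_amplitudes: dict = field(
        default_factory=lambda: {
            "left_arm": 1.0,
            "right_arm": 1.0,
            "left_leg": 1.0,
            "right_leg": 1.0,
        }
    )
    stride_scale: float = 1.0
    knee_bend: float = 0.12  # constant backward shank flexion, radians
    salt_pepper_fraction: float = 0.0
    boundary_jitter_px: int = 0
    seed: int = 0


#: Class-specific kinematics; amplitudes multiply the base swing amplitudes.
_CLASS_PARAMS = {
    "NM": dict(amps=(1.0, 1.0, 1.0, 1.0), stride=1.0, knee=0.12),
    "LL": dict(amps=(1.0, 1.0, 0.12, 1.0), stride=0.9, knee=0.12),
    "RL": dict(amps=(1.0, 1.0, 1.0, 0.12), stride=0.9, knee=0.12),
    "LA": dict(amps=(0.05, 1.0, 1.0, 1.0), stride=1.0, knee=0.12),
    "RA": dict(amps=(1.0, 0.05, 1.0, 1.0), stride=1.0, knee=0.12),
    # shuffling gait: bent knees, small steps, damped swing everywhere
    "FB": dict(amps=(0.45, 0.45, 0.45, 0.45), stride=0.55, knee=0.55),
}


def default_config(class_label: str, **overrides) -> WalkerConfig:
    """Canonical :class:`WalkerConfig` for an impairment class."""
    if class_label not in _CLASS_PARAMS:
        raise ValueError(f"unknown gait class {class_label!r} (expected one of {GAIT_CLASSES})")
    p = _CLASS_PARAMS[class_label]
    la, ra, ll, rl = p["amps"]
    cfg = WalkerConfig(
        class_label=class_label,
        limb_amplitudes={
            "left_arm": la,
            "right_arm": ra,
            "left_leg": ll,
            "right_leg": rl,
        },
        stride_scale=p["stride"],
        knee_bend=p["knee"],
    )
    return replace(cfg, **overrides)


def _thick_segment(canvas: np.ndarray, p0, p1, width: float) -> None:
    """Rasterize a line segment of the given width, with rounded caps."""
    (x0, y0), (x1, y1) = p0, p1
    dx, dy = x1 - x0, y1 - y0
    norm = math.hypot(dx, dy)
    h = width / 2.0
    if norm > 0:
        nx, ny = -dy / norm * h, dx / norm * h
        rr, cc = draw.polygon(
            [y0 - ny, y0 + ny, y1 + ny, y1 - ny],
            [x0 - nx, x0 + nx, x1 + nx, x1 - nx],
            shape=canvas.shape,
        )
        canvas[rr, cc] = 1
    for x, y in ((x0, y0), (x1, y1)):
        rr, cc = draw.disk((y, x), max(h, 1.0), shape=canvas.shape)
        canvas[rr, cc] = 1


def _render_frame(config: WalkerConfig, phase: float) -> np.ndarray:
    H, W = config.canvas
    u, w = H / 200.0, W / 100.0
    x0 = W / 2.0
    amp = config.limb_amplitudes
    img = np.zeros((H, W), dtype=np.uint8)

    # trunk and head
    rr, cc = draw.disk((36 * u, x0), 11 * u, shape=img.shape)
    img[rr, cc] = 1
    rr, cc = draw.ellipse(78 * u, x0, 34 * u, 11 * w, shape=img.shape)
    img[rr, cc] = 1

    thigh, shank = 42 * u, 42 * u
    upper, fore = 30 * u, 27 * u
    # near (right) vs far (left): the far side sits behind and above in the
    # lateral projection and is drawn shorter and thinner (partial occlusion)
    side = {
        "right": dict(dx=0.0, dy=0.0, scale=1.0, leg_w=9 * w, arm_w=7 * w),
        "left": dict(dx=-8 * w, dy=-4 * u, scale=0.62, leg_w=5 * w, arm_w=4 * w),
    }

    def limb(joint_xy, lengths, angles, width):
        x, y = joint_xy
        pts = [(x, y)]
        for L, th in zip(lengths, angles):
            x, y = x + L * math.sin(th), y + L * math.cos(th)
            pts.append((x, y))
        for a, b in zip(pts[:-1], pts[1:]):
            _thick_segment(img, a, b, width)

    for name, ph_off, which in (
        ("left_leg", math.pi, "left"),
        ("right_leg", 0.0, "right"),
    ):
        s = side[which]
        th = _LEG_SWING * amp[name] * config.stride_scale * math.cos(phase + ph_off)
        sh = 1.35 * th - config.knee_bend
        hip = (x0 + s["dx"], 104 * u + s["dy"])
        limb(hip, (thigh * s["scale"], shank * s["scale"]), (th, sh), s["leg_w"])

    for name, ph_off, which in (
        ("left_arm", 0.0, "left"),
        ("right_arm", math.pi, "right"),
    ):
        s = side[which]
        th = _ARM_SWING * amp[name] * math.cos(phase + ph_off + _ARM_LAG)
        fo = 1.15 * th + 0.35
        shoulder = (x0 + s["dx"], 54 * u + s["dy"])
        limb(shoulder, (upper * s["scale"], fore * s["scale"]), (th, fo), s["arm_w"])

    return img


def render_walker(config: WalkerConfig) -> SilhouetteSequence:
    """Render a walking sequence of ``frames_per_cycle × n_cycles`` frames.

    Noise-free sequences are exactly periodic with ``frames_per_cycle``.
    Salt-and-pepper noise and boundary jitter are applied after
    rasterization, seeded from ``config.seed``, and restricted to the
    canvas interior so a one-pixel background border always remains.
    """
    H, W = config.canvas
    if H < 80 or W < 40:
        raise ValueError(f"canvas {config.canvas} too small for the walker")
    if config.frames_per_cycle < 8:
        raise ValueError("frames_per_cycle must be at least 8")
    rng = np.random.default_rng(config.seed)
    frames = []
    n_frames = config.frames_per_cycle * config.n_cycles
    for t in range(n_frames):
        phase = 2 * math.pi * (t % config.frames_per_cycle) / config.frames_per_cycle
        img = _render_frame(config, phase)
        if config.boundary_jitter_px > 0:
            band = (
                ndimage.binary_dilation(img, iterations=config.boundary_jitter_px)
                & ~img.astype(bool)
            )
            add = band & (rng.random(img.shape) < 0.3)
            img = (img.astype(bool) | add).astype(np.uint8)
        if config.salt_pepper_fraction > 0:
            flips = rng.random((H - 2, W - 2)) < config.salt_pepper_fraction
            interior = img[1:-1, 1:-1]
            img[1:-1, 1:-1] = np.where(flips, 1 - interior, interior)
        img[0, :] = img[-1, :] = 0
        img[:, 0] = img[:, -1] = 0
        frames.append(img)
    return SilhouetteSequence(
        frames=frames,
        source_id=f"walker-{config.class_label}-seed{config.seed}",
        class_label=config.class_label,
    )


def make_dataset(
    classes,
    per_class: int,
    base_config: WalkerConfig | None = None,
    seed: int = 0,
) -> list[SilhouetteSequence]:
    """Labeled sequences with per-sequence nuisance variation.

    For each class, ``per_class`` sequences are rendered with the cycle
    length jittered by ±2 frames and each limb amplitude by ±8%, emulating
    within-class variability. Deterministic given ``seed``.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    rng = np.random.default_rng(seed)
    sequences = []
    for cls in classes:
        if cls not in _CLASS_PARAMS:
            raise ValueError(f"unknown gait class {cls!r}")
        for i in range(per_class):
            cfg = default_config(cls)
            if base_config is not None:
                cfg = replace(
                    cfg,
                    frames_per_cycle=base_config.frames_per_cycle,
                    n_cycles=base_config.n_cycles,
                    canvas=base_config.canvas,
                    salt_pepper_fraction=base_config.salt_pepper_fraction,
                    boundary_jitter_px=base_config.boundary_jitter_px,
                )
            cfg = replace(
                cfg,
                frames_per_cycle=cfg.frames_per_cycle + int(rng.integers(-2, 3)),
                limb_amplitudes={
                    k: v * rng.uniform(0.92, 1.08)
                    for k, v in cfg.limb_amplitudes.items()
                },
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            seq = render_walker(cfg)
            seq.source_id = f"{cls}_{i:03d}"
            sequences.append(seq)
    return sequences


def write_dataset(sequences, out_dir: str | Path) -> Path:
    """Write sequences as PNG frame directories plus a labels.csv index."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["source_id,class_label,n_frames"]
    for seq in sequences:
        d = out_dir / seq.source_id
        d.mkdir(exist_ok=True)
        for i, f in enumerate(seq.frames):
            Image.fromarray((f * 255).astype(np.uint8)).save(d / f"{i:04d}.png")
        rows.append(f"{seq.source_id},{seq.class_label},{len(seq.frames)}")
    (out_dir / "labels.csv").write_text("\n".join(rows) + "\n")
    return out_dir
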