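"""Feature extraction and per-class PCA reduction for gait maps.

Because a pretrained color CNN weighs its input channels differently, the
same gait map yields a different feature set for every ordering of its
color channels. The augmentation here therefore generates all 3! = 6
channel permutations ("color shift") of a map, runs each through a
pluggable image-descriptor backend, and concatenates the six outputs into
one feature vector — 4096 × 6 = 24,576 entries with the reference fc7-style
CNN backend. Grayscale maps replicate to three identical channels, so all
six blocks coincide (harmless redundancy).

Dimensionality is then reduced by class-wise principal component analysis:
for each class, the top ``P`` (default 15) principal directions of the
class's centered feature matrix are kept, and a feature vector is projected
onto every class's components, giving an ``n_classes × P`` reduced vector
(90 entries for 6 classes at P = 15).

Backends:

``PooledGridExtractor``
    The built-in deterministic descriptor: per-channel 16×16 mean-pooled
    intensities plus 16-bin channel histograms (816 values). Needs no
    pretrained weights and keeps the whole pipeline reproducible offline.
``AlexNetFC7Extractor``
    fc7 activations (4096) of a pretrained AlexNet; optional dependency
    (``pip install gaitrep[alexnet]``), weight download required.
``FunctionExtractor``
    Wrap any callable as a backend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from skimage.transform import resize

from .gaitmaps import GaitMap

__all__ = [
    "PERMUTATIONS",
    "FeatureVector",
    "ReducerModel",
    "FeatureExtractor",
    "PooledGridExtractor",
    "FunctionExtractor",
    "AlexNetFC7Extractor",
    "color_permutations",
    "extract_features",
    "features_from_map",
    "fit_reducer",
    "reduce_features",
]

#: Fixed block order of the channel permutations:
#: (R,G,B), (R,B,G), (G,R,B), (G,B,R), (B,R,G), (B,G,R).
PERMUTATIONS = ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))


@dataclass
class FeatureVector:
    values: np.ndarray
    per_perm_dim: int
    label: Optional[str] = None
    source_id: str = ""

    @property
    def n_perms(self) -> int:
        return len(PERMUTATIONS)

    @property
    def total_dim(self) -> int:
        return len(self.values)


class FeatureExtractor:
    """Interface: maps one (H, W, 3) float image to a fixed-length vector."""

    #: (height, width) the backend expects; images are resized to this.
    input_size: tuple[int, int]
    #: output dimensionality per image
    dim: int

    def __call__(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class PooledGridExtractor(FeatureExtractor):
    """Deterministic offline descriptor: pooled grid + channel histograms.

    Each channel is rescaled to [0, 1] by the image maximum (gait maps are
    nonnegative but unbounded, e.g. tGBI), mean-pooled onto a
    ``grid`` × ``grid`` lattice, and summarized by a ``bins``-bin
    histogram; pooled cells and histograms of the three channels are
    concatenated.
    """

    def __init__(self, grid: int = 16, bins: int = 16, input_size: tuple[int, int] = (64, 64)):
        self.grid = grid
        self.bins = bins
        self.input_size = input_size
        self.dim = 3 * (grid * grid + bins)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float)
        if img.ndim != 3 or img.shape[-1] != 3:
            raise ValueError("extractor expects an (H, W, 3) image")
        img = resize(img, (*self.input_size, 3), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
        peak = img.max()
        if peak > 0:
            img = img / peak
        pooled = resize(img, (self.grid, self.grid, 3), order=1, mode="edge",
                        anti_aliasing=True, preserve_range=True)
        hists = [
            np.histogram(img[..., c], bins=self.bins, range=(0.0, 1.0))[0]
            / img[..., c].size
            for c in range(3)
        ]
        return np.concatenate(
            [pooled[..., c].ravel() for c in range(3)] + hists
        ).astype(float)


class FunctionExtractor(FeatureExtractor):
    """Adapter turning any callable into a feature backend."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], dim: int,
                 input_size: tuple[int, int] = (64, 64)):
        self.fn = fn
        self.dim = dim
        self.input_size = input_size

    def __call__(self, image: np.ndarray) -> np.ndarray:
        out = np.asarray(self.fn(image), dtype=float).ravel()
        if out.size != self.dim:
            raise ValueError(f"extractor returned {out.size} values, declared {self.dim}")
        return out


class AlexNetFC7Extractor(FeatureExtractor):
    """fc7 activations of an ImageNet-pretrained AlexNet (4096 features).

    Requires torch/torchvision; images are bilinearly resized to 224×224
    (no aspect-ratio preservation) and normalized with the standard
    ImageNet channel statistics after per-image rescaling to [0, 1].
    """

    input_size = (224, 224)
    dim = 4096

    def __init__(self):
        try:
            import torch
            import torchvision
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "AlexNetFC7Extractor needs the optional 'alexnet' extra "
                "(pip install gaitrep[alexnet])"
            ) from exc
        self._torch = torch
        net = torchvision.models.alexnet(weights="IMAGENET1K_V1")
        net.eval()
        # everything up to and including fc7 (classifier index 5 = ReLU after fc7)
        self._features = net.features
        self._avgpool = net.avgpool
        self._classifier = net.classifier[:5]

    def __call__(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        torch = self._torch
        img = np.asarray(image, dtype=float)
        img = resize(img, (*self.input_size, 3), order=1, preserve_range=True)
        peak = img.max()
        if peak > 0:
            img = img / peak
        mean = np.array([0.485, 0.456, 0.406])
        std = np.array([0.229, 0.224, 0.225])
        img = (img - mean) / std
        x = torch.from_numpy(img.transpose(2, 0, 1)[None]).float()
        with torch.no_grad():
            h = self._features(x)
            h = self._avgpool(h)
            h = torch.flatten(h, 1)
            h = self._classifier(h)
        return h.numpy().ravel()


def color_permutations(gait_map: GaitMap | np.ndarray) -> list[np.ndarray]:
    """All six channel orderings of a map, in the fixed block order.

    Single-channel maps are replicated to three identical channels first,
    so the six outputs coincide.
    """
    pixels = gait_map.pixels if isinstance(gait_map, GaitMap) else np.asarray(gait_map)
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    if pixels.shape[-1] != 3:
        raise ValueError("map must have 1 or 3 channels")
    return [pixels[..., list(p)] for p in PERMUTATIONS]


def extract_features(
    images: Sequence[np.ndarray],
    extractor: FeatureExtractor,
    label: Optional[str] = None,
    source_id: str = "",
) -> FeatureVector:
    """Concatenate the extractor's output over the six permuted images."""
    if len(images) != len(PERMUTATIONS):
        raise ValueError(f"expected {len(PERMUTATIONS)} permuted images, got {len(images)}")
    blocks = []
    for i, img in enumerate(images):
        try:
            blocks.append(extractor(img))
        except Exception as exc:
            raise RuntimeError(f"extractor failed on permutation {i}") from exc
    return FeatureVector(
        values=np.concatenate(blocks),
        per_perm_dim=extractor.dim,
        label=label,
        source_id=source_id,
    )


def features_from_map(
    gait_map: GaitMap,
    extractor: FeatureExtractor,
    label: Optional[str] = None,
    source_id: str = "",
) -> FeatureVector:
    """Color-shift augmentation + extraction for a single map."""
    return extract_features(color_permutations(gait_map), extractor, label, source_id)


@dataclass
class ReducerModel:
    """Per-class PCA projector.

    For each class ``c``, ``components[c]`` is a (P, D) matrix of
    orthonormal principal directions and ``means[c]`` the class mean; the
    reduced vector concatenates ``components[c] @ (v - means[c])`` over
    ``class_order``.
    """

    class_order: list[str]
    components: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)
    explained_variance_fraction: dict = field(default_factory=dict)
    n_components: int = 15

    @property
    def reduced_dim(self) -> int:
        return sum(self.components[c].shape[0] for c in self.class_order)

    def save(self, path) -> None:
        arrays = {"class_order": np.array(self.class_order)}
        for c in self.class_order:
            arrays[f"components_{c}"] = self.components[c]
            arrays[f"mean_{c}"] = self.means[c]
            arrays[f"evf_{c}"] = np.array(self.explained_variance_fraction[c])
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "ReducerModel":
        data = np.load(path, allow_pickle=False)
        order = [str(c) for c in data["class_order"]]
        model = cls(class_order=order)
        for c in order:
            model.components[c] = data[f"components_{c}"]
            model.means[c] = data[f"mean_{c}"]
            model.explained_variance_fraction[c] = float(data[f"evf_{c}"])
        model.n_components = model.components[order[0]].shape[0]
        return model


def fit_reducer(
    vectors: Sequence[FeatureVector] | np.ndarray,
    labels: Optional[Sequence[str]] = None,
    P: int = 15,
    variance_goal: float = 0.80,
) -> ReducerModel:
    """Fit the class-wise PCA reducer.

    Each class is centered by its own mean and decomposed by SVD; the top
    ``P`` right-singular vectors become the class's components. ``P`` is
    clamped (with a warning) to ``class count − 1``; a warning also fires
    when a class retains less than ``variance_goal`` of its variance.
    """
    if labels is None:
        X = np.stack([v.values for v in vectors])
        labels = [v.label for v in vectors]
    else:
        X = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    class_order = sorted(set(labels.tolist()))
    model = ReducerModel(class_order=class_order, n_components=P)
    for c in class_order:
        Xc = X[labels == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        p_eff = min(P, Xc.shape[0] - 1, Xc.shape[1])
        if p_eff < P:
            warnings.warn(
                f"class {c!r}: P clamped from {P} to {p_eff} "
                f"({Xc.shape[0]} samples, {Xc.shape[1]} features)",
                stacklevel=2,
            )
        mu = Xc.mean(axis=0)
        _, s, vt = np.linalg.svd(Xc - mu, full_matrices=False)
        total = float((s**2).sum())
        evf = float((s[:p_eff] ** 2).sum() / total) if total > 0 else 1.0
        if evf < variance_goal:
            warnings.warn(
                f"class {c!r}: top {p_eff} components retain only {evf:.1%} "
                f"of the variance (goal {variance_goal:.0%})",
                stacklevel=2,
            )
        model.components[c] = vt[:p_eff]
        model.means[c] = mu
        model.explained_variance_fraction[c] = evf
    return model


def reduce_features(v: FeatureVector | np.ndarray, model: ReducerModel) -> np.ndarray:
    """Project a feature vector onto every class's components.

    Returns the concatenation of ``components_c @ (v − μ_c)`` over the
    model's class order.
    """
    vec = v.values if isinstance(v, FeatureVector) else np.asarray(v, dtype=float)
    blocks = []
    for c in model.class_order:
        comps = model.components[c]
        if comps.shape[1] != vec.size:
            raise ValueError(
                f"dimension mismatch: vector has {vec.size}, model expects {comps.shape[1]}"
            )
        blocks.append(comps @ (vec - model.means[c]))
    return np.concatenate(blocks)
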