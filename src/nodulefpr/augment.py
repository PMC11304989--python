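"""Parameterized stochastic 3D patch augmentations with weak/strong policies.

Two augmentation strengths drive the consistency objective on unlabeled
data: *weak* augmentations (axis flips and small integer-voxel
translations) produce the reference view, and *strong* augmentations (a
weak augmentation followed by one heavier operator: in-plane rotation,
isotropic scaling, additive Gaussian noise, intensity scale/shift, Gaussian
blur or cutout) produce the perturbed view whose prediction is pulled
toward the reference.  On the labeled stream a single operator — including
the identity — is drawn uniformly per sample.

All operators preserve patch shape, the value range [−1, 1] and the label.
Rotations are in-plane by default because the anisotropic z-spacing makes
through-plane interpolation lossy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from nodulefpr.preprocess import ROI

__all__ = [
    "AugmentationPolicy",
    "WEAK_MENU",
    "STRONG_MENU",
    "FULL_MENU",
    "weak_augment",
    "strong_augment",
    "labeled_augment",
    "apply_operator",
]

PAD_VALUE = -1.0

Patch = np.ndarray


def _flip(patch: Patch, rng: np.random.Generator, magnitude: float) -> Patch:
    axes = [a for a in range(3) if rng.uniform() < 0.5]
    return np.flip(patch, axis=axes).copy() if axes else patch.copy()


def _translate(patch: Patch, rng: np.random.Generator, magnitude: float) -> Patch:
    max_shift = [int(np.floor(0.1 * n * magnitude)) for n in patch.shape]
    shift = [int(rng.integers(-m, m + 1)) if m > 0 else 0 for m in max_shift]
    return translate_patch(patch, shift)


def translate_patch(patch: Patch, shift: Sequence[int]) -> Patch:
    """Integer-voxel translation with −1 (air) fill; exactly invertible away
    from the borders."""
    out = np.full_like(patch, PAD_VALUE)
    src, dst = [], []
    for n, s in zip(patch.shape, shift):
        src.append(slice(max(-s, 0), min(n - s, n)))
        dst.append(slice(max(s, 0), min(n + s, n)))
    out[tuple(dst)] = patch[tuple(src)]
    return out


def _rotate(patch: Patch, rng: np.random.Generator, magnitude: float) -> Patch:
    angle = rng.uniform(-30.0, 30.0) * magnitude
    return ndimage.rotate(
        patch, angle, axes=(1, 2), reshape=False, order=1, cval=PAD_VALUE
    )


def _scale(patch: Patch, rng: np.random.Generator, magnitude: float) -> Patch:
    factor = 1.0 + rng.uniform(-0.2, 0.2) * magnitude
    center = (np.asarray(patch.shape, dtype=float) - 1.0) / 2.0
    matrix = np.eye(3) / factor
    offset = center - matrix @ center
    return ndimage.affine_transform(
        patch, matrix, offset=offset, order=1, cval=PAD_VALUE
    )


def _noise(patch: Patch, rng: np.random.Generator, magnitude: float) -> Patch:
    std = 0.1 * magnitude
    return patch + rng.normal(0.0, std, size=patch.shape).astype(patch.dtype)


def _intensity(patch: Patch, rng: np.random.Generator, magnitude: float) -> Patch:
    scale = 1.0 + rng.uniform(-0.2, 0.2) * magnitude
    shift = rng.uniform(-0.2, 0.2) * magnitude
    return patch * scale + shift


def _blur(patch: Patch, rng: np.random.Generator, magnitude: float) -> Patch:
    sigma = rng.uniform(0.0, 1.0) * magnitude
    return ndimage.gaussian_filter(patch, sigma=sigma) if sigma > 1e-6 else patch.copy()


def _cutout(patch: Patch, rng: np.random.Generator, magnitude: float) -> Patch:
    out = patch.copy()
    sides = [max(int(np.floor(0.25 * n * magnitude)), 1) for n in patch.shape]
    starts = [int(rng.integers(0, n - side + 1)) for n, side in zip(patch.shape, sides)]
    out[tuple(slice(s, s + w) for s, w in zip(starts, sides))] = PAD_VALUE
    return out


def _identity(patch: Patch, rng: np.random.Generator, magnitude: float) -> Patch:
    return patch.copy()


_OPERATORS: Dict[str, Callable[[Patch, np.random.Generator, float], Patch]] = {
    "identity": _identity,
    "flip": _flip,
    "translate": _translate,
    "rotate": _rotate,
    "scale": _scale,
    "noise": _noise,
    "intensity": _intensity,
    "blur": _blur,
    "cutout": _cutout,
}

WEAK_MENU: Tuple[str, ...] = ("flip", "translate")
STRONG_MENU: Tuple[str, ...] = ("rotate", "scale", "noise", "intensity", "blur", "cutout")
FULL_MENU: Tuple[str, ...] = WEAK_MENU + STRONG_MENU


@dataclass
class AugmentationPolicy:
    """Named augmentation policy for one data stream.

    ``kind`` is one of {weak, strong, labeled}; ``menu`` lists the operator
    names the policy may draw beyond its baseline (editable without code
    changes).  The weak baseline is always flip + translate; the labeled
    policy additionally includes the identity.
    """

    kind: str = "weak"
    magnitude: float = 1.0
    menu: Tuple[str, ...] = field(default_factory=lambda: STRONG_MENU)

    def __post_init__(self) -> None:
        if self.kind not in ("weak", "strong", "labeled"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("magnitude must lie in [0, 1]")
        for name in self.menu:
            if name not in _OPERATORS:
                raise KeyError(f"unknown augmentation operator {name!r}")

    def apply(self, patch: Patch, rng: Union[int, np.random.Generator]) -> Patch:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        if self.kind == "weak":
            return weak_augment(patch, rng, self.magnitude)
        if self.kind == "strong":
            return strong_augment(patch, rng, self.magnitude, menu=self.menu)
        return labeled_augment(patch, rng, self.magnitude, menu=self.menu)


def _unwrap(roi: Union[ROI, Patch]):
    if isinstance(roi, ROI):
        return roi.patch, roi
    return np.asarray(roi), None


def _wrap(patch: Patch, template) -> Union[ROI, Patch]:
    patch = np.clip(patch, -1.0, 1.0).astype(np.float32)
    if template is not None:
        return ROI(patch=patch, candidate=template.candidate, label=template.label)
    return patch


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def weak_augment(
    roi: Union[ROI, Patch],
    seed: Union[int, np.random.Generator] = 0,
    magnitude: float = 1.0,
) -> Union[ROI, Patch]:
    """Random axis flips plus an integer-voxel translation of at most 10% of
    the patch extent.  Magnitude 0 is the identity; label and shape are
    unchanged."""
    patch, template = _unwrap(roi)
    rng = _rng(seed)
    if magnitude > 0:
        patch = _flip(patch, rng, magnitude)
        patch = _translate(patch, rng, magnitude)
    else:
        patch = patch.copy()
    return _wrap(patch, template)


def strong_augment(
    roi: Union[ROI, Patch],
    seed: Union[int, np.random.Generator] = 0,
    magnitude: float = 1.0,
    menu: Sequence[str] = STRONG_MENU,
) -> Union[ROI, Patch]:
    """A weak augmentation followed by one operator drawn uniformly from the
    strong menu.  Magnitude 0 reduces to the weak augmentation alone."""
    for name in menu:
        if name not in _OPERATORS:
            raise KeyError(f"unknown augmentation operator {name!r}")
    patch, template = _unwrap(roi)
    rng = _rng(seed)
    if magnitude > 0:
        patch = _flip(patch, rng, magnitude)
        patch = _translate(patch, rng, magnitude)
        name = menu[int(rng.integers(len(menu)))]
        patch = _OPERATORS[name](patch, rng, magnitude)
    else:
        patch = weak_augment(patch, rng, magnitude)
    return _wrap(patch, template)


def labeled_augment(
    roi: Union[ROI, Patch],
    seed: Union[int, np.random.Generator] = 0,
    magnitude: float = 1.0,
    menu: Sequence[str] = FULL_MENU,
    return_name: bool = False,
) -> Union[ROI, Patch, Tuple[Union[ROI, Patch], str]]:
    """One operator from {identity} ∪ menu, each with equal probability,
    applied uniformly to positive and negative samples alike.

    With ``return_name`` the chosen operator name is returned alongside the
    output (useful for auditing the selection distribution).
    """
    patch, template = _unwrap(roi)
    rng = _rng(seed)
    options = ("identity",) + tuple(menu)
    name = options[int(rng.integers(len(options)))]
    if name not in _OPERATORS:
        raise KeyError(f"unknown augmentation operator {name!r}")
    patch = _OPERATORS[name](patch, rng, magnitude)
    out = _wrap(patch, template)
    return (out, name) if return_name else out


def apply_operator(
    name: str,
    roi: Union[ROI, Patch],
    seed: Union[int, np.random.Generator] = 0,
    magnitude: float = 1.0,
) -> Union[ROI, Patch]:
    """Apply a single named operator (mainly for tests and visualisation)."""
    if name not in _OPERATORS:
        raise KeyError(f"unknown augmentation operator {name!r}")
    patch, template = _unwrap(roi)
    return _wrap(_OPERATORS[name](patch, _rng(seed), magnitude), template)
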