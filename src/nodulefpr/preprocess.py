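"""Normalization and ROI extraction: from HU volumes to training patches.

The pipeline brings every scan to a common geometry and intensity scale and
cuts fixed-size patches around candidate locations:

1. resample to (2.0, 0.625, 0.625) mm spacing (trilinear);
2. clip HU to [−1000, 400] and rescale linearly to [−1, 1];
3. extract a 30-mm cube around each candidate → a (15, 48, 48) patch,
   padding out-of-volume regions with −1 (air);
4. sample nodule-free negative candidates uniformly over lung tissue
   (1000 per scan in the reference configuration) and oversample positives
   (250× in the reference configuration) to counter class imbalance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from nodulefpr.volumes import (
    NEGATIVE,
    POSITIVE,
    AnnotationRecord,
    Candidate,
    Volume,
    voxel_to_world,
    world_to_voxel,
)

__all__ = [
    "PreprocessConfig",
    "ROI",
    "PlacementError",
    "SamplingError",
    "resample_volume",
    "normalize_intensity",
    "extract_roi",
    "sample_negatives",
    "oversample_positives",
    "filter_scans",
]


class PlacementError(ValueError):
    """Raised when an ROI center lies too far outside the volume."""


class SamplingError(RuntimeError):
    """Raised when negative sampling cannot find enough admissible centers."""


@dataclass
class PreprocessConfig:
    """Pipeline constants.

    ``roi_size_mm`` of 30 at the target spacing yields patches of
    15 × 48 × 48 voxels (30/2 slices, 30/0.625 in-plane).
    """

    target_spacing: Tuple[float, float, float] = (2.0, 0.625, 0.625)
    hu_window: Tuple[float, float] = (-1000.0, 400.0)
    roi_size_mm: float = 30.0
    negatives_per_scan: int = 1000
    positive_oversample: int = 250

    def __post_init__(self) -> None:
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError("hu_window must satisfy lo < hi")
        if self.roi_size_mm <= 0:
            raise ValueError("roi_size_mm must be positive")

    @property
    def roi_shape(self) -> Tuple[int, int, int]:
        return tuple(
            int(round(self.roi_size_mm / s)) for s in self.target_spacing
        )


@dataclass
class ROI:
    """A fixed-size normalized patch centered on a candidate."""

    patch: np.ndarray  # (z, y, x), values in [−1, 1]
    candidate: Optional[Candidate] = None
    label: str = "unknown"


def resample_volume(
    vol: Volume, target_spacing: Sequence[float]
) -> Volume:
    """Trilinear resampling to ``target_spacing``; origin preserved.

    Output dimensions are ``round(dim · spacing / target)`` per axis.  The
    output grid is anchored at voxel (0, 0, 0), so when the input is already
    at the target spacing the operation is the identity on lattice points.
    """
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if tuple(vol.spacing) == target:
        return Volume(vol.data.copy(), vol.spacing, vol.origin)
    out_shape = tuple(
        max(int(round(n * s / t)), 1)
        for n, s, t in zip(vol.data.shape, vol.spacing, target)
    )
    # new index -> old continuous index: i_new · target / spacing
    axes = [
        np.arange(n, dtype=np.float64) * t / s
        for n, s, t in zip(out_shape, vol.spacing, target)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    data = map_coordinates(
        vol.data.astype(np.float32), coords, order=1, mode="nearest"
    ).reshape(out_shape)
    return Volume(data=data, spacing=target, origin=vol.origin)


def normalize_intensity(
    vol: Volume, hu_window: Tuple[float, float] = (-1000.0, 400.0)
) -> Volume:
    """Clip to the HU window and rescale linearly to [−1, 1]."""
    lo, hi = (float(h) for h in hu_window)
    if lo >= hi:
        raise ValueError("hu_window must satisfy lo < hi")
    data = np.clip(vol.data.astype(np.float32), lo, hi)
    data = 2.0 * (data - lo) / (hi - lo) - 1.0
    return Volume(data=data, spacing=vol.spacing, origin=vol.origin)


def extract_roi(
    vol: Volume,
    center_world: Sequence[float],
    roi_size_mm: float = 30.0,
    candidate: Optional[Candidate] = None,
    label: str = "unknown",
    pad_value: float = -1.0,
) -> ROI:
    """Cut a fixed-size cube (in mm) around a world point.

    The volume must already be at the target spacing and normalized.  The
    center voxel is the nearest voxel to ``center_world`` (half-up rounding
    of the continuous index, so even-sized extents have a fixed, documented
    center convention); out-of-volume regions are padded with ``pad_value``
    (−1 = air after normalization).  Centers farther than ``roi_size_mm``
    outside the volume bounding box raise :class:`PlacementError`.
    """
    shape = tuple(int(round(roi_size_mm / s)) for s in vol.spacing)
    idx = world_to_voxel(vol, center_world)
    for c, n, s in zip(idx, vol.data.shape, vol.spacing):
        if c < -roi_size_mm / s or c > (n - 1) + roi_size_mm / s:
            raise PlacementError(
                f"ROI center index {tuple(round(v, 2) for v in idx)} lies more "
                f"than the ROI size outside the volume of shape {vol.data.shape}"
            )
    center = tuple(int(math.floor(c + 0.5)) for c in idx)
    patch = np.full(shape, pad_value, dtype=np.float32)
    src_lo, src_hi, dst_lo, dst_hi = [], [], [], []
    for c, m, n in zip(center, shape, vol.data.shape):
        start = c - m // 2
        s_lo, s_hi = max(start, 0), min(start + m, n)
        src_lo.append(s_lo)
        src_hi.append(s_hi)
        dst_lo.append(s_lo - start)
        dst_hi.append(s_hi - start)
    if all(hi > lo for lo, hi in zip(src_lo, src_hi)):
        patch[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = (
            vol.data[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
        )
    return ROI(patch=patch, candidate=candidate, label=label)


def sample_negatives(
    vol: Volume,
    truth: Sequence[AnnotationRecord],
    n: int = 1000,
    seed: int = 0,
    roi_size_mm: float = 30.0,
    scan_id: Optional[str] = None,
    max_tries: int = 200,
) -> List[Candidate]:
    """Sample ``n`` nodule-free candidate centers, uniform over lung tissue.

    A center is admissible when its ROI box does not intersect the bounding
    sphere of any truth nodule.  Sampling is restricted to lung-tissue
    voxels — parenchyma plus vessels and airway walls, excluding outside
    air and the chest wall; the volume may be HU-valued or already
    normalized.  Deterministic given ``seed``; raises
    :class:`SamplingError` when the admissible region is too small.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    data = vol.data
    normalized = data.min() >= -1.0 - 1e-6 and data.max() <= 1.0 + 1e-6
    # lung tissue including vessels/airway walls, excluding outside air and
    # the chest wall — the "remaining areas" a first-stage detector scans
    lo, hi = (-0.95, 0.65) if normalized else (-965.0, 155.0)
    pool = np.argwhere((data > lo) & (data < hi))
    if len(pool) == 0:
        raise SamplingError("no parenchyma-density voxels available for sampling")
    if scan_id is None:
        scan_id = truth[0].scan_id if truth else "scan"
    half = roi_size_mm / 2.0
    centers = np.array([t.center_world for t in truth], dtype=float).reshape(-1, 3)
    radii = np.array([t.diameter_mm / 2.0 for t in truth], dtype=float)

    out: List[Candidate] = []
    for _ in range(max_tries):
        need = n - len(out)
        if need <= 0:
            break
        draw = pool[rng.integers(len(pool), size=2 * need + 8)]
        jitter = rng.uniform(-0.5, 0.5, size=draw.shape)
        world = np.stack(
            [voxel_to_world(vol, kji) for kji in draw + jitter]
        )  # (m, 3) in (x, y, z)
        if len(centers):
            # ROI box (half-extent `half` per world axis) vs truth bounding sphere:
            # closest point of the box to the sphere center must be outside it
            delta = np.abs(world[:, None, :] - centers[None, :, :])
            closest = np.maximum(delta - half, 0.0)
            dist = np.sqrt((closest**2).sum(axis=2))
            ok = (dist > radii[None, :]).all(axis=1)
        else:
            ok = np.ones(len(world), dtype=bool)
        for w in world[ok][:need]:
            out.append(
                Candidate(scan_id=scan_id, center_world=tuple(w), label=NEGATIVE)
            )
    if len(out) < n:
        raise SamplingError(
            f"only {len(out)}/{n} admissible negative centers found after "
            f"{max_tries} rounds"
        )
    return out


def oversample_positives(
    rois: Sequence[ROI], factor: int, seed: Optional[int] = None
) -> List[ROI]:
    """Repeat each positive ROI ``factor`` times; negatives are untouched.

    With ``seed`` given, the output order is shuffled reproducibly;
    otherwise positives-then-negatives order is preserved.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    out: List[ROI] = []
    for roi in rois:
        if roi.label == POSITIVE:
            out.extend([roi] * factor)
        else:
            out.append(roi)
    if seed is not None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(out))
        out = [out[i] for i in order]
    return out


def filter_scans(
    metadata: Sequence[Dict], max_thickness_mm: float = 2.5, z_tol_mm: float = 1e-3
) -> List[Dict]:
    """Keep scans with consistent geometry, following the LUNA16 criteria.

    Each metadata record needs ``slice_thickness_mm`` and ``z_positions``
    (per-slice z in mm).  A scan is kept iff its thickness is at most
    ``max_thickness_mm``, the z deltas are uniform within ``z_tol_mm`` and
    there are no gaps (missing slices show up as doubled deltas and fail
    the uniformity check).
    """
    kept: List[Dict] = []
    for meta in metadata:
        if float(meta["slice_thickness_mm"]) > max_thickness_mm:
            continue
        z = np.asarray(meta["z_positions"], dtype=float)
        if len(z) >= 2:
            deltas = np.diff(np.sort(z))
            if deltas.min() <= 0:
                continue
            if np.ptp(deltas) > z_tol_mm:
                continue
        kept.append(meta)
    return kept
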