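"""Phantom-like and clinical-like chest-CT simulation with ground truth.

The generator emulates two data regimes:

* **phantom mode** — an anthropomorphic thorax phantom: clean lung
  parenchyma (≈ −850 HU) inside a chest-wall shell (≈ +40 HU), air outside
  (−1000 HU), a sparse branching "vascular insert" (≈ +50 HU), and inserted
  synthetic nodules from four shape families (spherical, elliptical,
  lobulated, spiculated), 5–20 mm diameter, densities {−630, −10, 100} HU.
* **clinical mode** — the same scaffold plus the structures that make real
  scans hard: textured parenchyma, denser bifurcating vessel trees, airways,
  scar-like blobs, pleural-attached and calcified nodules.  These act as
  "hard mimics" for a false-positive-reduction classifier trained on clean
  phantom data.

All generators are pure functions of (parameters, seed).  A region-proposal
emulator (:func:`propose_candidates`) stands in for the high-sensitivity
first detection stage, producing candidate lists in world coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

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
    "NoduleSpec",
    "ScanLayout",
    "LayoutError",
    "DegenerateShapeError",
    "SHAPE_FAMILIES",
    "PHANTOM_DENSITIES_HU",
    "CATALOGUE_DIAMETERS_MM",
    "DEFAULT_SPACING",
    "DEFAULT_GRID",
    "generate_nodule_mask",
    "generate_phantom_scan",
    "generate_clinical_scan",
    "propose_candidates",
    "phantom_nodule_catalogue",
    "random_layout",
    "default_phantom_layouts",
]

SHAPE_FAMILIES = ("spherical", "elliptical", "lobulated", "spiculated")
#: nodule densities available in phantom mode (HU)
PHANTOM_DENSITIES_HU = (-630.0, -10.0, 100.0)
#: diameters of the physical nodule inventory (mm)
CATALOGUE_DIAMETERS_MM = (5.0, 8.0, 10.0, 20.0)

#: (z, y, x) mm — the target spacing of the downstream pipeline; generating
#: at this spacing makes resampling the identity.
DEFAULT_SPACING = (2.0, 0.625, 0.625)
#: (z, y, x) voxels — desk-scale grid: 40 × 60 × 60 mm field of view.
DEFAULT_GRID = (20, 96, 96)

# background tissue densities (HU)
HU_AIR = -1000.0
HU_PARENCHYMA = -850.0
HU_WALL = 40.0
HU_VESSEL = 50.0


class LayoutError(ValueError):
    """Raised when nodules in a layout overlap or do not fit the lung region."""


class DegenerateShapeError(ValueError):
    """Raised when a nodule diameter is below one voxel along some axis."""


@dataclass
class NoduleSpec:
    """Ground-truth descriptor of one inserted nodule."""

    shape_family: str
    diameter_mm: float
    density_hu: float
    center_world: Tuple[float, float, float]  # (x, y, z) mm
    attachment: str = "none"  # {none, vessel, pleural}

    def __post_init__(self) -> None:
        if self.shape_family not in SHAPE_FAMILIES:
            raise ValueError(f"unknown shape family {self.shape_family!r}")
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if self.attachment not in ("none", "vessel", "pleural"):
            raise ValueError(f"unknown attachment {self.attachment!r}")
        self.center_world = tuple(float(c) for c in self.center_world)


@dataclass
class ScanLayout:
    """Per-scan collection of nodules plus the acquisition protocol knobs.

    The protocol of the real acquisitions (dose, pitch, reconstruction
    kernel) is collapsed onto two effective parameters: additive Gaussian
    noise level (HU std) and slice thickness.
    """

    scan_id: str
    nodules: List[NoduleSpec] = field(default_factory=list)
    noise_hu: float = 12.0
    slice_thickness_mm: float = 2.0
    seed: int = 0


# ---------------------------------------------------------------------------
# nodule masks


def _mask_grid(diameter_mm: float, spacing: Sequence[float]):
    """Odd-sized voxel grid covering 1.5·d per axis, with mm offset coords."""
    dims = []
    for s in spacing:
        n = int(math.ceil(1.5 * diameter_mm / s))
        if n % 2 == 0:
            n += 1
        dims.append(max(n, 1))
    offs = [
        (np.arange(n, dtype=np.float64) - (n - 1) / 2.0) * s
        for n, s in zip(dims, spacing)
    ]
    zz, yy, xx = np.meshgrid(*offs, indexing="ij", sparse=True)
    return zz, yy, xx


def generate_nodule_mask(
    shape_family: str,
    diameter_mm: float,
    spacing: Sequence[float] = DEFAULT_SPACING,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Rasterize one nodule as a boolean occupancy grid.

    The grid is centered on the nodule and spans at most 1.5·d per axis.
    Shape construction:

    * spherical — ball of radius d/2;
    * elliptical — ellipsoid with axis ratios drawn from [0.6, 1.0],
      rescaled so the mean axis equals d;
    * lobulated — union of 3–6 spheres with radii in [0.3 d, 0.5 d] and
      centers within 0.3 d of the nodule center (lobes clipped so the total
      extent stays within 1.5 d);
    * spiculated — central sphere of radius 0.35 d plus 8–16 radial conical
      spikes of length ≤ 0.5 d.

    Raises :class:`DegenerateShapeError` when the diameter is below one
    voxel along any axis.
    """
    if shape_family not in SHAPE_FAMILIES:
        raise ValueError(f"unknown shape family {shape_family!r}")
    if diameter_mm <= 0 or any(s <= 0 for s in spacing):
        raise ValueError("diameter and spacing must be positive")
    if any(diameter_mm < s for s in spacing):
        raise DegenerateShapeError(
            f"diameter {diameter_mm} mm is below one voxel for spacing {tuple(spacing)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = float(diameter_mm)
    zz, yy, xx = _mask_grid(d, spacing)

    if shape_family == "spherical":
        return zz**2 + yy**2 + xx**2 <= (d / 2) ** 2

    if shape_family == "elliptical":
        ratios = rng.uniform(0.6, 1.0, size=3)
        ratios = ratios / ratios.mean()  # mean axis equals d
        a_z, a_y, a_x = np.minimum(ratios * d / 2.0, 0.75 * d)
        return (zz / a_z) ** 2 + (yy / a_y) ** 2 + (xx / a_x) ** 2 <= 1.0

    if shape_family == "lobulated":
        n_lobes = int(rng.integers(3, 7))
        mask = np.zeros(np.broadcast(zz, yy, xx).shape, dtype=bool)
        for _ in range(n_lobes):
            direction = _random_unit(rng)
            offset = direction * rng.uniform(0.0, 0.3 * d)
            radius = rng.uniform(0.3 * d, 0.5 * d)
            # keep the union inside the 1.5·d bounding box
            radius = min(radius, 0.75 * d - np.linalg.norm(offset))
            mask |= (zz - offset[0]) ** 2 + (yy - offset[1]) ** 2 + (
                xx - offset[2]
            ) ** 2 <= radius**2
        return mask

    # spiculated
    core_r = 0.35 * d
    mask = zz**2 + yy**2 + xx**2 <= core_r**2
    n_spikes = int(rng.integers(8, 17))
    r2 = zz**2 + yy**2 + xx**2
    for _ in range(n_spikes):
        u = _random_unit(rng)
        length = rng.uniform(0.25 * d, 0.5 * d)
        tip = min(core_r + length, 0.75 * d)
        base_w = rng.uniform(0.08 * d, 0.15 * d)
        t = zz * u[0] + yy * u[1] + xx * u[2]  # axial coordinate along spike
        perp2 = r2 - t**2
        taper = base_w * (1.0 - t / tip)
        mask |= (t >= 0) & (t <= tip) & (perp2 <= np.maximum(taper, 0.0) ** 2)
    return mask


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-9:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


# ---------------------------------------------------------------------------
# scan scaffold


def _thorax_background(
    grid: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    rng: np.random.Generator,
    wall_mm: float = 4.0,
):
    """Air / chest-wall / parenchyma scaffold; returns (data, lung_mask)."""
    nz, ny, nx = grid
    sz, sy, sx = spacing
    z = (np.arange(nz) - (nz - 1) / 2) * sz
    y = (np.arange(ny) - (ny - 1) / 2) * sy
    x = (np.arange(nx) - (nx - 1) / 2) * sx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij", sparse=True)
    # elliptical cylinder "body" occupying most of the in-plane field of view
    a_y = 0.46 * ny * sy
    a_x = 0.46 * nx * sx
    r_out = (yy / a_y) ** 2 + (xx / a_x) ** 2
    r_in = (yy / (a_y - wall_mm)) ** 2 + (xx / (a_x - wall_mm)) ** 2
    data = np.full(grid, HU_AIR, dtype=np.float32)
    body = np.broadcast_to(r_out <= 1.0, grid)
    lung = np.broadcast_to(r_in <= 1.0, grid)
    data[body & ~lung] = HU_WALL
    data[lung] = HU_PARENCHYMA
    return data, lung, (zz, yy, xx)


def lung_region(
    grid: Tuple[int, int, int],
    spacing: Tuple[float, float, float] = DEFAULT_SPACING,
) -> np.ndarray:
    """The deterministic lung-interior mask of the simulated thorax.

    Useful for analyses that must exclude the chest wall (e.g. counting
    intra-pulmonary structures).
    """
    _, lung, _ = _thorax_background(grid, spacing, np.random.default_rng(0))
    return np.ascontiguousarray(lung)


def _paint_tube(
    data: np.ndarray,
    spacing: Tuple[float, float, float],
    p0: np.ndarray,
    p1: np.ndarray,
    radius_mm: float,
    value: float,
    lung: np.ndarray,
) -> None:
    """Paint a cylinder (as overlapping balls) between two voxel-space points.

    ``p0``/``p1`` are continuous (k, j, i) indices; painting is restricted to
    the lung region so tubes never pierce the chest wall.
    """
    sz, sy, sx = spacing
    length_mm = float(np.linalg.norm((p1 - p0) * np.array([sz, sy, sx])))
    n_steps = max(int(length_mm / (0.5 * min(spacing))), 2)
    rz = max(int(math.ceil(radius_mm / sz)), 1)
    ry = max(int(math.ceil(radius_mm / sy)), 1)
    rx = max(int(math.ceil(radius_mm / sx)), 1)
    oz = (np.arange(-rz, rz + 1) * sz)[:, None, None]
    oy = (np.arange(-ry, ry + 1) * sy)[None, :, None]
    ox = (np.arange(-rx, rx + 1) * sx)[None, None, :]
    ball = oz**2 + oy**2 + ox**2 <= radius_mm**2
    nz, ny, nx = data.shape
    for t in np.linspace(0.0, 1.0, n_steps):
        c = p0 + t * (p1 - p0)
        k, j, i = int(round(c[0])), int(round(c[1])), int(round(c[2]))
        k0, k1 = max(k - rz, 0), min(k + rz + 1, nz)
        j0, j1 = max(j - ry, 0), min(j + ry + 1, ny)
        i0, i1 = max(i - rx, 0), min(i + rx + 1, nx)
        if k0 >= k1 or j0 >= j1 or i0 >= i1:
            continue
        sub = ball[k0 - (k - rz) : k1 - (k - rz), j0 - (j - ry) : j1 - (j - ry),
                   i0 - (i - rx) : i1 - (i - rx)]
        region = data[k0:k1, j0:j1, i0:i1]
        paint = sub & lung[k0:k1, j0:j1, i0:i1]
        region[paint] = value
        data[k0:k1, j0:j1, i0:i1] = region


def _vessel_tree(
    data: np.ndarray,
    spacing: Tuple[float, float, float],
    lung: np.ndarray,
    rng: np.random.Generator,
    n_roots: int,
    depth: int,
    radius_mm: float,
    value: float = HU_VESSEL,
) -> None:
    """Recursive branching tubes emulating a vascular insert / vessel tree."""
    nz, ny, nx = data.shape
    center = np.array([(nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2], dtype=float)

    def branch(p: np.ndarray, direction: np.ndarray, r: float, level: int) -> None:
        if level <= 0 or r < 0.4:
            return
        length_vox = rng.uniform(0.2, 0.4) * min(nz, ny, nx)
        q = p + direction * length_vox
        q = np.clip(q, 0, np.array([nz - 1, ny - 1, nx - 1], dtype=float))
        _paint_tube(data, spacing, p, q, r, value, lung)
        for _ in range(2):
            new_dir = direction + rng.normal(scale=0.6, size=3)
            new_dir /= max(np.linalg.norm(new_dir), 1e-9)
            branch(q, new_dir, r * rng.uniform(0.55, 0.8), level - 1)

    for _ in range(n_roots):
        start = center + rng.normal(scale=[data.shape[0] * 0.15,
                                           data.shape[1] * 0.1,
                                           data.shape[2] * 0.1])
        direction = _random_unit(rng)
        branch(start, direction, radius_mm, depth)


def _insert_nodule(
    data: np.ndarray,
    spacing: Tuple[float, float, float],
    center_idx: Tuple[int, int, int],
    mask: np.ndarray,
    density_hu: float,
    edge_sigma_vox: float = 0.7,
) -> None:
    """Blend a nodule mask into the volume with Gaussian edge smoothing.

    The smoothing emulates partial-volume averaging at the nodule boundary.
    """
    soft = gaussian_filter(mask.astype(np.float32), sigma=edge_sigma_vox)
    soft = np.clip(soft / max(soft.max(), 1e-9), 0.0, 1.0)
    mz, my, mx = mask.shape
    k, j, i = center_idx
    k0 = k - mz // 2
    j0 = j - my // 2
    i0 = i - mx // 2
    nz, ny, nx = data.shape
    ks, js, is_ = max(k0, 0), max(j0, 0), max(i0, 0)
    ke, je, ie = min(k0 + mz, nz), min(j0 + my, ny), min(i0 + mx, nx)
    if ks >= ke or js >= je or is_ >= ie:
        raise LayoutError("nodule lies entirely outside the volume")
    sub = soft[ks - k0 : ke - k0, js - j0 : je - j0, is_ - i0 : ie - i0]
    region = data[ks:ke, js:je, is_:ie]
    data[ks:ke, js:je, is_:ie] = region * (1.0 - sub) + density_hu * sub


def _check_no_overlap(nodules: Sequence[NoduleSpec]) -> None:
    # masks are bounded by a 0.75·d radius, so this sphere test is sufficient
    for a_i in range(len(nodules)):
        for b_i in range(a_i + 1, len(nodules)):
            a, b = nodules[a_i], nodules[b_i]
            dist = math.dist(a.center_world, b.center_world)
            if dist < 0.75 * (a.diameter_mm + b.diameter_mm):
                raise LayoutError(
                    f"nodules {a_i} and {b_i} overlap (centers {dist:.1f} mm apart)"
                )


def generate_phantom_scan(
    layout: ScanLayout,
    grid: Tuple[int, int, int] = DEFAULT_GRID,
    spacing: Tuple[float, float, float] = None,
) -> Tuple[Volume, List[AnnotationRecord]]:
    """Render a phantom-mode scan from a layout; deterministic given the seed.

    Returns the volume (HU-valued, origin at (0,0,0)) and one annotation per
    nodule with its true center and diameter.
    """
    if spacing is None:
        spacing = (layout.slice_thickness_mm, DEFAULT_SPACING[1], DEFAULT_SPACING[2])
    _check_no_overlap(layout.nodules)
    rng = np.random.default_rng(layout.seed)
    data, lung, _ = _thorax_background(grid, spacing, rng)
    # sparse "vascular insert"
    _vessel_tree(data, spacing, lung, rng, n_roots=2, depth=2, radius_mm=1.2)
    vol = Volume(data=data, spacing=spacing, origin=(0.0, 0.0, 0.0))

    annotations: List[AnnotationRecord] = []
    for n_i, spec in enumerate(layout.nodules):
        mask = generate_nodule_mask(
            spec.shape_family, spec.diameter_mm, spacing,
            seed=np.random.default_rng((layout.seed, 1, n_i)),
        )
        k, j, i = world_to_voxel(vol, spec.center_world)
        _insert_nodule(
            data, spacing, (int(round(k)), int(round(j)), int(round(i))),
            mask, spec.density_hu,
        )
        annotations.append(
            AnnotationRecord(
                scan_id=layout.scan_id,
                center_world=spec.center_world,
                diameter_mm=spec.diameter_mm,
                agreement=4,
            )
        )
    if layout.noise_hu > 0:
        data += rng.normal(0.0, layout.noise_hu, size=data.shape).astype(np.float32)
    vol.data = data
    return vol, annotations


# ---------------------------------------------------------------------------
# clinical mode


def generate_clinical_scan(
    seed: int,
    difficulty: float = 1.0,
    n_nodules: Optional[int] = None,
    grid: Tuple[int, int, int] = DEFAULT_GRID,
    spacing: Tuple[float, float, float] = DEFAULT_SPACING,
    scan_id: Optional[str] = None,
    diameter_range_mm: Tuple[float, float] = (5.0, 20.0),
) -> Tuple[Volume, List[AnnotationRecord]]:
    """Render a clinical-like scan: phantom scaffold plus hard-mimic anatomy.

    ``difficulty`` in [0, 1] scales the extra structure: at 0 the output is
    distributionally close to a phantom scan (no mimics, phantom densities);
    at 1 the scan carries textured parenchyma, dense vessel trees, airways,
    scar blobs, pleural-attached and possibly calcified nodules.
    """
    if not 0.0 <= difficulty <= 1.0:
        raise ValueError("difficulty must lie in [0, 1]")
    scan_id = scan_id or f"clinical-{seed}"
    rng = np.random.default_rng(seed)
    noise_hu = 12.0 + 10.0 * difficulty
    data, lung, _ = _thorax_background(grid, spacing, rng)

    # parenchymal texture: band-limited noise, amplitude grows with difficulty
    if difficulty > 0:
        tex = rng.normal(size=grid).astype(np.float32)
        tex = gaussian_filter(tex, sigma=(0.8, 2.0, 2.0))
        tex *= 60.0 * difficulty / max(tex.std(), 1e-9)
        data[lung] += tex[lung]

    # vessels: sparse insert at difficulty 0, denser bifurcating tree otherwise
    n_roots = 2 + int(round(2 * difficulty))
    depth = 2 + int(round(difficulty))
    _vessel_tree(data, spacing, lung, rng, n_roots=n_roots, depth=depth,
                 radius_mm=1.2 + 0.2 * difficulty)

    vol = Volume(data=data, spacing=spacing, origin=(0.0, 0.0, 0.0))

    if difficulty > 0:
        # airways: air-density tubes through the lung
        for _ in range(1 + int(round(2 * difficulty))):
            p0 = _random_lung_point(lung, rng)
            direction = _random_unit(rng)
            p1 = p0 + direction * 0.5 * min(grid)
            _paint_tube(data, spacing, p0, p1, 1.5, HU_AIR, lung)
        # scar-like soft-tissue blobs (hard mimics); placed in clear
        # parenchyma so they form structures distinct from the vessel tree
        for _ in range(int(round(5 * difficulty))):
            d_blob = rng.uniform(4.0, 8.0)
            rj = 1 + int(d_blob / spacing[1])
            rk = 1 + int(d_blob / (2 * spacing[0]))
            for _try in range(60):
                c = _random_lung_point(lung, rng, margin_vox=4)
                k, j, i = (int(round(v)) for v in c)
                region = data[max(k - rk, 0) : k + rk + 1,
                              max(j - rj, 0) : j + rj + 1,
                              max(i - rj, 0) : i + rj + 1]
                if region.max() < -500.0:
                    blob = generate_nodule_mask("lobulated", d_blob, spacing,
                                                seed=rng)
                    _insert_nodule(data, spacing, (k, j, i), blob,
                                   rng.uniform(-150.0, 60.0))
                    break

    # nodules
    if n_nodules is None:
        n_nodules = int(rng.integers(1, 5))
    nodules: List[NoduleSpec] = []
    attempts = 0
    while len(nodules) < n_nodules and attempts < 200:
        attempts += 1
        diameter = float(rng.uniform(*diameter_range_mm))
        pleural = difficulty > 0 and rng.uniform() < 0.3 * difficulty
        c_idx = _random_lung_point(
            lung, rng,
            margin_vox=2 if pleural else 1 + int(diameter / (2 * min(spacing)) / 4),
        )
        center = voxel_to_world(vol, c_idx)
        if difficulty > 0 and rng.uniform() < 0.15 * difficulty:
            density = float(rng.uniform(200.0, 400.0))  # calcified
        elif difficulty > 0:
            density = float(rng.uniform(-400.0, 150.0))
        else:
            density = float(rng.choice(PHANTOM_DENSITIES_HU))
        spec = NoduleSpec(
            shape_family=str(rng.choice(SHAPE_FAMILIES)),
            diameter_mm=diameter,
            density_hu=density,
            center_world=center,
            attachment="pleural" if pleural else "none",
        )
        try:
            _check_no_overlap(nodules + [spec])
        except LayoutError:
            continue
        nodules.append(spec)

    annotations: List[AnnotationRecord] = []
    for n_i, spec in enumerate(nodules):
        mask = generate_nodule_mask(
            spec.shape_family, spec.diameter_mm, spacing,
            seed=np.random.default_rng((seed, 2, n_i)),
        )
        k, j, i = world_to_voxel(vol, spec.center_world)
        _insert_nodule(data, spacing,
                       (int(round(k)), int(round(j)), int(round(i))),
                       mask, spec.density_hu)
        annotations.append(
            AnnotationRecord(
                scan_id=scan_id,
                center_world=spec.center_world,
                diameter_mm=spec.diameter_mm,
                agreement=int(rng.integers(3, 5)),
            )
        )
    data += rng.normal(0.0, noise_hu, size=data.shape).astype(np.float32)
    vol.data = data
    return vol, annotations


def _random_lung_point(
    lung: np.ndarray, rng: np.random.Generator, margin_vox: int = 2
) -> np.ndarray:
    """A voxel index well inside the lung region (eroded by a z/y/x margin)."""
    nz, ny, nx = lung.shape
    for _ in range(500):
        k = int(rng.integers(margin_vox, max(nz - margin_vox, margin_vox + 1)))
        j = int(rng.integers(4 * margin_vox, max(ny - 4 * margin_vox, 4 * margin_vox + 1)))
        i = int(rng.integers(4 * margin_vox, max(nx - 4 * margin_vox, 4 * margin_vox + 1)))
        if lung[k, j, i]:
            return np.array([k, j, i], dtype=float)
    raise LayoutError("could not find a point inside the lung region")


# ---------------------------------------------------------------------------
# region-proposal emulation


def propose_candidates(
    vol: Volume,
    truth: Sequence[AnnotationRecord],
    n_per_scan: int = 150,
    sensitivity: float = 0.95,
    seed: int = 0,
    scan_id: Optional[str] = None,
) -> List[Candidate]:
    """Emulate the stage-1 detector union by sampling a candidate list.

    Each truth is included with probability ``sensitivity`` with a center
    jitter of at most 0.25·diameter; the remaining candidates are placed
    preferentially on bright structures (vessels / wall / mimics) until
    ``n_per_scan`` is reached.  Labels follow the FROC hit criterion: a
    candidate is positive iff its center lies within diameter/2 of a truth
    center.
    """
    if n_per_scan < len(truth):
        raise ValueError("n_per_scan must be at least the number of truths")
    rng = np.random.default_rng(seed)
    if scan_id is None:
        scan_id = truth[0].scan_id if truth else "scan"
    candidates: List[Candidate] = []
    for ann in truth:
        if rng.uniform() >= sensitivity:
            continue
        direction = _random_unit(rng)
        radius = 0.25 * ann.diameter_mm * rng.uniform() ** (1 / 3)
        center = tuple(np.asarray(ann.center_world) + direction * radius)
        candidates.append(Candidate(scan_id=scan_id, center_world=center))

    data = vol.data
    # bright structures inside the body: vessels, wall, mimics
    bright = np.argwhere((data > -500.0) & (data < 300.0))
    anywhere = np.argwhere(data > -990.0)  # exclude outside-body air
    n_fill = n_per_scan - len(candidates)
    for _ in range(n_fill):
        pool = bright if (len(bright) and rng.uniform() < 0.7) else anywhere
        k, j, i = pool[rng.integers(len(pool))]
        jitter = rng.uniform(-0.5, 0.5, size=3)
        center = voxel_to_world(vol, (k + jitter[0], j + jitter[1], i + jitter[2]))
        candidates.append(Candidate(scan_id=scan_id, center_world=center))

    for cand in candidates:
        cand.label = NEGATIVE
        for ann in truth:
            if math.dist(cand.center_world, ann.center_world) <= ann.diameter_mm / 2:
                cand.label = POSITIVE
                break
    return candidates


# ---------------------------------------------------------------------------
# layout catalogues


def phantom_nodule_catalogue() -> List[Tuple[str, float, float]]:
    """The 48-nodule phantom inventory: 4 shapes × 4 diameters × 3 densities.

    Returns (shape_family, diameter_mm, density_hu) triples.
    """
    return [
        (shape, d, rho)
        for rho in PHANTOM_DENSITIES_HU
        for shape in SHAPE_FAMILIES
        for d in CATALOGUE_DIAMETERS_MM
    ]


def random_layout(
    scan_id: str,
    seed: int,
    n_nodules: int = 3,
    grid: Tuple[int, int, int] = DEFAULT_GRID,
    spacing: Tuple[float, float, float] = DEFAULT_SPACING,
    catalogue_offset: int = 0,
    noise_hu: float = 12.0,
) -> ScanLayout:
    """Draw a valid phantom layout whose nodules fit inside the lung region.

    Nodule identities cycle through the phantom catalogue starting at
    ``catalogue_offset``; positions are rejection-sampled for non-overlap.
    """
    rng = np.random.default_rng(seed)
    cat = phantom_nodule_catalogue()
    nz, ny, nx = grid
    sz, sy, sx = spacing
    # lung interior bounds in world mm (origin at voxel (0,0,0))
    nodules: List[NoduleSpec] = []
    idx = catalogue_offset
    attempts = 0
    while len(nodules) < n_nodules and attempts < 500:
        attempts += 1
        shape, diameter, density = cat[idx % len(cat)]
        cap = 0.3 * min(nz * sz, ny * sy, nx * sx)
        if diameter > cap:
            # the biggest inventory nodules may not fit a desk-scale grid;
            # shrink them to the largest diameter that does
            diameter = cap
        if diameter < max(spacing):
            diameter = max(spacing) * 1.5  # keep the nodule resolvable
        margin = 0.8 * diameter
        x = rng.uniform(0.25 * nx * sx + margin / 2, 0.75 * nx * sx - margin / 2)
        y = rng.uniform(0.25 * ny * sy + margin / 2, 0.75 * ny * sy - margin / 2)
        z = rng.uniform(margin, (nz - 1) * sz - margin)
        spec = NoduleSpec(shape, diameter, density, (x, y, z))
        try:
            _check_no_overlap(nodules + [spec])
        except LayoutError:
            continue
        nodules.append(spec)
        idx += 1
    return ScanLayout(scan_id=scan_id, nodules=nodules, noise_hu=noise_hu, seed=seed)


def default_phantom_layouts(
    n_scans: int = 569,
    seed: int = 0,
    n_nodules: int = 3,
    grid: Tuple[int, int, int] = DEFAULT_GRID,
    spacing: Tuple[float, float, float] = DEFAULT_SPACING,
) -> List[ScanLayout]:
    """The default phantom dataset: ``n_scans`` layouts cycling the catalogue.

    The scan count defaults to the 569 layouts of the physical acquisition
    campaign; grids are desk scale (full-size grids reachable by arguments).
    """
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_scans)
    return [
        random_layout(
            scan_id=f"phantom-{i:04d}",
            seed=int(seeds[i]),
            n_nodules=n_nodules,
            grid=grid,
            spacing=spacing,
            catalogue_offset=i * n_nodules,
        )
        for i in range(n_scans)
    ]
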