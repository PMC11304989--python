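"""Volume / table data model, standard-format I/O and coordinate transforms.

Conventions used throughout the package:

* Voxel arrays are indexed ``(z, y, x)`` (slice, row, column); ``spacing``
  follows the same order in mm per voxel.
* World coordinates are ``(x, y, z)`` in mm, matching the candidate-CSV
  dialect (``seriesuid, coordX, coordY, coordZ``), with the origin being the
  world position of voxel ``(0, 0, 0)``.
* Voxel indices are 0-based, continuous indices are not rounded; region
  extents are half-open.
* Direction cosines are assumed identity; files carrying a non-identity
  direction matrix are rejected.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "Volume",
    "Candidate",
    "AnnotationRecord",
    "VolumeFormatError",
    "SchemaError",
    "read_volume",
    "write_volume",
    "world_to_voxel",
    "voxel_to_world",
    "read_candidates",
    "write_candidates",
    "read_annotations",
    "write_annotations",
]

#: recognised candidate labels
POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"

_VOLUME_SUFFIXES = (".mhd", ".mha", ".nii", ".nii.gz")


class VolumeFormatError(ValueError):
    """Raised when a volume file cannot be read or violates our conventions."""


class SchemaError(ValueError):
    """Raised when a CSV table lacks a mandatory column."""


@dataclass
class Volume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    data:
        ``(z, y, x)`` array, HU-valued or normalized.
    spacing:
        mm per voxel along ``(z, y, x)``; strictly positive.
    origin:
        world position (``x, y, z`` mm) of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume grid must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def extent_mm(self) -> Tuple[float, float, float]:
        """Physical size (z, y, x) of the grid in mm."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))


@dataclass
class Candidate:
    """A proposed detection: scan id, world center, optional score and label."""

    scan_id: str
    center_world: Tuple[float, float, float]  # (x, y, z) mm
    score: Optional[float] = None
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        self.center_world = tuple(float(c) for c in self.center_world)
        if self.score is not None:
            self.score = float(self.score)
            if not 0.0 <= self.score <= 1.0:
                raise ValueError(f"candidate score must lie in [0, 1], got {self.score}")
        if self.label not in (POSITIVE, NEGATIVE, UNKNOWN):
            raise ValueError(f"unknown candidate label {self.label!r}")


@dataclass
class AnnotationRecord:
    """A reference-standard nodule: scan id, world center and diameter."""

    scan_id: str
    center_world: Tuple[float, float, float]  # (x, y, z) mm
    diameter_mm: float
    #: number of readers agreeing on the finding (simulator supplies it;
    #: real tables may omit the column, in which case full agreement is assumed)
    agreement: int = 4

    def __post_init__(self) -> None:
        self.center_world = tuple(float(c) for c in self.center_world)
        self.diameter_mm = float(self.diameter_mm)
        if self.diameter_mm <= 0:
            raise ValueError(f"diameter_mm must be positive, got {self.diameter_mm}")


# ---------------------------------------------------------------------------
# volume I/O


def _check_direction(img: sitk.Image, path: os.PathLike) -> None:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise VolumeFormatError(
            f"{path}: non-identity direction matrix is not supported "
            f"(got {direction.tolist()})"
        )


def read_volume(path: os.PathLike | str) -> Volume:
    """Read a MetaImage (.mhd/.raw) or NIfTI (.nii/.nii.gz) volume.

    The returned array is ordered ``(z, y, x)``; spacing and origin come from
    the file header.  Unreadable files raise :class:`VolumeFormatError`.
    """
    path = os.fspath(path)
    if not str(path).endswith(_VOLUME_SUFFIXES):
        raise VolumeFormatError(
            f"{path}: unsupported volume format (expected one of {_VOLUME_SUFFIXES})"
        )
    if not os.path.exists(path):
        raise VolumeFormatError(f"{path}: file not found")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # SimpleITK wraps header/payload problems here
        raise VolumeFormatError(f"{path}: cannot read volume ({exc})") from exc
    _check_direction(img, path)
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    sx, sy, sz = img.GetSpacing()  # SimpleITK orders (x, y, z)
    ox, oy, oz = img.GetOrigin()
    return Volume(data=data, spacing=(sz, sy, sx), origin=(ox, oy, oz))


def write_volume(vol: Volume, path: os.PathLike | str) -> None:
    """Write a volume readable back by :func:`read_volume` with identical content.

    Float data is stored as 32-bit float without clipping; integer data keeps
    its dtype.  Spacing and origin are preserved at full float precision.
    """
    path = os.fspath(path)
    data = vol.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32, copy=False)
    img = sitk.GetImageFromArray(data)
    sz, sy, sx = vol.spacing
    img.SetSpacing((sx, sy, sz))
    ox, oy, oz = vol.origin
    img.SetOrigin((ox, oy, oz))
    try:
        sitk.WriteImage(img, path)
    except RuntimeError as exc:
        raise IOError(f"{path}: cannot write volume ({exc})") from exc


# ---------------------------------------------------------------------------
# coordinate transforms


def world_to_voxel(
    vol: Volume, p_world: Sequence[float]
) -> Tuple[float, float, float]:
    """Map a world point (x, y, z) mm to a continuous voxel index (k, j, i).

    ``index = (world − origin) / spacing`` per axis, without rounding.
    Out-of-grid indices are legal outputs; callers decide how to handle them.
    """
    x, y, z = (float(c) for c in p_world)
    ox, oy, oz = vol.origin
    sz, sy, sx = vol.spacing
    return ((z - oz) / sz, (y - oy) / sy, (x - ox) / sx)


def voxel_to_world(
    vol: Volume, idx: Sequence[float]
) -> Tuple[float, float, float]:
    """Map a continuous voxel index (k, j, i) to a world point (x, y, z) mm."""
    k, j, i = (float(c) for c in idx)
    ox, oy, oz = vol.origin
    sz, sy, sx = vol.spacing
    return (ox + i * sx, oy + j * sy, oz + k * sz)


# ---------------------------------------------------------------------------
# candidate / annotation tables (LUNA16 CSV dialect)

_COORD_COLS = ["coordX", "coordY", "coordZ"]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    for col in cols:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")


def read_candidates(path: os.PathLike | str) -> List[Candidate]:
    """Read a candidate CSV (``seriesuid,coordX,coordY,coordZ[,class][,probability]``).

    A ``class`` column of {0, 1} maps to labels {negative, positive}; rows
    without it are labeled unknown.  Row order is preserved.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["seriesuid", *_COORD_COLS], path)
    has_class = "class" in df.columns
    has_score = "probability" in df.columns
    out: List[Candidate] = []
    for row in df.to_dict("records"):  # 'class' is a keyword; avoid itertuples renaming
        label = UNKNOWN
        if has_class and not pd.isna(row["class"]):
            label = POSITIVE if int(row["class"]) == 1 else NEGATIVE
        score = None
        if has_score and not pd.isna(row["probability"]):
            score = float(row["probability"])
        out.append(
            Candidate(
                scan_id=str(row["seriesuid"]),
                center_world=(row["coordX"], row["coordY"], row["coordZ"]),
                score=score,
                label=label,
            )
        )
    return out


def write_candidates(candidates: Sequence[Candidate], path: os.PathLike | str) -> None:
    """Write candidates in the CSV dialect of :func:`read_candidates`.

    The ``class`` column is written when any candidate carries a label, the
    ``probability`` column when any carries a score.
    """
    rows = []
    any_label = any(c.label != UNKNOWN for c in candidates)
    any_score = any(c.score is not None for c in candidates)
    for c in candidates:
        row = {
            "seriesuid": c.scan_id,
            "coordX": c.center_world[0],
            "coordY": c.center_world[1],
            "coordZ": c.center_world[2],
        }
        if any_label:
            row["class"] = {POSITIVE: 1, NEGATIVE: 0, UNKNOWN: ""}[c.label]
        if any_score:
            row["probability"] = "" if c.score is None else c.score
        rows.append(row)
    cols = ["seriesuid", *_COORD_COLS] + (["class"] if any_label else []) + (
        ["probability"] if any_score else []
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_annotations(path: os.PathLike | str) -> List[AnnotationRecord]:
    """Read an annotation CSV (``seriesuid,coordX,coordY,coordZ,diameter_mm[,agreement]``)."""
    df = pd.read_csv(path)
    _require_columns(df, ["seriesuid", *_COORD_COLS, "diameter_mm"], path)
    has_agreement = "agreement" in df.columns
    out: List[AnnotationRecord] = []
    for row in df.itertuples(index=False):
        out.append(
            AnnotationRecord(
                scan_id=str(row.seriesuid),
                center_world=(row.coordX, row.coordY, row.coordZ),
                diameter_mm=row.diameter_mm,
                agreement=int(row.agreement) if has_agreement else 4,
            )
        )
    return out


def write_annotations(
    annotations: Sequence[AnnotationRecord], path: os.PathLike | str
) -> None:
    rows = [
        {
            "seriesuid": a.scan_id,
            "coordX": a.center_world[0],
            "coordY": a.center_world[1],
            "coordZ": a.center_world[2],
            "diameter_mm": a.diameter_mm,
            "agreement": a.agreement,
        }
        for a in annotations
    ]
    pd.DataFrame(
        rows, columns=["seriesuid", *_COORD_COLS, "diameter_mm", "agreement"]
    ).to_csv(path, index=False)
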