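"""Core imaging types and exact voxel geometry.

All geometry is expressed in physical millimetres.  A voxel at index
``(i, j, k)`` has its *center* at ``origin + (i, j, k) * spacing``; shape
membership is decided by whether that center lies inside the shape.  This
voxel-center convention mirrors how clinical workstations rasterize masks
and makes the geometry exactly reproducible by a brute-force per-voxel test.

Volumes are reported in mL (1 mL = 1 cm^3 = 1000 mm^3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ScalarImage",
    "LabelMap",
    "EllipsoidVOI",
    "CubeROI",
    "GeometryError",
    "PairingError",
    "voxels_in_shape",
    "volume_of",
    "read_image",
    "write_image",
    "read_labelmap",
    "write_labelmap",
    "check_paired",
    "shape_from_dict",
    "shape_to_dict",
]


class GeometryError(ValueError):
    """A shape/grid combination selects no voxels or is otherwise degenerate."""


class PairingError(ValueError):
    """An image and label map do not live on the same voxel grid."""


def _as_triple(x, name: str) -> tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"{name} must have 3 components, got {arr.size}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class ScalarImage:
    """A 3D grid of SUV values with physical voxel spacing.

    SUV (standardized uptake value) is dimensionless, so ``values`` carries
    no unit; ``spacing`` and ``origin`` are in mm.  Values must be finite
    and non-negative (SUV is a normalized activity concentration).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValueError(f"image must be 3D with positive extents, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image contains non-finite SUV values")
        if values.min() < 0:
            raise ValueError("image contains negative SUV values")
        spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", _as_triple(self.origin, "origin"))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


@dataclass(frozen=True)
class LabelMap:
    """Integer labels on the same grid as a paired :class:`ScalarImage`.

    ``legend`` maps each nonzero label to its role (lesion id or a reserved
    reference-tissue code); label 0 is background and needs no entry.
    """

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype {labels.dtype}")
        if labels.ndim != 3:
            raise ValueError(f"label map must be 3D, got shape {labels.shape}")
        legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} present in map but absent from legend")
        spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {spacing}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "legend", legend)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", _as_triple(self.origin, "origin"))

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class CubeROI:
    """Axis-aligned cubic region, e.g. the 10x10x10 mm reference-tissue ROI."""

    center: tuple[float, float, float]
    side: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _as_triple(self.center, "center"))
        if self.side <= 0:
            raise ValueError(f"cube side must be positive, got {self.side}")
        object.__setattr__(self, "side", float(self.side))


@dataclass(frozen=True)
class EllipsoidVOI:
    """Axis-aligned ellipsoid volume of interest, with optional exclusions.

    Exclusion shapes (ellipsoids or cubes) model the removal of adjacent
    physiologically avid structures, e.g. the pituitary gland, from the VOI.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    exclusions: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _as_triple(self.center, "center"))
        semi = _as_triple(self.semi_axes, "semi_axes")
        if any(a <= 0 for a in semi):
            raise ValueError(f"semi-axes must be positive, got {semi}")
        object.__setattr__(self, "semi_axes", semi)
        object.__setattr__(self, "exclusions", tuple(self.exclusions))


def _inclusion_mask(shape, image: ScalarImage) -> np.ndarray:
    xs = [image.axis_coords(ax) for ax in range(3)]
    grids = np.ix_(xs[0], xs[1], xs[2])
    if isinstance(shape, CubeROI):
        half = shape.side / 2.0
        mask = np.ones(image.shape, dtype=bool)
        for ax in range(3):
            mask &= np.abs(grids[ax] - shape.center[ax]) <= half
        return mask
    if isinstance(shape, EllipsoidVOI):
        q = np.zeros(image.shape, dtype=np.float64)
        for ax in range(3):
            q = q + ((grids[ax] - shape.center[ax]) / shape.semi_axes[ax]) ** 2
        return q <= 1.0
    raise TypeError(f"unsupported shape type {type(shape).__name__}")


def voxels_in_shape(shape, image: ScalarImage) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside ``shape``.

    Membership is inclusive at the boundary (ellipsoid: sum((x-c)/a)^2 <= 1;
    cube: |x-c| <= side/2 per axis).  For an :class:`EllipsoidVOI`, exclusion
    shapes are rasterized the same way and removed after inclusion.

    Raises
    ------
    GeometryError
        If the shape selects no voxel centers, before or after exclusion.
    """
    mask = _inclusion_mask(shape, image)
    if not mask.any():
        raise GeometryError(f"{type(shape).__name__} at {shape.center} selects no voxel centers")
    if isinstance(shape, EllipsoidVOI):
        for excl in shape.exclusions:
            mask &= ~_inclusion_mask(excl, image)
        if not mask.any():
            raise GeometryError(
                f"EllipsoidVOI at {shape.center} is empty after applying "
                f"{len(shape.exclusions)} exclusion shape(s)"
            )
    return mask


def volume_of(mask: np.ndarray, spacing) -> float:
    """Volume in mL of a boolean voxel mask: count * voxel volume / 1000."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError(f"mask must be boolean, got dtype {mask.dtype}")
    spacing = _as_triple(spacing, "spacing")
    return float(np.count_nonzero(mask)) * spacing[0] * spacing[1] * spacing[2] / 1000.0


# ---------------------------------------------------------------------------
# NIfTI-1 I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_image(path, image: ScalarImage) -> None:
    """Write a ScalarImage to a NIfTI-1 file (.nii or .nii.gz), float64."""
    nii = nib.Nifti1Image(image.values.astype(np.float64), _affine(image.spacing, image.origin))
    nii.header.set_data_dtype(np.float64)
    nib.save(nii, str(path))


def read_image(path) -> ScalarImage:
    """Read a ScalarImage from a NIfTI-1 file; spacing comes from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    nii = nib.load(str(path))
    values = np.asarray(nii.dataobj, dtype=np.float64)
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {values.ndim} axes")
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    origin = tuple(float(t) for t in nii.affine[:3, 3])
    return ScalarImage(values=values, spacing=spacing, origin=origin)


def _legend_path(path) -> Path:
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + "_legend.json")
    return path.with_name(name + "_legend.json")


def write_labelmap(path, labelmap: LabelMap) -> None:
    """Write a LabelMap as int32 NIfTI plus a JSON legend sidecar."""
    nii = nib.Nifti1Image(
        labelmap.labels.astype(np.int32), _affine(labelmap.spacing, labelmap.origin)
    )
    nii.header.set_data_dtype(np.int32)
    nib.save(nii, str(path))
    _legend_path(path).write_text(
        json.dumps({str(k): v for k, v in labelmap.legend.items()}, indent=2)
    )


def read_labelmap(path) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such label map file: {path}")
    nii = nib.load(str(path))
    labels = np.asarray(nii.dataobj).astype(np.int64)
    legend_file = _legend_path(path)
    legend: dict[int, str] = {}
    if legend_file.exists():
        legend = {int(k): v for k, v in json.loads(legend_file.read_text()).items()}
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:3])
    origin = tuple(float(t) for t in nii.affine[:3, 3])
    return LabelMap(labels=labels, legend=legend, spacing=spacing, origin=origin)


def check_paired(image: ScalarImage, labelmap: LabelMap) -> None:
    """Raise PairingError unless image and label map share grid shape and spacing."""
    if image.shape != labelmap.labels.shape:
        raise PairingError(
            f"image shape {image.shape} != label map shape {labelmap.labels.shape}"
        )
    if not np.allclose(image.spacing, labelmap.spacing, atol=1e-6):
        raise PairingError(
            f"image spacing {image.spacing} != label map spacing {labelmap.spacing}"
        )


# ---------------------------------------------------------------------------
# JSON shape (de)serialization


def shape_to_dict(shape) -> dict:
    if isinstance(shape, CubeROI):
        return {"type": "cube", "center": list(shape.center), "side": shape.side}
    if isinstance(shape, EllipsoidVOI):
        return {
            "type": "ellipsoid",
            "center": list(shape.center),
            "semi_axes": list(shape.semi_axes),
            "exclusions": [shape_to_dict(e) for e in shape.exclusions],
        }
    raise TypeError(f"unsupported shape type {type(shape).__name__}")


def shape_from_dict(d: dict):
    kind = d.get("type")
    if kind == "cube":
        return CubeROI(center=tuple(d["center"]), side=float(d.get("side", 10.0)))
    if kind == "ellipsoid":
        return EllipsoidVOI(
            center=tuple(d["center"]),
            semi_axes=tuple(d["semi_axes"]),
            exclusions=tuple(shape_from_dict(e) for e in d.get("exclusions", ())),
        )
    raise ValueError(f"unknown shape type {kind!r}")
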