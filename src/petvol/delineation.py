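"""Threshold resolution and lesion segmentation.

Four threshold families are supported:

* ``fixed``              — an absolute SUV cutoff (e.g. SUV 4.0);
* ``isocontour``         — a percentage of the lesion's SUVmax;
* ``ref_multiplicative`` — a percentage of a reference tissue's SUVmean
                           (e.g. 150% of bone-marrow SUVmean);
* ``ref_subtractive``    — the reference SUVmean "minus X%", i.e.
                           (1 - X/100) * SUVmean (e.g. pituitary minus 70%
                           -> 0.30 * SUVmean).

Segmentation keeps every VOI voxel with SUV >= the resolved threshold
(inclusive; ties have measure zero after blur/noise) and reports the volume
by voxel counting.  No connected-component filtering is applied by default;
an optional largest-component mode emulates the visual removal of
disconnected off-target uptake.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import label as cc_label

from .imaging import CubeROI, EllipsoidVOI, ScalarImage, volume_of, voxels_in_shape
from .phantom import TISSUES, TruthManifest

__all__ = [
    "FAMILIES",
    "ThresholdSpec",
    "ReferenceStats",
    "DelineationResult",
    "roi_stats",
    "lesion_suvmax",
    "resolve_threshold",
    "delineate",
    "run_battery",
    "voi_for_lesion",
    "default_battery",
    "load_battery",
    "save_battery",
]

FAMILIES = ("fixed", "isocontour", "ref_multiplicative", "ref_subtractive")

_TISSUE_ABBR = {"bone_marrow": "BM", "parotid": "parotis", "pituitary": "sella"}


@dataclass(frozen=True)
class ThresholdSpec:
    """One delineation rule: family, value, and (for ref_*) a reference tissue.

    ``value`` is an absolute SUV for the ``fixed`` family and a percentage
    for the other three.
    """

    family: str
    value: float
    ref_tissue: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown threshold family {self.family!r}")
        if self.value <= 0:
            raise ValueError(f"threshold value must be positive, got {self.value}")
        if self.family == "isocontour" and self.value > 100:
            raise ValueError("isocontour percentage must be <= 100")
        if self.family == "ref_subtractive" and self.value >= 100:
            raise ValueError("subtractive percentage must be < 100")
        if self.family.startswith("ref_"):
            if self.ref_tissue not in TISSUES:
                raise ValueError(
                    f"{self.family} requires ref_tissue in {TISSUES}, got {self.ref_tissue!r}"
                )
        elif self.ref_tissue is not None:
            raise ValueError(f"{self.family} takes no reference tissue")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.family == "fixed":
            return f"SUV {self.value:g}"
        if self.family == "isocontour":
            return f"Iso {self.value:g}"
        abbr = _TISSUE_ABBR[self.ref_tissue]
        if self.family == "ref_multiplicative":
            return f"{self.value:g}% SUV_{abbr}"
        return f"SUV_{abbr} minus {self.value:g}%"

    def to_dict(self) -> dict:
        d = {"family": self.family, "value": self.value, "label": self.label}
        if self.ref_tissue is not None:
            d["ref_tissue"] = self.ref_tissue
        return d


@dataclass(frozen=True)
class ReferenceStats:
    """SUV statistics of one reference-tissue ROI."""

    tissue: str
    suv_mean: float
    suv_max: float
    roi: CubeROI

    def __post_init__(self) -> None:
        # tolerance absorbs summation rounding on uniform regions
        tol = 1e-9 * max(1.0, abs(self.suv_max))
        if not (self.suv_max >= self.suv_mean - tol and self.suv_mean > 0):
            raise ValueError(
                f"require suv_max >= suv_mean > 0, got mean={self.suv_mean}, max={self.suv_max}"
            )


@dataclass(frozen=True)
class DelineationResult:
    label: str
    absolute_threshold_suv: float
    mask: np.ndarray
    volume_mL: float
    lesion_suv_max: float | None = None


def roi_stats(image: ScalarImage, roi: CubeROI, tissue: str) -> ReferenceStats:
    """SUVmean and SUVmax over the voxels of a cubic reference ROI."""
    mask = voxels_in_shape(roi, image)
    vals = image.values[mask]
    return ReferenceStats(
        tissue=tissue, suv_mean=float(vals.mean()), suv_max=float(vals.max()), roi=roi
    )


def lesion_suvmax(image: ScalarImage, voi: EllipsoidVOI) -> float:
    """Maximum SUV over the VOI voxels (after exclusions)."""
    mask = voxels_in_shape(voi, image)
    return float(image.values[mask].max())


def resolve_threshold(
    spec: ThresholdSpec,
    refs: dict[str, ReferenceStats] | None = None,
    lesion_suv_max: float | None = None,
) -> float:
    """Turn a threshold rule into an absolute SUV cutoff."""
    if spec.family == "fixed":
        resolved = spec.value
    elif spec.family == "isocontour":
        if lesion_suv_max is None:
            raise ValueError(f"{spec.label}: isocontour threshold requires lesion SUVmax")
        resolved = spec.value / 100.0 * lesion_suv_max
    else:
        if not refs or spec.ref_tissue not in refs:
            raise ValueError(f"{spec.label}: missing reference stats for {spec.ref_tissue!r}")
        mean = refs[spec.ref_tissue].suv_mean
        if spec.family == "ref_multiplicative":
            resolved = spec.value / 100.0 * mean
        else:  # ref_subtractive: "SUVmean minus X%"
            resolved = (1.0 - spec.value / 100.0) * mean
    if resolved <= 0:
        raise ValueError(f"{spec.label}: resolved threshold {resolved} is not positive")
    return float(resolved)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = cc_label(mask, structure=structure)
    if n <= 1:
        return mask
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    return labeled == int(sizes.argmax())


def delineate(
    image: ScalarImage,
    voi: EllipsoidVOI,
    threshold_suv: float,
    largest_component_only: bool = False,
) -> DelineationResult:
    """Segment the VOI at an absolute SUV threshold (inclusive >=).

    An empty suprathreshold set is a valid 0 mL result, not an error.
    """
    voi_mask = voxels_in_shape(voi, image)
    mask = voi_mask & (image.values >= threshold_suv)
    if largest_component_only and mask.any():
        mask = _largest_component(mask)
    return DelineationResult(
        label=f"SUV>={threshold_suv:g}",
        absolute_threshold_suv=float(threshold_suv),
        mask=mask,
        volume_mL=volume_of(mask, image.spacing),
        lesion_suv_max=float(image.values[voi_mask].max()),
    )


def voi_for_lesion(lesion, margin_mm: float = 10.0) -> EllipsoidVOI:
    """Ellipsoid VOI surrounding a manifest lesion with a physical margin."""
    return EllipsoidVOI(
        center=lesion.center_mm,
        semi_axes=tuple(a + margin_mm for a in lesion.semi_axes_mm),
    )


def reference_stats_from_manifest(
    image: ScalarImage, manifest: TruthManifest
) -> dict[str, ReferenceStats]:
    return {
        t.tissue: roi_stats(image, CubeROI(center=t.roi_center_mm, side=10.0), t.tissue)
        for t in manifest.tissues
    }


def run_battery(
    image: ScalarImage,
    labelmap,
    manifest: TruthManifest,
    battery: list[ThresholdSpec],
    voi_margin_mm: float = 10.0,
    truth: str = "reference",
) -> list[dict]:
    """Apply every threshold rule to every lesion of one scene.

    Returns one row (dict) per lesion: identity columns, the CT-surrogate
    reference volume, lesion SUVmax, per-tissue reference SUVmeans, then one
    volume column per battery label.  ``truth`` selects which manifest volume
    is reported as ``ct_volume_mL``: "reference" (default, the CT surrogate),
    "analytic", or "voxel".
    """
    if truth not in ("reference", "analytic", "voxel"):
        raise ValueError(f"unknown truth selector {truth!r}")
    refs = reference_stats_from_manifest(image, manifest)
    rows = []
    for lesion in manifest.lesions:
        try:
            voi = voi_for_lesion(lesion, voi_margin_mm)
            suvmax = lesion_suvmax(image, voi)
            ct_vol = {
                "reference": lesion.reference_volume_mL,
                "analytic": lesion.true_volume_mL,
                "voxel": lesion.voxel_volume_mL,
            }[truth]
            row = {
                "scene_id": manifest.scene_id,
                "lesion_id": lesion.lesion_id,
                "ct_volume_mL": ct_vol,
                "lesion_suv_max": suvmax,
            }
            for tissue in TISSUES:
                row[f"suvmean_{tissue}"] = refs[tissue].suv_mean
            for spec in battery:
                t = resolve_threshold(spec, refs=refs, lesion_suv_max=suvmax)
                row[spec.label] = delineate(image, voi, t).volume_mL
            rows.append(row)
        except Exception as exc:
            raise RuntimeError(
                f"battery failed for lesion {lesion.lesion_id} "
                f"(scene {manifest.scene_id}): {exc}"
            ) from exc
    return rows


# ---------------------------------------------------------------------------
# Default battery: every tabulated threshold rule of the study.


def default_battery() -> list[ThresholdSpec]:
    specs: list[ThresholdSpec] = []
    for v in (2.5, 3.0, 3.5, 3.75, 4.0, 4.5, 5.0, 10.0, 15.0):
        specs.append(ThresholdSpec("fixed", v))
    for v in (10, 15, 20, 25, 30, 35, 40, 45, 50):
        specs.append(ThresholdSpec("isocontour", float(v)))
    for v in (400, 375, 350, 200, 150):
        specs.append(ThresholdSpec("ref_multiplicative", float(v), "bone_marrow"))
    for v in (60, 50, 40, 30, 10):
        specs.append(ThresholdSpec("ref_subtractive", float(v), "bone_marrow"))
    for v in (400, 375, 350, 300, 250, 200, 150):
        specs.append(ThresholdSpec("ref_multiplicative", float(v), "parotid"))
    for v in (80, 70, 60, 40):
        specs.append(ThresholdSpec("ref_subtractive", float(v), "parotid"))
    specs.append(ThresholdSpec("ref_multiplicative", 125.0, "pituitary"))
    for v in (80, 70, 60, 50, 40, 35, 30):
        specs.append(ThresholdSpec("ref_subtractive", float(v), "pituitary"))
    return specs


def save_battery(path, battery: list[ThresholdSpec]) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in battery], indent=2))


def load_battery(path) -> list[ThresholdSpec]:
    raw = json.loads(Path(path).read_text())
    return [
        ThresholdSpec(
            family=d["family"],
            value=float(d["value"]),
            ref_tissue=d.get("ref_tissue"),
            label=d.get("label", ""),
        )
        for d in raw
    ]
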