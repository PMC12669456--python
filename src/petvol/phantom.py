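"""Synthetic SUV phantom cohorts for delineation benchmarking.

Each scene emulates one cranial somatostatin-receptor PET acquisition:
an ellipsoidal lesion at a uniform plateau SUV on a uniform background,
plus one cubic region per reference tissue (bone marrow, parotid gland,
pituitary gland) at an independently sampled SUVmean.  The scene is then
blurred with a Gaussian point-spread function to emulate finite scanner
resolution (the source of partial-volume effects) and optionally degraded
with additive Gaussian noise truncated at zero.

The label map marks the *pre-blur* shapes, so it plays the role of the
morphological ground truth that a contrast-enhanced CT contour provides in
a clinical study.  The truth manifest records, per lesion, both the analytic
ellipsoid volume (4/3*pi*a*b*c) and the voxelized label-map volume; the
latter is the volume that is exactly attainable on the discrete grid.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import (
    CubeROI,
    EllipsoidVOI,
    LabelMap,
    ScalarImage,
    volume_of,
    voxels_in_shape,
    write_image,
    write_labelmap,
)

__all__ = [
    "TISSUES",
    "TISSUE_LABELS",
    "PhantomConfig",
    "LesionTruth",
    "TissueTruth",
    "TruthManifest",
    "Scene",
    "PhantomError",
    "generate_cohort",
    "apply_psf",
    "sample_tissue_suv",
    "save_cohort",
]

TISSUES = ("bone_marrow", "parotid", "pituitary")

# Reserved label codes; lesions occupy 1..k.
TISSUE_LABELS = {"bone_marrow": 100, "parotid": 101, "pituitary": 102}

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_PLACEMENT_RETRIES = 100


class PhantomError(RuntimeError):
    """Raised when a scene cannot be assembled (e.g. placement failure)."""


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level generator settings.

    Defaults reproduce the study conditions: 19 lesions with reference
    volumes log-uniform on 1.1-6.1 mL (the observed cohort range, all
    >= 1 mL), reference-tissue SUVmean uniform over the observed ranges
    (bone marrow 0.67-1.89, parotid 0.63-2.09, pituitary 5.86-15.23),
    sampled independently per scene, a 5 mm FWHM point-spread function,
    and noiseless voxels.  Spacing is a typical clinical PET grid.
    """

    n_lesions: int = 19
    volume_range_mL: tuple[float, float] = (1.1, 6.1)
    lesion_plateau_suv_range: tuple[float, float] = (6.0, 20.0)
    background_suv: float = 0.5
    tissue_suv_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "bone_marrow": (0.67, 1.89),
            "parotid": (0.63, 2.09),
            "pituitary": (5.86, 15.23),
        }
    )
    psf_fwhm_mm: float = 5.0
    noise_sd_suv: float = 0.0
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    lesions_per_scene: int = 1
    # Std of an optional multiplicative error on the reference volume handed
    # downstream, emulating manual-contouring variability (0 = analytic truth).
    reference_volume_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        lo, hi = self.volume_range_mL
        if lo < 1.0:
            raise ValueError("minimum lesion volume must be >= 1 mL (cohort inclusion rule)")
        if not (lo <= hi):
            raise ValueError(f"volume range must be ordered, got {self.volume_range_mL}")
        defaults = {
            "bone_marrow": (0.67, 1.89),
            "parotid": (0.63, 2.09),
            "pituitary": (5.86, 15.23),
        }
        merged = {**defaults, **{k: tuple(v) for k, v in self.tissue_suv_ranges.items()}}
        for name, (a, b) in merged.items():
            if name not in TISSUES:
                raise ValueError(f"unknown tissue {name!r}")
            if not (0 < a <= b):
                raise ValueError(f"tissue {name} range must be ordered positive, got {(a, b)}")
        object.__setattr__(self, "tissue_suv_ranges", merged)
        plo, phi = self.lesion_plateau_suv_range
        if not (0 < plo <= phi):
            raise ValueError("plateau SUV range must be ordered positive")
        if self.background_suv < 0:
            raise ValueError("background SUV must be >= 0")
        if self.psf_fwhm_mm < 0:
            raise ValueError("PSF FWHM must be >= 0")
        if self.noise_sd_suv < 0:
            raise ValueError("noise SD must be >= 0")
        if self.lesions_per_scene < 1:
            raise ValueError("lesions_per_scene must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tissue_suv_ranges"] = {k: list(v) for k, v in self.tissue_suv_ranges.items()}
        for key in ("volume_range_mL", "lesion_plateau_suv_range", "spacing_mm", "grid_shape"):
            d[key] = list(d[key])
        return d


@dataclass(frozen=True)
class LesionTruth:
    lesion_id: int
    label: int
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    true_volume_mL: float  # analytic 4/3*pi*a*b*c / 1000
    voxel_volume_mL: float  # label-map voxel count * voxel volume
    reference_volume_mL: float  # value handed downstream as the CT surrogate
    plateau_suv: float


@dataclass(frozen=True)
class TissueTruth:
    tissue: str
    roi_center_mm: tuple[float, float, float]
    true_suvmean: float


@dataclass(frozen=True)
class TruthManifest:
    scene_id: int
    lesions: tuple[LesionTruth, ...]
    tissues: tuple[TissueTruth, ...]
    seed: int
    config: dict

    def to_dict(self) -> dict:
        return {
            "scene_id": self.scene_id,
            "lesions": [dataclasses.asdict(l) for l in self.lesions],
            "tissues": [dataclasses.asdict(t) for t in self.tissues],
            "seed": self.seed,
            "config": self.config,
        }

    @staticmethod
    def from_dict(d: dict) -> "TruthManifest":
        def _tup(x):
            return tuple(float(v) for v in x)

        lesions = tuple(
            LesionTruth(
                lesion_id=int(l["lesion_id"]),
                label=int(l["label"]),
                center_mm=_tup(l["center_mm"]),
                semi_axes_mm=_tup(l["semi_axes_mm"]),
                true_volume_mL=float(l["true_volume_mL"]),
                voxel_volume_mL=float(l["voxel_volume_mL"]),
                reference_volume_mL=float(l["reference_volume_mL"]),
                plateau_suv=float(l["plateau_suv"]),
            )
            for l in d["lesions"]
        )
        tissues = tuple(
            TissueTruth(
                tissue=t["tissue"],
                roi_center_mm=_tup(t["roi_center_mm"]),
                true_suvmean=float(t["true_suvmean"]),
            )
            for t in d["tissues"]
        )
        return TruthManifest(
            scene_id=int(d["scene_id"]),
            lesions=lesions,
            tissues=tissues,
            seed=int(d["seed"]),
            config=dict(d["config"]),
        )


@dataclass(frozen=True)
class Scene:
    image: ScalarImage
    labels: LabelMap
    manifest: TruthManifest


def apply_psf(image: ScalarImage, fwhm_mm: float) -> ScalarImage:
    """Gaussian blur, isotropic in physical space.

    sigma per axis (in voxels) = fwhm / (2*sqrt(2*ln 2)) / spacing_axis.
    Edge handling replicates the boundary voxel, which preserves a constant
    background exactly; structures are kept away from the border by the
    generator so total image mass is conserved.
    """
    if fwhm_mm < 0:
        raise ValueError(f"PSF FWHM must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return image
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in image.spacing]
    blurred = gaussian_filter(image.values, sigma=sigma_vox, mode="nearest")
    return ScalarImage(values=blurred, spacing=image.spacing, origin=image.origin)


def sample_tissue_suv(config: PhantomConfig, tissue: str, rng: np.random.Generator) -> float:
    """Draw one reference-tissue SUVmean, uniform over its configured range.

    Only the median and range of the tissue SUVmean distributions are
    published, so a bounded uniform is the least-assumptive choice; tissues
    are sampled independently, matching the observed absence of cross-tissue
    correlation.
    """
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    lo, hi = config.tissue_suv_ranges[tissue]
    if lo == hi:
        return float(lo)
    return float(rng.uniform(lo, hi))


def _extent_mm(config: PhantomConfig) -> np.ndarray:
    return np.asarray(config.grid_shape, dtype=float) * np.asarray(config.spacing_mm)


def _tissue_roi_centers(config: PhantomConfig) -> dict[str, tuple[float, float, float]]:
    ex = _extent_mm(config)
    fractions = {
        "bone_marrow": (0.16, 0.16, 0.22),
        "parotid": (0.84, 0.16, 0.22),
        "pituitary": (0.16, 0.84, 0.22),
    }
    return {t: tuple(float(f * e) for f, e in zip(fr, ex)) for t, fr in fractions.items()}


def _sample_lesion_geometry(
    config: PhantomConfig, rng: np.random.Generator
) -> tuple[float, tuple[float, float, float]]:
    """Sample (analytic volume mL, semi-axes mm) with mild random anisotropy."""
    lo, hi = config.volume_range_mL
    if lo == hi:
        vol = float(lo)
    else:
        vol = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    r0 = (3.0 * vol * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    ratios = rng.uniform(0.8, 1.25, size=3)
    ratios /= np.prod(ratios) ** (1.0 / 3.0)  # volume-preserving anisotropy
    semi = tuple(float(r0 * f) for f in ratios)
    return vol, semi


def _place_lesion(
    config: PhantomConfig,
    rng: np.random.Generator,
    semi_axes: tuple[float, float, float],
    tissue_centers: dict[str, tuple[float, float, float]],
    placed: list[tuple[tuple[float, float, float], tuple[float, float, float]]],
) -> tuple[float, float, float]:
    ex = _extent_mm(config)
    max_semi = max(semi_axes)
    blur_margin = 4.0 * config.psf_fwhm_mm * FWHM_TO_SIGMA + 2.0
    lo = np.full(3, max_semi + blur_margin)
    hi = ex - max_semi - blur_margin
    if np.any(hi <= lo):
        raise PhantomError(
            f"grid extent {tuple(ex)} mm too small for lesion with semi-axes {semi_axes} mm"
        )
    clearance = 6.0
    for _ in range(_PLACEMENT_RETRIES):
        center = tuple(float(rng.uniform(l, h)) for l, h in zip(lo, hi))
        ok = True
        for tc in tissue_centers.values():
            if max(abs(c - t) for c, t in zip(center, tc)) < max_semi + 5.0 + clearance:
                ok = False
                break
        for pc, ps in placed:
            sep = np.linalg.norm(np.subtract(center, pc))
            if sep < max_semi + max(ps) + clearance:
                ok = False
                break
        if ok:
            return center
    raise PhantomError(
        f"could not place lesion with semi-axes {semi_axes} mm after "
        f"{_PLACEMENT_RETRIES} attempts"
    )


def _build_scene(
    config: PhantomConfig,
    scene_id: int,
    lesion_ids: list[int],
    rng: np.random.Generator,
) -> Scene:
    spacing = tuple(config.spacing_mm)
    tissue_centers = _tissue_roi_centers(config)

    base = ScalarImage(
        values=np.full(config.grid_shape, config.background_suv, dtype=np.float64),
        spacing=spacing,
    )
    values = base.values.copy()
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    legend: dict[int, str] = {}

    tissues = []
    for tissue in TISSUES:
        suv = sample_tissue_suv(config, tissue, rng)
        roi = CubeROI(center=tissue_centers[tissue], side=10.0)
        mask = voxels_in_shape(roi, base)
        values[mask] = suv
        labels[mask] = TISSUE_LABELS[tissue]
        legend[TISSUE_LABELS[tissue]] = tissue
        tissues.append(TissueTruth(tissue=tissue, roi_center_mm=roi.center, true_suvmean=suv))

    lesions = []
    placed: list[tuple[tuple[float, float, float], tuple[float, float, float]]] = []
    for lesion_id in lesion_ids:
        vol, semi = _sample_lesion_geometry(config, rng)
        plateau = float(rng.uniform(*config.lesion_plateau_suv_range))
        center = _place_lesion(config, rng, semi, tissue_centers, placed)
        placed.append((center, semi))
        shape = EllipsoidVOI(center=center, semi_axes=semi)
        mask = voxels_in_shape(shape, base)
        values[mask] = plateau
        label = len(lesions) + 1
        labels[mask] = label
        legend[label] = f"lesion_{lesion_id}"
        voxel_vol = volume_of(mask, spacing)
        ref_vol = vol
        if config.reference_volume_noise_sd > 0:
            ref_vol = float(vol * max(0.05, 1.0 + rng.normal(0.0, config.reference_volume_noise_sd)))
        lesions.append(
            LesionTruth(
                lesion_id=lesion_id,
                label=label,
                center_mm=center,
                semi_axes_mm=semi,
                true_volume_mL=vol,
                voxel_volume_mL=voxel_vol,
                reference_volume_mL=ref_vol,
                plateau_suv=plateau,
            )
        )

    image = ScalarImage(values=values, spacing=spacing)
    image = apply_psf(image, config.psf_fwhm_mm)
    if config.noise_sd_suv > 0:
        noisy = image.values + rng.normal(0.0, config.noise_sd_suv, size=image.shape)
        image = ScalarImage(values=np.clip(noisy, 0.0, None), spacing=spacing)

    manifest = TruthManifest(
        scene_id=scene_id,
        lesions=tuple(lesions),
        tissues=tuple(tissues),
        seed=config.seed,
        config=config.to_dict(),
    )
    labelmap = LabelMap(labels=labels, legend=legend, spacing=spacing)
    return Scene(image=image, labels=labelmap, manifest=manifest)


def generate_cohort(config: PhantomConfig) -> list[Scene]:
    """Generate the full synthetic cohort; identical seed => identical output."""
    rng = np.random.default_rng(config.seed)
    lesion_ids = list(range(1, config.n_lesions + 1))
    scenes = []
    scene_id = 0
    for start in range(0, len(lesion_ids), config.lesions_per_scene):
        chunk = lesion_ids[start : start + config.lesions_per_scene]
        scenes.append(_build_scene(config, scene_id, chunk, rng))
        scene_id += 1
    return scenes


def save_cohort(scenes: list[Scene], out_dir) -> pd.DataFrame:
    """Write scene_k.nii.gz, scene_k_labels.nii.gz, scene_k_manifest.json
    and cohort_index.csv under ``out_dir``; returns the index frame."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for scene in scenes:
        k = scene.manifest.scene_id
        write_image(out / f"scene_{k}.nii.gz", scene.image)
        write_labelmap(out / f"scene_{k}_labels.nii.gz", scene.labels)
        (out / f"scene_{k}_manifest.json").write_text(
            json.dumps(scene.manifest.to_dict(), indent=2)
        )
        for lesion in scene.manifest.lesions:
            rows.append(
                {
                    "scene_id": k,
                    "lesion_id": lesion.lesion_id,
                    "true_volume_mL": lesion.true_volume_mL,
                    "voxel_volume_mL": lesion.voxel_volume_mL,
                    "reference_volume_mL": lesion.reference_volume_mL,
                    "plateau_suv": lesion.plateau_suv,
                }
            )
    index = pd.DataFrame(rows)
    index.to_csv(out / "cohort_index.csv", index=False)
    return index
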