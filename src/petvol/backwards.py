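"""Per-lesion backwards thresholding.

For one lesion, the volume-vs-threshold curve V(t) over its VOI is a
right-continuous, non-increasing step function: the only attainable volumes
are voxel multiples, reached exactly at the observed SUV values.  Backwards
thresholding inverts it — find the absolute SUV whose segmented volume is
closest to the reference volume — by exhaustively evaluating V at every
unique SUV in the VOI.  Ties break toward the larger threshold.  The cohort
of matched thresholds is summarized by mean, sample SD and CoV, and the
mean threshold is reapplied to every lesion to score it as a single fixed
rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agreement import AgreementRow, agreement_row, cov_pct
from .delineation import delineate, voi_for_lesion
from .imaging import EllipsoidVOI, ScalarImage, voxels_in_shape

__all__ = [
    "MatchedThreshold",
    "BackwardsResult",
    "match_threshold",
    "summarize_backwards",
    "run_backwards_cohort",
]


@dataclass(frozen=True)
class MatchedThreshold:
    lesion_id: int | None
    matched_threshold_suv: float
    achieved_volume_mL: float
    target_volume_mL: float
    unattainable: bool  # target exceeds the full VOI volume


def match_threshold(
    image: ScalarImage, voi: EllipsoidVOI, target_mL: float, lesion_id: int | None = None
) -> MatchedThreshold:
    """Find the SUV threshold whose suprathreshold VOI volume is nearest
    ``target_mL``; exact on the step function, ties toward the larger SUV."""
    if target_mL <= 0:
        raise ValueError(f"target volume must be positive, got {target_mL}")
    mask = voxels_in_shape(voi, image)
    vals = np.sort(image.values[mask])
    candidates = np.unique(vals)
    # count of voxels >= t for each candidate t
    counts = vals.size - np.searchsorted(vals, candidates, side="left")
    sx, sy, sz = image.spacing
    # same operation order as volume_of, so reapplication is bit-identical
    volumes = counts.astype(float) * sx * sy * sz / 1000.0
    full = volumes[0]
    if target_mL > full:
        return MatchedThreshold(
            lesion_id=lesion_id,
            matched_threshold_suv=float(candidates[0]),
            achieved_volume_mL=float(full),
            target_volume_mL=float(target_mL),
            unattainable=True,
        )
    err = np.abs(volumes - target_mL)
    # argmin keeps the first minimum; candidates are ascending, so scan the
    # reversed array to prefer the larger threshold on ties
    idx = err.size - 1 - int(np.argmin(err[::-1]))
    return MatchedThreshold(
        lesion_id=lesion_id,
        matched_threshold_suv=float(candidates[idx]),
        achieved_volume_mL=float(volumes[idx]),
        target_volume_mL=float(target_mL),
        unattainable=False,
    )


def summarize_backwards(thresholds) -> tuple[float, float, float]:
    """(mean, sample SD, CoV%) of a cohort of matched thresholds."""
    arr = np.asarray(thresholds, dtype=float).reshape(-1)
    if arr.size < 2:
        raise ValueError(f"summary requires n >= 2 thresholds, got n={arr.size}")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if mean <= 0:
        raise ValueError(f"CoV undefined for non-positive mean threshold {mean}")
    return mean, sd, float(cov_pct(arr))


@dataclass(frozen=True)
class BackwardsResult:
    per_lesion: tuple[MatchedThreshold, ...]
    mean_threshold_suv: float
    sd_threshold_suv: float
    cov_pct: float
    reapplied: AgreementRow  # cohort-mean threshold scored as a fixed rule


def run_backwards_cohort(
    scenes,
    truth: str = "reference",
    voi_margin_mm: float = 10.0,
    alpha: float = 0.05,
    loa_multiplier: float = 1.96,
) -> BackwardsResult:
    """Backwards-threshold every lesion of a cohort and reapply the mean.

    ``truth`` selects the matching target per lesion: "reference" (the CT
    surrogate volume), "analytic" or "voxel" (the label-map volume, the only
    target exactly attainable on the grid).
    """
    if truth not in ("reference", "analytic", "voxel"):
        raise ValueError(f"unknown truth selector {truth!r}")
    matched: list[MatchedThreshold] = []
    lesion_refs: list[tuple] = []  # (scene, lesion, voi, target)
    for scene in scenes:
        for lesion in scene.manifest.lesions:
            target = {
                "reference": lesion.reference_volume_mL,
                "analytic": lesion.true_volume_mL,
                "voxel": lesion.voxel_volume_mL,
            }[truth]
            voi = voi_for_lesion(lesion, voi_margin_mm)
            matched.append(match_threshold(scene.image, voi, target, lesion.lesion_id))
            lesion_refs.append((scene, lesion, voi, target))
    mean, sd, cov = summarize_backwards([m.matched_threshold_suv for m in matched])
    pet = [delineate(s.image, voi, mean).volume_mL for s, _, voi, _ in lesion_refs]
    targets = [t for _, _, _, t in lesion_refs]
    row = agreement_row(
        f"backwards mean SUV {mean:.2f}", pet, targets, alpha=alpha, loa_multiplier=loa_multiplier
    )
    return BackwardsResult(
        per_lesion=tuple(matched),
        mean_threshold_suv=mean,
        sd_threshold_suv=sd,
        cov_pct=cov,
        reapplied=row,
    )
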