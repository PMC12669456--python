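"""End-to-end orchestration: phantom -> delineation -> backwards -> agreement.

``run_all`` produces the full report bundle for one seeded configuration:
per-lesion volume batteries, per-rule agreement statistics, reference-tissue
summaries, the backwards-thresholding summary, and a JSON run manifest
echoing the exact configuration.  Identical configuration and seed give
byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as ag
from .backwards import BackwardsResult, run_backwards_cohort
from .delineation import ThresholdSpec, default_battery, run_battery
from .phantom import TISSUES, PhantomConfig, Scene, generate_cohort, save_cohort

__all__ = ["RunConfig", "RunResult", "run_all", "best_per_family"]


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    battery: tuple[ThresholdSpec, ...] = field(default_factory=lambda: tuple(default_battery()))
    alpha: float = 0.05
    loa_multiplier: float = 1.96
    truth: str = "reference"  # which manifest volume plays the CT reference
    voi_margin_mm: float = 10.0

    def to_dict(self) -> dict:
        return {
            "phantom": self.phantom.to_dict(),
            "battery": [s.to_dict() for s in self.battery],
            "alpha": self.alpha,
            "loa_multiplier": self.loa_multiplier,
            "truth": self.truth,
            "voi_margin_mm": self.voi_margin_mm,
        }


@dataclass
class RunResult:
    scenes: list[Scene]
    volumes: pd.DataFrame
    agreement: pd.DataFrame
    tissues: pd.DataFrame
    tissue_correlations: pd.DataFrame
    backwards: BackwardsResult
    backwards_table: pd.DataFrame
    warnings: list[str]
    manifest: dict


def _tissue_tables(volumes: pd.DataFrame, alpha: float):
    """Per-tissue summary (median, range, CoV) and pairwise correlations,
    computed on the measured ROI SUVmeans (one per scene)."""
    per_scene = volumes.drop_duplicates("scene_id")
    summary_rows = []
    vectors = {}
    for tissue in TISSUES:
        vals = per_scene[f"suvmean_{tissue}"].to_numpy()
        vectors[tissue] = vals
        summary_rows.append(
            {
                "tissue": tissue,
                "suvmean_median": float(np.median(vals)),
                "suvmean_min": float(vals.min()),
                "suvmean_max": float(vals.max()),
                "cov_pct": ag.cov_pct(vals),
                "n": int(vals.size),
            }
        )
    corr = ag.cross_correlate_tissues(vectors, alpha=alpha)
    corr_rows = [
        {
            "tissue_a": a,
            "tissue_b": b,
            "r": res.r,
            "p_value": res.p_value,
            "method": res.method,
        }
        for (a, b), res in corr.items()
    ]
    return pd.DataFrame(summary_rows), pd.DataFrame(corr_rows)


def run_all(config: RunConfig, out_dir=None, write_scenes: bool = False) -> RunResult:
    """Execute the whole analysis; optionally write the report bundle.

    When ``out_dir`` is given, writes cohort_index.csv, volumes.csv,
    agreement.csv, tissues.csv, tissue_correlations.csv, backwards.csv and
    run_manifest.json there (NIfTI scenes only if ``write_scenes``).
    """
    warnings: list[str] = []
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    scenes = generate_cohort(config.phantom)
    timings["phantom_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rows: list[dict] = []
    for scene in scenes:
        rows.extend(
            run_battery(
                scene.image,
                scene.labels,
                scene.manifest,
                list(config.battery),
                voi_margin_mm=config.voi_margin_mm,
                truth=config.truth,
            )
        )
    volumes = pd.DataFrame(rows)
    timings["delineation_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    agreement_rows = []
    ct = volumes["ct_volume_mL"].to_numpy()
    for spec in config.battery:
        pet = volumes[spec.label].to_numpy()
        try:
            row = ag.agreement_row(
                spec.label, pet, ct, alpha=config.alpha, loa_multiplier=config.loa_multiplier
            ).to_dict()
        except ValueError as exc:
            # a degenerate battery row (e.g. zero variance when no lesion
            # reaches the threshold) is reported as NaN, not a run failure
            warnings.append(f"agreement skipped for {spec.label!r}: {exc}")
            row = {
                "label": spec.label,
                "r": float("nan"),
                "r_squared": float("nan"),
                "p_value": float("nan"),
                "method": "none",
                "bias": float(np.mean(pet - ct)),
                "sd_diff": float(np.std(pet - ct, ddof=1)) if pet.size > 1 else float("nan"),
                "loa_low": float("nan"),
                "loa_high": float("nan"),
                "n": int(pet.size),
            }
        row["family"] = spec.family
        agreement_rows.append(row)
    agreement_df = pd.DataFrame(agreement_rows)
    tissues_df, tissue_corr_df = _tissue_tables(volumes, config.alpha)
    timings["agreement_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    bw = run_backwards_cohort(
        scenes,
        truth=config.truth,
        voi_margin_mm=config.voi_margin_mm,
        alpha=config.alpha,
        loa_multiplier=config.loa_multiplier,
    )
    for m in bw.per_lesion:
        if m.unattainable:
            warnings.append(
                f"backwards target {m.target_volume_mL:.3f} mL exceeds VOI volume "
                f"for lesion {m.lesion_id}; minimum threshold used"
            )
    backwards_table = pd.DataFrame(
        [
            {
                "lesion_id": m.lesion_id,
                "matched_threshold_suv": m.matched_threshold_suv,
                "achieved_volume_mL": m.achieved_volume_mL,
                "target_volume_mL": m.target_volume_mL,
                "unattainable": m.unattainable,
            }
            for m in bw.per_lesion
        ]
    )
    timings["backwards_s"] = time.perf_counter() - t0

    manifest = {
        "config": config.to_dict(),
        "seed": config.phantom.seed,
        "n_scenes": len(scenes),
        "n_lesions": int(volumes.shape[0]),
        "backwards": {
            "mean_threshold_suv": bw.mean_threshold_suv,
            "sd_threshold_suv": bw.sd_threshold_suv,
            "cov_pct": bw.cov_pct,
            "reapplied": bw.reapplied.to_dict(),
        },
        "warnings": warnings,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }

    result = RunResult(
        scenes=scenes,
        volumes=volumes,
        agreement=agreement_df,
        tissues=tissues_df,
        tissue_correlations=tissue_corr_df,
        backwards=bw,
        backwards_table=backwards_table,
        warnings=warnings,
        manifest=manifest,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if write_scenes:
            save_cohort(scenes, out / "scenes")
        index_rows = [
            {
                "scene_id": s.manifest.scene_id,
                "lesion_id": l.lesion_id,
                "true_volume_mL": l.true_volume_mL,
                "voxel_volume_mL": l.voxel_volume_mL,
                "reference_volume_mL": l.reference_volume_mL,
                "plateau_suv": l.plateau_suv,
            }
            for s in scenes
            for l in s.manifest.lesions
        ]
        pd.DataFrame(index_rows).to_csv(out / "cohort_index.csv", index=False)
        volumes.to_csv(out / "volumes.csv", index=False)
        agreement_df.to_csv(out / "agreement.csv", index=False)
        tissues_df.to_csv(out / "tissues.csv", index=False)
        tissue_corr_df.to_csv(out / "tissue_correlations.csv", index=False)
        summary = pd.DataFrame(
            [
                {"quantity": "mean_threshold_suv", "value": bw.mean_threshold_suv},
                {"quantity": "sd_threshold_suv", "value": bw.sd_threshold_suv},
                {"quantity": "cov_pct", "value": bw.cov_pct},
                {"quantity": "reapplied_r", "value": bw.reapplied.r},
                {"quantity": "reapplied_r_squared", "value": bw.reapplied.r_squared},
                {"quantity": "reapplied_p_value", "value": bw.reapplied.p_value},
            ]
        )
        pd.concat([backwards_table, summary], axis=0).to_csv(out / "backwards.csv", index=False)
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))

    return result


def best_per_family(agreement_df: pd.DataFrame) -> dict[str, str]:
    """Per threshold family, the label with maximal r (ties: smaller |bias|)."""
    if "family" not in agreement_df.columns:
        raise ValueError("agreement frame lacks a 'family' column")
    out: dict[str, str] = {}
    for family, group in agreement_df.dropna(subset=["r"]).groupby("family"):
        best = group.sort_values(
            ["r", "bias"], key=lambda c: c if c.name == "r" else c.abs(), ascending=[False, True]
        ).iloc[0]
        out[str(family)] = str(best["label"])
    return out
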