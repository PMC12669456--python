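"""Agreement statistics: normality-gated correlation, Bland-Altman, CoV.

The correlation method is chosen by a Shapiro-Wilk gate: Pearson when both
paired samples look normal (p >= alpha for each), Spearman otherwise.
Bland-Altman differences are oriented PET minus reference, so a positive
bias means the PET delineation overestimates the reference volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementRow",
    "CorrelationResult",
    "BlandAltman",
    "normality_p",
    "correlate",
    "bland_altman",
    "cov_pct",
    "cross_correlate_tissues",
    "agreement_row",
    "bland_altman_plot",
    "scatter_plot",
]


def _clean(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def normality_p(x) -> float:
    """Two-sided Shapiro-Wilk p-value; requires 3 <= n <= 5000, non-constant."""
    arr = _clean(x, "sample")
    if not (3 <= arr.size <= 5000):
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={arr.size}")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    return float(stats.shapiro(arr).pvalue)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    method: str  # "pearson" or "spearman"
    n: int


def correlate(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson if both samples pass the normality gate at ``alpha``, else
    Spearman (Pearson on mid-ranks; two-sided t-approximate p)."""
    xa, ya = _clean(x, "x"), _clean(y, "y")
    if xa.size != ya.size:
        raise ValueError(f"paired samples differ in length: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise ValueError(f"correlation requires n >= 3, got n={xa.size}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation is undefined for a zero-variance sample")
    use_pearson = normality_p(xa) >= alpha and normality_p(ya) >= alpha
    if use_pearson:
        res = stats.pearsonr(xa, ya)
        method = "pearson"
    else:
        res = stats.spearmanr(xa, ya)
        method = "spearman"
    r = float(res.statistic if hasattr(res, "statistic") else res.correlation)
    return CorrelationResult(
        r=r, r_squared=r * r, p_value=float(res.pvalue), method=method, n=int(xa.size)
    )


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray
    slope: float  # difference regressed on pair means; proportional-bias diagnostic
    n: int


def bland_altman(pet_mL, ct_mL, loa_multiplier: float = 1.96) -> BlandAltman:
    """Bland-Altman agreement of PET against the reference.

    Differences are PET - reference; bias is their mean, sd the sample SD
    (n-1), limits of agreement bias +/- ``loa_multiplier`` * sd.  The slope
    of the differences regressed on the pair means diagnoses proportional
    bias (overestimation growing with lesion size when positive).
    """
    pet, ct = _clean(pet_mL, "pet"), _clean(ct_mL, "ct")
    if pet.size != ct.size:
        raise ValueError(f"paired samples differ in length: {pet.size} vs {ct.size}")
    if pet.size < 2:
        raise ValueError(f"Bland-Altman requires n >= 2, got n={pet.size}")
    diffs = pet - ct
    means = (pet + ct) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if np.ptp(means) == 0:
        slope = float("nan")
    else:
        slope = float(stats.linregress(means, diffs).slope)
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        means=means,
        diffs=diffs,
        slope=slope,
        n=int(pet.size),
    )


def cov_pct(values) -> float:
    """Coefficient of variation, percent: 100 * sample SD / mean."""
    arr = _clean(values, "values")
    if arr.size < 2:
        raise ValueError(f"CoV requires n >= 2, got n={arr.size}")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError(f"CoV undefined for non-positive mean {mean}")
    return float(100.0 * arr.std(ddof=1) / mean)


def cross_correlate_tissues(tissue_suvmeans: dict, alpha: float = 0.05) -> dict:
    """Pairwise correlation between reference-tissue SUVmean vectors.

    ``tissue_suvmeans`` maps tissue name -> per-scene SUVmean sequence.
    Returns {(tissue_a, tissue_b): CorrelationResult} for each unordered
    pair (a < b); the diagonal is omitted.
    """
    names = sorted(tissue_suvmeans)
    arrays = {t: _clean(tissue_suvmeans[t], t) for t in names}
    n = {t: a.size for t, a in arrays.items()}
    if len(set(n.values())) != 1:
        raise ValueError(f"tissue vectors differ in length: {n}")
    if next(iter(n.values())) < 3:
        raise ValueError("cross-correlation requires >= 3 scenes")
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[(a, b)] = correlate(arrays[a], arrays[b], alpha=alpha)
    return out


@dataclass(frozen=True)
class AgreementRow:
    """One evaluated threshold rule: correlation plus Bland-Altman columns."""

    label: str
    r: float
    r_squared: float
    p_value: float
    method: str
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "r": self.r,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "method": self.method,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
        }


def agreement_row(
    label: str, pet_mL, ct_mL, alpha: float = 0.05, loa_multiplier: float = 1.96
) -> AgreementRow:
    corr = correlate(pet_mL, ct_mL, alpha=alpha)
    ba = bland_altman(pet_mL, ct_mL, loa_multiplier=loa_multiplier)
    return AgreementRow(
        label=label,
        r=corr.r,
        r_squared=corr.r_squared,
        p_value=corr.p_value,
        method=corr.method,
        bias=ba.bias,
        sd_diff=ba.sd_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        n=corr.n,
    )


# ---------------------------------------------------------------------------
# Plotting (optional outputs; headless backend)


def scatter_plot(pet_mL, ct_mL, label: str, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pet, ct = _clean(pet_mL, "pet"), _clean(ct_mL, "ct")
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(ct, pet, s=18, color="tab:blue")
    lim = [0, max(float(pet.max()), float(ct.max())) * 1.05]
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.set_xlabel("reference volume (mL)")
    ax.set_ylabel("PET volume (mL)")
    ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(pet_mL, ct_mL, label: str, path, loa_multiplier: float = 1.96) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(pet_mL, ct_mL, loa_multiplier=loa_multiplier)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(ba.means, ba.diffs, s=18, color="tab:blue")
    ax.axhline(ba.bias, color="red", lw=1.0, label=f"bias {ba.bias:.2f}")
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="green", lw=1.0, ls="--")
    ax.set_xlabel("mean of PET and reference (mL)")
    ax.set_ylabel("PET - reference (mL)")
    ax.set_title(label)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
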