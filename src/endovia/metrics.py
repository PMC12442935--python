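"""Segmentation-agreement and method-comparison statistics.

Everything needed to validate a stained-area segmentation against a
reference: pixel confusion counts over an evaluation region, the standard
overlap metrics (precision, recall, balanced accuracy, Dice, IoU), standard
and modified (Dubuisson–Jain) Hausdorff distances between boundary sets,
continuous agreement of mortality fractions (MAE / RMSE / R²) with
percentile-bootstrap CIs, Bland–Altman limits of agreement, Pearson
correlation, and the rotation-homoscedasticity procedure (per-ring z-scores
and Levene's test across rotations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .raster import BinaryMask
from .rings import outer_boundary

__all__ = [
    "ConfusionCounts",
    "AgreementStats",
    "HausdorffResult",
    "MethodComparison",
    "confusion",
    "overlap_metrics",
    "hausdorff_distances",
    "continuous_agreement",
    "bootstrap_ci",
    "bland_altman",
    "pearson",
    "rotation_homoscedasticity",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts restricted to an evaluation region."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def region_size(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class AgreementStats:
    """Overlap metrics; ``None`` plus an entry in ``undefined`` when a
    denominator vanishes (never a silent 0)."""

    precision: float | None = None
    recall: float | None = None
    balanced_accuracy: float | None = None
    dice: float | None = None
    iou: float | None = None
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "balanced_accuracy": self.balanced_accuracy,
            "dice": self.dice,
            "iou": self.iou,
            "undefined": self.undefined,
        }


def confusion(pred: BinaryMask, truth: BinaryMask, region: BinaryMask) -> ConfusionCounts:
    """Count TP/FP/FN/TN over the pixels of ``region`` only."""
    if pred.shape != truth.shape or pred.shape != region.shape:
        raise ValueError(
            f"mask shapes differ: pred {pred.shape}, truth {truth.shape}, "
            f"region {region.shape}"
        )
    r = region.membership
    p = pred.membership[r]
    t = truth.membership[r]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def overlap_metrics(c: ConfusionCounts) -> AgreementStats:
    """Precision, recall, balanced accuracy, Dice and IoU from counts."""
    if c.region_size == 0:
        raise ValueError("evaluation region is empty")
    out = AgreementStats()

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            out.undefined.append(name)
            return None
        return num / den

    out.precision = ratio(c.tp, c.tp + c.fp, "precision")
    out.recall = ratio(c.tp, c.tp + c.fn, "recall")
    spec = ratio(c.tn, c.tn + c.fp, "specificity")
    if out.recall is not None and spec is not None:
        out.balanced_accuracy = 0.5 * (out.recall + spec)
    else:
        out.undefined.append("balanced_accuracy")
    out.dice = ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "dice")
    out.iou = ratio(c.tp, c.tp + c.fp + c.fn, "iou")
    return out


@dataclass
class HausdorffResult:
    """Standard and modified Hausdorff distances between boundary sets.

    Reported in pixels, normalised by the image diagonal, and in
    millimetres when a physical scale is supplied.
    """

    std_px: float
    mod_px: float
    std_norm: float
    mod_norm: float
    std_mm: float | None = None
    mod_mm: float | None = None

    def to_dict(self) -> dict:
        return {
            "hausdorff_std_px": self.std_px,
            "hausdorff_mod_px": self.mod_px,
            "hausdorff_std_norm": self.std_norm,
            "hausdorff_mod_norm": self.mod_norm,
            "hausdorff_std_mm": self.std_mm,
            "hausdorff_mod_mm": self.mod_mm,
        }


def hausdorff_distances(
    pred: BinaryMask, truth: BinaryMask, mm_per_pixel: float | None = None
) -> HausdorffResult:
    """Hausdorff distances between the outer boundaries of two masks.

    standard = max over both directions of the max nearest-point distance;
    modified (Dubuisson–Jain) = max over both directions of the *mean*
    nearest-point distance.  Raises when either mask is empty (undefined).
    """
    if pred.shape != truth.shape:
        raise ValueError("masks must share dimensions")
    if pred.is_empty() or truth.is_empty():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    a = np.argwhere(outer_boundary(pred))
    b = np.argwhere(outer_boundary(truth))
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    std = float(max(d_ab.max(), d_ba.max()))
    mod = float(max(d_ab.mean(), d_ba.mean()))
    diag = float(np.hypot(*pred.shape))
    return HausdorffResult(
        std_px=std,
        mod_px=mod,
        std_norm=std / diag,
        mod_norm=mod / diag,
        std_mm=std * mm_per_pixel if mm_per_pixel else None,
        mod_mm=mod * mm_per_pixel if mm_per_pixel else None,
    )


def continuous_agreement(pred: np.ndarray, truth: np.ndarray):
    """MAE, RMSE and R² of predicted vs reference fractions.

    R² uses the reference as the baseline (1 − SSres/SStot); it is returned
    as ``None`` when the reference is constant (SStot = 0).
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("pred and truth must be equal-length 1-D vectors of length >= 2")
    d = p - t
    mae = float(np.abs(d).mean())
    rmse = float(np.sqrt((d**2).mean()))
    sstot = float(((t - t.mean()) ** 2).sum())
    r2 = None if sstot == 0 else float(1 - (d**2).sum() / sstot)
    return mae, rmse, r2


def bootstrap_ci(
    samples,
    statistic,
    n_resamples: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of a statistic.

    ``samples`` is a 1-D array, or a tuple of equal-length arrays that are
    resampled jointly (paired bootstrap); ``statistic`` receives the
    resampled array(s) and returns a scalar.
    """
    paired = isinstance(samples, (tuple, list)) and isinstance(
        samples[0], (np.ndarray, list, tuple)
    )
    arrays = [np.asarray(a) for a in samples] if paired else [np.asarray(samples)]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays) or n < 2:
        raise ValueError("need >= 2 samples of equal length")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_resamples)
    for i in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        picked = [a[idx] for a in arrays]
        vals[i] = statistic(*picked) if paired else statistic(picked[0])
    alpha = (1 - level) / 2
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


@dataclass
class MethodComparison:
    """Bland–Altman summary of method B minus method A differences."""

    n: int
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    mean_ci: tuple[float, float]
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]
    pearson_rho: float | None = None
    pearson_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_difference": self.mean_difference,
            "sd_difference": self.sd_difference,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "mean_ci": list(self.mean_ci),
            "loa_low_ci": list(self.loa_low_ci),
            "loa_high_ci": list(self.loa_high_ci),
            "pearson_rho": self.pearson_rho,
            "pearson_p": self.pearson_p,
        }


def bland_altman(method_a, method_b) -> MethodComparison:
    """Bland–Altman analysis of differences d = B − A.

    Limits of agreement are mean ± 1.96·SD (sample SD); CI ribbons use the
    standard formulas SE(mean) = SD/√n and SE(LoA) = SD·√(3/n).
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("method vectors must be equal-length 1-D with n >= 2")
    d = b - a
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = mean - 1.96 * sd
    loa_high = mean + 1.96 * sd
    tcrit = stats.t.ppf(0.975, n - 1)
    se_mean = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    return MethodComparison(
        n=n,
        mean_difference=mean,
        sd_difference=sd,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        mean_ci=(float(mean - tcrit * se_mean), float(mean + tcrit * se_mean)),
        loa_low_ci=(float(loa_low - tcrit * se_loa), float(loa_low + tcrit * se_loa)),
        loa_high_ci=(float(loa_high - tcrit * se_loa), float(loa_high + tcrit * se_loa)),
    )


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def rotation_homoscedasticity(
    table: pd.DataFrame,
    value_col: str = "mortality_pct",
    center: str = "mean",
) -> pd.DataFrame:
    """Per-ring Levene test of mortality variance across image rotations.

    ``table`` is tidy with columns ``tissue_id``, ``rotation_deg``, ``ring``
    and ``value_col``.  For each ring the values are z-scored against the
    grand mean/SD pooled over all rotations and tissues of that ring, then
    Levene's test (classic mean-centered by default; ``center='median'`` for
    Brown–Forsythe) is run across the rotation groups.

    Returns a DataFrame with columns ``ring``, ``levene_W``, ``levene_p``,
    ``n_rotations``, ``n_tissues``.
    """
    required = {"tissue_id", "rotation_deg", "ring", value_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    if table["rotation_deg"].nunique() < 2:
        raise ValueError("need at least 2 rotations")
    if table["tissue_id"].nunique() < 3:
        raise ValueError("need at least 3 tissues")
    rows = []
    for ring, sub in table.groupby("ring"):
        vals = sub[value_col].to_numpy(dtype=float)
        mu, sigma = vals.mean(), vals.std(ddof=1)
        z = (vals - mu) / sigma if sigma > 0 else np.zeros_like(vals)
        sub = sub.assign(_z=z)
        groups = [g["_z"].to_numpy() for _, g in sub.groupby("rotation_deg")]
        spreads = [np.abs(g - (np.mean(g) if center == "mean" else np.median(g))) for g in groups]
        if all(s.max() == 0 for s in spreads if s.size):
            w, p = 0.0, 1.0  # identical values in every group: nothing to test
        else:
            w, p = stats.levene(*groups, center=center)
        rows.append(
            {
                "ring": ring,
                "levene_W": float(w),
                "levene_p": float(p),
                "n_rotations": len(groups),
                "n_tissues": sub["tissue_id"].nunique(),
            }
        )
    return pd.DataFrame(rows).sort_values("ring").reset_index(drop=True)
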