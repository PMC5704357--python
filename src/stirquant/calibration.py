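"""ROC-based calibration of the SD multiplier k.

For a cohort of labelled image sets, the full quantification pipeline is run
at each candidate k; a set is test-positive when at least one lesion
survives the size filter.  Sensitivity/specificity against the reference
labels trace an ROC curve as k varies (larger k → fewer detections, so
sensitivity is non-increasing and specificity non-decreasing in k).  The
operating point is chosen by Youden's J = sensitivity + specificity − 1,
with ties broken toward the larger k (higher specificity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_io import ImageVolume, ReferenceROI, RegionMask, voxel_volume_cm3
from .quantify import (
    DEFAULT_CONNECTIVITY,
    DEFAULT_MIN_SIZE,
    compute_threshold,
    filter_small,
    label_components,
    mask_hyperintense,
    roi_stats,
)


@dataclass(frozen=True)
class CalibrationCase:
    """One labelled image set for the k sweep."""

    image: ImageVolume
    bone: RegionMask
    roi: ReferenceROI
    positive: bool


@dataclass(frozen=True)
class ROCCurve:
    """Sensitivity/specificity at each k, in increasing-k order."""

    k: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=float)
        sens = np.asarray(self.sensitivity, dtype=float)
        spec = np.asarray(self.specificity, dtype=float)
        if not (len(k) == len(sens) == len(spec)) or len(k) == 0:
            raise ValueError("curve arrays must be non-empty and equal length")
        if np.any(np.diff(k) <= 0):
            raise ValueError("k grid must be strictly increasing")
        for arr in (sens, spec):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("sensitivity/specificity must lie in [0, 1]")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "sensitivity", sens)
        object.__setattr__(self, "specificity", spec)

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def sweep_k(cases: Sequence[CalibrationCase], k_grid: Sequence[float],
            connectivity: int = DEFAULT_CONNECTIVITY,
            min_size: int = DEFAULT_MIN_SIZE) -> ROCCurve:
    """Run the pipeline at every k and tabulate sensitivity/specificity.

    ROI statistics are computed once per case; only the threshold, masking
    and component filtering are repeated across the grid.
    """
    k_grid = np.asarray(list(k_grid), dtype=float)
    if k_grid.size == 0 or np.any(np.diff(k_grid) <= 0):
        raise ValueError("k_grid must be non-empty and strictly increasing")
    labels = np.array([c.positive for c in cases], dtype=bool)
    if labels.size == 0 or labels.all() or not labels.any():
        raise ValueError(
            "ROC needs at least one positive and one negative case"
        )

    stats = [roi_stats(c.image, c.roi) for c in cases]
    sens = np.empty_like(k_grid)
    spec = np.empty_like(k_grid)
    for i, k in enumerate(k_grid):
        test_pos = np.empty(len(cases), dtype=bool)
        for j, case in enumerate(cases):
            T = compute_threshold(stats[j].mean, stats[j].sd, k)
            mask = mask_hyperintense(case.image, case.bone, T)
            comps = filter_small(label_components(mask, connectivity), min_size)
            test_pos[j] = len(comps) >= 1
        tp = int((test_pos & labels).sum())
        tn = int((~test_pos & ~labels).sum())
        sens[i] = tp / labels.sum()
        spec[i] = tn / (~labels).sum()
    return ROCCurve(k_grid, sens, spec)


def sweep_k_volume_rule(cases: Sequence[CalibrationCase],
                        k_grid: Sequence[float],
                        min_volume_cm3: float,
                        connectivity: int = DEFAULT_CONNECTIVITY,
                        min_size: int = DEFAULT_MIN_SIZE,
                        include_gap: bool = False) -> ROCCurve:
    """Alternative positivity rule: total lesion volume above a cutoff."""
    k_grid = np.asarray(list(k_grid), dtype=float)
    labels = np.array([c.positive for c in cases], dtype=bool)
    if labels.size == 0 or labels.all() or not labels.any():
        raise ValueError("ROC needs at least one positive and one negative case")
    stats = [roi_stats(c.image, c.roi) for c in cases]
    sens = np.empty_like(k_grid)
    spec = np.empty_like(k_grid)
    for i, k in enumerate(k_grid):
        test_pos = np.empty(len(cases), dtype=bool)
        for j, case in enumerate(cases):
            T = compute_threshold(stats[j].mean, stats[j].sd, k)
            mask = mask_hyperintense(case.image, case.bone, T)
            comps = filter_small(label_components(mask, connectivity), min_size)
            vox = voxel_volume_cm3(case.image, include_gap=include_gap)
            test_pos[j] = sum(len(c) for c in comps) * vox > min_volume_cm3
        tp = int((test_pos & labels).sum())
        tn = int((~test_pos & ~labels).sum())
        sens[i] = tp / labels.sum()
        spec[i] = tn / (~labels).sum()
    return ROCCurve(k_grid, sens, spec)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under (1 − specificity, sensitivity), with the
    corner points (0, 0) and (1, 1) appended before integration."""
    fpr = 1.0 - curve.specificity
    tpr = curve.sensitivity
    # Lexicographic order keeps equal-FPR points as a vertical segment
    # (zero width) rather than a spurious chord.
    order = np.lexsort((tpr, fpr))
    x = np.concatenate([[0.0], fpr[order], [1.0]])
    y = np.concatenate([[0.0], tpr[order], [1.0]])
    return float(np.trapezoid(y, x))


def optimal_k(curve: ROCCurve) -> float:
    """k maximizing Youden's J; ties go to the larger k."""
    j = curve.youden
    best = np.flatnonzero(j == j.max())[-1]
    return float(curve.k[best])


def default_k_grid(k_min: float = 0.25, k_max: float = 6.0,
                   k_step: float = 0.05) -> np.ndarray:
    """Default sweep grid covering both anatomy presets (4.15, 2.64)."""
    n = int(round((k_max - k_min) / k_step))
    return np.round(k_min + k_step * np.arange(n + 1), 10)
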