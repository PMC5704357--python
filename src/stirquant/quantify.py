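"""Core lesion quantification for one image set.

The method: the mean and SD of signal intensity in a reference ROI of
visibly normal bone marrow define a threshold ``T = mean + k * SD``.  Every
bone-marrow voxel strictly brighter than ``T`` is a candidate edema voxel;
candidates are grouped into connected components and components smaller than
``min_size`` voxels (default 10) are discarded as noise artefacts.  Each
surviving component is one lesion.  Per image set we report the total lesion
volume (``volume_hyper``, cm³), the lesion count, and summary statistics of
the per-voxel relative intensity

    S_RelHyper = (S_hyper - mean_bone) / mean_bone

pooled over all surviving lesion voxels.

``k`` presets: 4.15 for the spine and 2.64 for the sacroiliac joints — the
ROC-calibrated operating points for each anatomy (see ``calibration``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import (
    GridMismatchError,
    ImageVolume,
    ReferenceROI,
    RegionMask,
    voxel_volume_cm3,
    warn_small_roi,
)

#: ROC-calibrated SD multipliers per anatomy.
PRESET_K = {"spine": 4.15, "si": 2.64}

#: Minimum connected-component size kept as a lesion (voxels).
DEFAULT_MIN_SIZE = 10

#: Default 3D adjacency for lesion components.
DEFAULT_CONNECTIVITY = 26

_STRUCTURES_3D = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}
_STRUCTURES_2D = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass(frozen=True)
class ROIStats:
    """Reference-marrow statistics: mean, sample SD (n−1) and voxel count."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class ThresholdSpec:
    """SD multiplier ``k`` and the threshold derived from an ROI."""

    k: float
    preset: str = "custom"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")

    @classmethod
    def from_preset(cls, preset: str) -> "ThresholdSpec":
        if preset not in PRESET_K:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESET_K)}")
        return cls(PRESET_K[preset], preset=preset)

    def threshold(self, roi_stats: ROIStats) -> float:
        return compute_threshold(roi_stats.mean, roi_stats.sd, self.k)


@dataclass(frozen=True)
class Lesion:
    """One connected supra-threshold component surviving the size filter."""

    label: int
    coordinates: np.ndarray          # (size, 3) voxel indices
    volume_cm3: float
    s_hyper: np.ndarray              # raw intensities, one per voxel
    s_rel_hyper: np.ndarray          # Eq. relative intensities, one per voxel

    @property
    def size(self) -> int:
        return len(self.coordinates)


@dataclass(frozen=True)
class QuantResult:
    """Per-image-set quantification summary.

    Intensity summaries are ``None`` (absent), not 0, when there is no
    lesion: cohort means over all image sets include zero volumes but only
    lesion-positive sets contribute intensity statistics.
    """

    lesions: tuple[Lesion, ...]
    volume_hyper_cm3: float
    n_objects: int
    s_rel_mean: float | None
    s_rel_median: float | None
    s_rel_p75: float | None
    s_rel_p90: float | None
    roi_stats: ROIStats
    threshold: float
    k: float
    image_id: str = ""

    @property
    def test_positive(self) -> bool:
        return self.n_objects >= 1

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "volume_hyper_cm3": self.volume_hyper_cm3,
            "n_objects": self.n_objects,
            "s_rel_mean": self.s_rel_mean,
            "s_rel_median": self.s_rel_median,
            "s_rel_p75": self.s_rel_p75,
            "s_rel_p90": self.s_rel_p90,
            "roi_mean": self.roi_stats.mean,
            "roi_sd": self.roi_stats.sd,
            "roi_n": self.roi_stats.n,
            "threshold": self.threshold,
            "k": self.k,
        }


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def roi_stats(image: ImageVolume, roi: ReferenceROI) -> ROIStats:
    """Mean and sample SD (denominator n−1) of the image in the ROI.

    Warns when the ROI has fewer than 200 voxels.
    """
    if roi.n == 0:
        raise ValueError("empty reference ROI")
    roi.check_bounds(image.shape)
    r, c, s = roi.coordinates.T
    values = image.voxels[r, c, s]
    warn_small_roi(roi.n)
    sd = float(np.std(values, ddof=1)) if roi.n > 1 else 0.0
    return ROIStats(mean=float(np.mean(values)), sd=sd, n=roi.n)


def compute_threshold(mean: float, sd: float, k: float) -> float:
    """Lesion threshold ``T = mean + k * sd``."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if k < 0:
        raise ValueError("k must be >= 0")
    return mean + k * sd


def mask_hyperintense(image: ImageVolume, bone: RegionMask, T: float) -> RegionMask:
    """Voxels inside the bone mask with intensity strictly above ``T``."""
    if bone.shape != image.shape:
        raise GridMismatchError(
            f"bone mask grid {bone.shape} does not match image grid {image.shape}"
        )
    return RegionMask(bone.voxels & (image.voxels > T), id=image.id)


def label_components(mask: RegionMask, connectivity: int = DEFAULT_CONNECTIVITY
                     ) -> list[np.ndarray]:
    """Partition mask voxels into maximal connected components.

    ``connectivity`` 6/18/26 labels in 3D; 4/8 labels each slice
    independently in-plane (the per-slice mode used for SI-joint slice
    analysis).  Returns one ``(size, 3)`` coordinate array per component.
    """
    if connectivity in _STRUCTURES_3D:
        labels, n = ndimage.label(mask.voxels, structure=_STRUCTURES_3D[connectivity])
        return _components_from_labels(labels, n)
    if connectivity in _STRUCTURES_2D:
        comps: list[np.ndarray] = []
        structure = _STRUCTURES_2D[connectivity]
        for s in range(mask.shape[2]):
            labels, n = ndimage.label(mask.voxels[:, :, s], structure=structure)
            for comp in _components_from_labels(labels, n):
                coords = np.column_stack(
                    [comp, np.full(len(comp), s, dtype=int)]
                )
                comps.append(coords)
        return comps
    raise ValueError(
        f"connectivity must be one of 6/18/26 (3D) or 4/8 (per-slice), got {connectivity}"
    )


def _components_from_labels(labels: np.ndarray, n: int) -> list[np.ndarray]:
    if n == 0:
        return []
    order = np.argsort(labels, axis=None, kind="stable")
    flat = labels.ravel()[order]
    coords = np.column_stack(np.unravel_index(order, labels.shape))
    starts = np.searchsorted(flat, np.arange(1, n + 2))
    return [coords[starts[i]:starts[i + 1]] for i in range(n)]


def filter_small(components: list[np.ndarray], min_size: int = DEFAULT_MIN_SIZE
                 ) -> list[np.ndarray]:
    """Keep components with at least ``min_size`` voxels (10 survives, 9 not)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [c for c in components if len(c) >= min_size]


def relative_intensity(s_hyper: np.ndarray | float, roi_mean: float):
    """Relative lesion intensity ``(S_hyper − mean_bone) / mean_bone``."""
    if roi_mean <= 0:
        raise ValueError("reference-marrow mean must be > 0")
    return (np.asarray(s_hyper, dtype=float) - roi_mean) / roi_mean


def summarize(components: list[np.ndarray], image: ImageVolume,
              stats: ROIStats, threshold: float, k: float,
              voxel_volume: float) -> QuantResult:
    """Build the per-set summary from size-filtered components.

    ``volume_hyper`` is the surviving voxel count times the voxel volume;
    intensity summaries are pooled over all surviving voxels of the set,
    not averaged per lesion.
    """
    lesions = []
    pooled: list[np.ndarray] = []
    for i, coords in enumerate(components, start=1):
        r, c, s = coords.T
        s_hyper = image.voxels[r, c, s]
        s_rel = relative_intensity(s_hyper, stats.mean)
        lesions.append(Lesion(
            label=i, coordinates=coords,
            volume_cm3=len(coords) * voxel_volume,
            s_hyper=s_hyper, s_rel_hyper=s_rel,
        ))
        pooled.append(s_rel)

    if lesions:
        all_rel = np.concatenate(pooled)
        s_mean = float(np.mean(all_rel))
        s_median = float(np.median(all_rel))
        # Linear interpolation between order statistics at rank p*(n-1)+1.
        s_p75 = float(np.percentile(all_rel, 75, method="linear"))
        s_p90 = float(np.percentile(all_rel, 90, method="linear"))
    else:
        s_mean = s_median = s_p75 = s_p90 = None

    total_voxels = sum(les.size for les in lesions)
    return QuantResult(
        lesions=tuple(lesions),
        volume_hyper_cm3=total_voxels * voxel_volume,
        n_objects=len(lesions),
        s_rel_mean=s_mean, s_rel_median=s_median,
        s_rel_p75=s_p75, s_rel_p90=s_p90,
        roi_stats=stats, threshold=threshold, k=k,
        image_id=image.id,
    )


# ---------------------------------------------------------------------------
# One-call pipeline for a single image set
# ---------------------------------------------------------------------------

def quantify_image_set(image: ImageVolume, bone: RegionMask, roi: ReferenceROI,
                       spec: ThresholdSpec,
                       connectivity: int = DEFAULT_CONNECTIVITY,
                       min_size: int = DEFAULT_MIN_SIZE,
                       include_gap: bool = False) -> QuantResult:
    """Run ROI statistics → threshold → masking → components → summary."""
    stats = roi_stats(image, roi)
    T = spec.threshold(stats)
    mask = mask_hyperintense(image, bone, T)
    components = filter_small(label_components(mask, connectivity), min_size)
    vox = voxel_volume_cm3(image, include_gap=include_gap)
    return summarize(components, image, stats, T, spec.k, vox)


def lesion_mask(result: QuantResult, shape: tuple[int, int, int]) -> RegionMask:
    """Binary mask of all surviving lesion voxels (for export/overlay)."""
    out = np.zeros(shape, dtype=bool)
    for les in result.lesions:
        r, c, s = les.coordinates.T
        out[r, c, s] = True
    return RegionMask(out, id=result.image_id)
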