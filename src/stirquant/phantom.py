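"""Synthetic STIR-like phantoms with ground truth.

The phantom emulates the features of a STIR acquisition that the
quantification pipeline is sensitive to: homogeneous marrow at a base
intensity with additive noise, brighter elliptical edema lesions of
controlled contrast (in units of the marrow noise SD), darker surrounding
soft tissue, and an optional smooth multiplicative bias field mimicking
coil-proximity shading.  Geometry defaults follow a typical protocol:
1 × 1 mm in-plane, 4 mm slices with a 10% gap.

It does not attempt anatomical realism (no vertebral shapes, joints or
partial-volume edges); ground truth is the geometric ellipsoid mask, not
the post-noise supra-threshold set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .image_io import ImageVolume, ReferenceROI, RegionMask, circular_roi


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal lesion: centre and semi-axes in voxels, contrast as a
    multiple of the marrow noise SD."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    contrast: float

    def __post_init__(self) -> None:
        if min(self.semi_axes) < 1:
            raise ValueError("lesion semi-axes must be >= 1 voxel")


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 12)
    spacing: tuple[float, float, float] = (1.0, 1.0, 4.0)
    slice_gap_fraction: float = 0.1
    mu_bone: float = 100.0
    sigma_bone: float = 10.0
    mu_background: float = 40.0
    sigma_background: float = 8.0
    #: half-open bone-region bounds ((r0, r1), (c0, c1), (s0, s1));
    #: ``None`` = central half in-plane, all slices
    bone_box: tuple[tuple[int, int], ...] | None = None
    lesions: tuple[LesionSpec, ...] = ()
    bias_amplitude: float = 0.0
    bias_scale: float = 20.0  # Gaussian bump width, voxels
    bias_center: tuple[float, float, float] | None = None
    noise: str = "gaussian"
    roi_center: tuple[float, float] | None = None
    roi_radius: float = 8.5  # disk of ~225 voxels, above the 200-voxel floor
    roi_slice: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_bone <= 0:
            raise ValueError("sigma_bone must be > 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")
        if self.noise not in ("gaussian", "rician"):
            raise ValueError("noise must be 'gaussian' or 'rician'")

    def resolved_bone_box(self) -> tuple[tuple[int, int], ...]:
        if self.bone_box is not None:
            return self.bone_box
        nr, nc, ns = self.shape
        return ((nr // 4, nr - nr // 4), (nc // 4, nc - nc // 4), (0, ns))


def generate_phantom(config: PhantomConfig, seed: int | None = None
                     ) -> tuple[ImageVolume, RegionMask, RegionMask, ReferenceROI]:
    """Build (image, bone mask, ground-truth lesion mask, reference ROI).

    Deterministic for a fixed seed.  Raises if a lesion extends outside the
    bone region or the reference ROI overlaps a lesion.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    shape = config.shape
    box = config.resolved_bone_box()

    bone = np.zeros(shape, dtype=bool)
    (r0, r1), (c0, c1), (s0, s1) = box
    bone[r0:r1, c0:c1, s0:s1] = True

    gt = np.zeros(shape, dtype=bool)
    contrast_add = np.zeros(shape, dtype=float)
    rr, cc, ss = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]]
    for les in config.lesions:
        (lr, lc, ls), (a, b, c) = les.center, les.semi_axes
        inside = (((rr - lr) / a) ** 2 + ((cc - lc) / b) ** 2
                  + ((ss - ls) / c) ** 2) <= 1.0
        if not (inside <= bone).all():
            raise ValueError(
                f"lesion at {les.center} extends outside the bone region {box}"
            )
        gt |= inside
        contrast_add[inside] = les.contrast * config.sigma_bone

    roi = _place_roi(config, bone, gt)

    base = np.full(shape, config.mu_background, dtype=float)
    base[bone] = config.mu_bone

    if config.bias_amplitude > 0:
        center = config.bias_center
        if center is None:
            center = (float(r0), float(c0), (s0 + s1 - 1) / 2.0)
        d2 = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2
              + (ss - center[2]) ** 2)
        field_map = 1.0 + config.bias_amplitude * np.exp(
            -d2 / (2.0 * config.bias_scale ** 2))
    else:
        field_map = 1.0

    signal = base * field_map + contrast_add
    sigma = np.where(bone, config.sigma_bone, config.sigma_background)
    if config.noise == "gaussian":
        voxels = signal + rng.normal(0.0, 1.0, shape) * sigma
    else:  # rician: magnitude of complex signal with iid Gaussian channels
        n1 = rng.normal(0.0, 1.0, shape) * sigma
        n2 = rng.normal(0.0, 1.0, shape) * sigma
        voxels = np.hypot(signal + n1, n2)
    voxels = np.clip(voxels, 0.0, None)

    image = ImageVolume(voxels, config.spacing, config.slice_gap_fraction,
                        id=f"phantom-{seed}")
    return (image, RegionMask(bone, id="bone"), RegionMask(gt, id="lesions"), roi)


def _place_roi(config: PhantomConfig, bone: np.ndarray, gt: np.ndarray
               ) -> ReferenceROI:
    """Resolve the reference ROI; auto-placement scans slices for a
    lesion-free disk at the bone centre."""
    (r0, r1), (c0, c1), (s0, s1) = config.resolved_bone_box()
    center = config.roi_center
    if center is None:
        center = ((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0)

    def disk_ok(roi: ReferenceROI) -> bool:
        coords = roi.coordinates
        if (coords < 0).any() or (coords >= np.asarray(bone.shape)).any():
            return False
        r, c, s = coords.T
        return bool(bone[r, c, s].all() and not gt[r, c, s].any())

    if config.roi_slice is not None:
        roi = circular_roi(center, config.roi_radius, config.roi_slice, id="roi")
        coords = roi.coordinates
        if (coords < 0).any() or (coords >= np.asarray(bone.shape)).any():
            raise ValueError("reference ROI extends outside the grid")
        r, c, s = coords.T
        if not bone[r, c, s].all():
            raise ValueError("reference ROI extends outside the bone region")
        if gt[r, c, s].any():
            raise ValueError("reference ROI overlaps a ground-truth lesion")
        return roi

    for s in range(s0, s1):
        roi = circular_roi(center, config.roi_radius, s, id="roi")
        if disk_ok(roi):
            return roi
    raise ValueError(
        "no lesion-free slice available for automatic ROI placement; "
        "set roi_center/roi_slice explicitly"
    )


def default_lesion(config: PhantomConfig | None = None,
                   contrast: float = 10.0,
                   semi_axes: tuple[float, float, float] = (8.0, 8.0, 3.0)
                   ) -> LesionSpec:
    """A lesion centred in the upper-slice half of the default bone region."""
    cfg = config or PhantomConfig()
    (r0, r1), (c0, c1), (s0, s1) = cfg.resolved_bone_box()
    margin = max(semi_axes)
    center = ((r0 + r1) / 2.0, (c0 + c1) / 2.0, s1 - 1 - semi_axes[2])
    del margin
    return LesionSpec(center=center, semi_axes=semi_axes, contrast=contrast)


def cohort_configs(n_positive: int, n_negative: int, seed: int,
                   base: PhantomConfig | None = None,
                   contrast: float = 10.0) -> list[PhantomConfig]:
    """Configs for a labelled cohort: lesion-bearing then lesion-free
    phantoms, each with its own sub-seed.  Positivity is encoded by the
    presence of a lesion; the i-th config uses seed ``seed + i``."""
    base = base or PhantomConfig()
    les = default_lesion(base, contrast=contrast)
    out = []
    for i in range(n_positive + n_negative):
        lesions = (les,) if i < n_positive else ()
        out.append(replace(base, lesions=lesions, seed=seed + i))
    return out
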