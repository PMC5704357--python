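"""Histogram-matching intensity normalization.

STIR intensities are in arbitrary scanner units, so volumes from different
sessions cannot be thresholded on a common scale.  Matching each volume's
intensity histogram to a single reference volume puts every image set on the
same overall brightness before the reference-ROI threshold is computed.

The mapping is a binned quantile transform: each volume is first min–max
scaled onto the joint intensity range of image and reference (so both fill
the full grid of ``n_bins`` equal-width bins regardless of their native
scales), then every voxel is sent through the image CDF and the inverse
reference CDF.  The transform is monotone non-decreasing, so voxel ranks —
and hence the supra-threshold voxel set after re-deriving the ROI threshold
— are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import ImageVolume


@dataclass(frozen=True)
class HistogramSpec:
    """Binning for the quantile mapping; the intensity range is always the
    joint min/max of image and reference."""

    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def match_histogram(image: ImageVolume, reference: ImageVolume,
                    spec: HistogramSpec = HistogramSpec()) -> ImageVolume:
    """Map ``image`` intensities so their distribution matches ``reference``.

    Returns a volume on the image's grid.  A constant image maps to the
    reference's median intensity; a constant reference with a non-constant
    image has no well-defined target histogram and raises ``ValueError``.
    """
    img = image.voxels
    ref = reference.voxels
    if img.size == 0 or ref.size == 0:
        raise ValueError("cannot match empty volumes")

    ref_spread = float(ref.max() - ref.min())
    img_spread = float(img.max() - img.min())
    if img_spread == 0.0:
        # Degenerate CDF: every quantile of the image is the same point, so
        # the natural target is the reference's 0.5 quantile.
        out = np.full_like(img, float(np.quantile(ref, 0.5)))
        return ImageVolume(out, image.spacing, image.slice_gap_fraction,
                           id=image.id)
    if ref_spread == 0.0:
        raise ValueError(
            "constant reference volume: target histogram is undefined for a "
            "non-constant image"
        )

    # Min-max scaling each volume onto the joint range means both span the
    # whole bin grid; equivalently, bin each over its own min-max range.
    img_edges = np.linspace(float(img.min()), float(img.max()), spec.n_bins + 1)
    ref_edges = np.linspace(float(ref.min()), float(ref.max()), spec.n_bins + 1)

    img_cdf = _binned_cdf(img, img_edges)
    ref_cdf = _binned_cdf(ref, ref_edges)

    # voxel -> image CDF value -> reference inverse CDF.  Both CDFs are
    # piecewise linear through the binned counts, so the composition is
    # monotone non-decreasing and continuous within bins.
    u = np.interp(img.ravel(), img_edges, img_cdf)
    out = np.interp(u, ref_cdf, ref_edges).reshape(img.shape)
    return ImageVolume(out, image.spacing, image.slice_gap_fraction, id=image.id)


def synthetic_reference(anatomy: str = "spine") -> ImageVolume:
    """Deterministic synthetic reference volume for histogram matching.

    A stand-in for a real reference acquisition, which cannot be
    redistributed: a lesion-free noise phantom with typical geometry for
    the anatomy, generated from a fixed seed so every call (and every
    user) normalizes to the identical target histogram.  Supplying a real
    scanner reference instead is always preferable when one is available.
    """
    from .phantom import PhantomConfig, generate_phantom

    seeds = {"spine": 101, "si": 202}
    if anatomy not in seeds:
        raise ValueError(f"anatomy must be one of {sorted(seeds)}")
    image, _, _, _ = generate_phantom(PhantomConfig(), seed=seeds[anatomy])
    return ImageVolume(image.voxels, image.spacing, image.slice_gap_fraction,
                       id=f"synthetic-reference-{anatomy}")


def _binned_cdf(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """CDF sampled at every bin edge (0 at the left edge, 1 at the right)."""
    hist, _ = np.histogram(values, bins=edges)
    cdf = np.concatenate([[0.0], np.cumsum(hist, dtype=float)])
    return cdf / cdf[-1]
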