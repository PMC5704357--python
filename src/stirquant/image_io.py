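"""Volume, mask, ROI and label-table I/O.

Everything downstream shares one voxel-geometry contract: images and masks
live on a common 0-based ``(row, column, slice)`` lattice with spacing in
millimetres and an optional fractional inter-slice gap.  No resampling or
registration is provided — masks must be drawn on the image grid.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("stirquant")

#: Minimum recommended reference-ROI size (voxels); smaller ROIs give a
#: noisy estimate of the normal-marrow mean/SD and only trigger a warning.
MIN_ROI_VOXELS = 200


class FormatError(ValueError):
    """Raised when a file cannot be read as the expected image format."""


class GridMismatchError(ValueError):
    """Raised when a mask or ROI does not live on the image's voxel grid."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar MR volume (arbitrary units) with voxel geometry.

    Parameters
    ----------
    voxels
        3D array of finite, non-negative intensities, indexed
        ``(row, column, slice)``.
    spacing
        In-plane row/column spacing and slice thickness, all in mm.
    slice_gap_fraction
        Inter-slice gap as a fraction of slice thickness (0.1 means a 10%
        gap); ≥ 0.
    id
        Opaque identifier used in result tables and logs.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    slice_gap_fraction: float = 0.0
    id: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError(f"expected a 3D grid, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("intensities must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"all spacing components must be > 0, got {spacing}")
        if self.slice_gap_fraction < 0:
            raise ValueError("slice_gap_fraction must be >= 0")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class RegionMask:
    """Binary mask on the same lattice as the volume it annotates."""

    voxels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {vox.shape}")
        object.__setattr__(self, "voxels", vox.astype(bool))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class ReferenceROI:
    """Voxel coordinates of the reference "normal bone marrow" region.

    The mean/SD of the image in this region define the lesion threshold
    ``T = mean + k * SD``.  Coordinates are 0-based ``(row, column, slice)``
    and must be unique.
    """

    coordinates: np.ndarray  # (n, 3) int
    id: str = ""

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coordinates, dtype=int))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be an (n, 3) index array")
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValueError("ROI coordinates must be unique")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n(self) -> int:
        return len(self.coordinates)

    def check_bounds(self, shape: tuple[int, int, int]) -> None:
        c = self.coordinates
        if c.size and ((c < 0).any() or (c >= np.asarray(shape)).any()):
            raise GridMismatchError(
                f"ROI coordinates fall outside the image grid {shape}"
            )


@dataclass(frozen=True)
class LabelTable:
    """Reference scores (e.g. SPARCC) per image set or per slice.

    A unit is *positive* exactly when its score is > 0.
    """

    rows: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject", "image_set", "slice", "score")

    def __post_init__(self) -> None:
        df = self.rows.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"label table missing columns: {missing}")
        df["score"] = pd.to_numeric(df["score"])
        if (df["score"] < 0).any():
            raise ValueError("reference scores must be >= 0")
        df["positive"] = df["score"] > 0
        object.__setattr__(self, "rows", df)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def load_volume(path: str | Path, format: str | None = None) -> ImageVolume:
    """Read a 3D volume from a NIfTI file or a DICOM series directory.

    Spacing is taken from the header.  For DICOM, the slice-gap fraction is
    derived as ``(SpacingBetweenSlices − SliceThickness) / SliceThickness``
    when both tags are present; otherwise (and for NIfTI, which does not
    store the gap separately) it defaults to 0 with a logged note.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    fmt = format
    if fmt is None:
        fmt = "dicom" if path.is_dir() else "nifti"
    if fmt == "nifti":
        return _load_nifti(path)
    if fmt == "dicom":
        return _load_dicom_series(path)
    raise FormatError(f"unsupported format hint {fmt!r}")


def _load_nifti(path: Path) -> ImageVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z == 0 for z in zooms):
        raise FormatError(f"{path}: missing or zero voxel spacing in header")
    if any(z < 0 for z in zooms):
        raise FormatError(f"{path}: negative voxel spacing in header")
    logger.debug("%s: NIfTI header has no slice-gap field; using gap 0", path)
    return ImageVolume(data, tuple(float(z) for z in zooms), 0.0, id=path.stem)


def _load_dicom_series(path: Path) -> ImageVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no readable DICOM images in {path}")
    slices.sort(key=lambda ds: float(getattr(ds, "InstanceNumber", 0)))
    first = slices[0]
    if not hasattr(first, "PixelSpacing"):
        raise FormatError(f"{path}: DICOM series lacks PixelSpacing")
    if not hasattr(first, "SliceThickness"):
        raise FormatError(f"{path}: DICOM series lacks SliceThickness")
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    thickness = float(first.SliceThickness)
    gap = 0.0
    between = getattr(first, "SpacingBetweenSlices", None)
    if between is not None and thickness > 0:
        gap = max(0.0, (float(between) - thickness) / thickness)
    else:
        logger.info("%s: SpacingBetweenSlices absent; using slice gap 0", path)
    data = np.stack([ds.pixel_array.astype(float) for ds in slices], axis=-1)
    return ImageVolume(data, (row_sp, col_sp, thickness), gap, id=path.name)


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with spacing in the header."""
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_mask(path: str | Path, reference: ImageVolume) -> RegionMask:
    """Read a binary mask; any nonzero voxel counts as inside."""
    vol = load_volume(path, format="nifti" if Path(path).is_file() else None)
    if vol.shape != reference.shape:
        raise GridMismatchError(
            f"mask grid {vol.shape} does not match image grid {reference.shape}"
        )
    return RegionMask(vol.voxels != 0, id=vol.id)


def save_mask(mask: RegionMask, path: str | Path,
              spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def circular_roi(center: tuple[float, float], radius: float,
                 slice_index: int, id: str = "") -> ReferenceROI:
    """Build a circular in-plane ROI (the conventional ≥ 200-voxel disk).

    Voxels whose in-plane centre lies within ``radius`` of ``center``
    (row, column) in the given slice are included.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    r0, c0 = center
    lo_r, hi_r = int(np.floor(r0 - radius)), int(np.ceil(r0 + radius))
    lo_c, hi_c = int(np.floor(c0 - radius)), int(np.ceil(c0 + radius))
    rr, cc = np.mgrid[lo_r:hi_r + 1, lo_c:hi_c + 1]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    coords = np.column_stack([
        rr[inside], cc[inside], np.full(int(inside.sum()), slice_index)
    ])
    return ReferenceROI(coords, id=id)


def load_roi(path: str | Path) -> ReferenceROI:
    """Read an ROI spec: a CSV of ``row,col,slice`` voxel coordinates, or a
    JSON object ``{"center": [r, c], "radius": x, "slice": s}``."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        spec = json.loads(text)
        return circular_roi(tuple(spec["center"]), float(spec["radius"]),
                            int(spec["slice"]), id=path.stem)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        cols = {c.strip().lower() for c in reader.fieldnames or ()}
        if not {"row", "col", "slice"} <= cols:
            raise FormatError(
                f"{path}: ROI CSV needs columns row,col,slice (got {sorted(cols)})"
            )
        coords = [(int(row["row"]), int(row["col"]), int(row["slice"]))
                  for row in reader]
    if not coords:
        raise FormatError(f"{path}: empty ROI coordinate list")
    return ReferenceROI(np.asarray(coords), id=path.stem)


def save_roi(roi: ReferenceROI, path: str | Path) -> None:
    df = pd.DataFrame(roi.coordinates, columns=["row", "col", "slice"])
    df.to_csv(path, index=False)


def load_labels(path: str | Path) -> LabelTable:
    """Read a reference-score table: CSV with header
    ``subject,image_set,slice,score`` (slice empty for per-set scores)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return LabelTable(df)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def voxel_volume_cm3(volume: ImageVolume, include_gap: bool = False) -> float:
    """Volume of one voxel in cm³.

    By default the inter-slice gap is excluded — the signal is only sampled
    within the slice thickness.  With ``include_gap`` each voxel is credited
    with its share of the gap, ``thickness * (1 + gap_fraction)``.
    """
    row, col, thick = volume.spacing
    if include_gap:
        thick = thick * (1.0 + volume.slice_gap_fraction)
    return row * col * thick / 1000.0


def warn_small_roi(n: int) -> None:
    if n < MIN_ROI_VOXELS:
        warnings.warn(
            f"reference ROI has only {n} voxels (< {MIN_ROI_VOXELS}); "
            "threshold statistics may be unstable",
            stacklevel=3,
        )
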