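"""Reading and writing ADC images, ROI masks and lesion label tables.

ADC (apparent diffusion coefficient) maps are 2D grayscale images whose
pixel values are diffusion magnitudes in units of 1e-6 mm^2/s.  Lesions and
the whole prostate gland arrive as binary masks drawn on the same pixel
grid.  Everything downstream works on boolean masks aligned to the image;
polygon ROIs (ImageJ ``.roi``) are rasterized on import.

Grid convention: row-major, 0-based, ``(row, col)`` indexing.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

logger = logging.getLogger(__name__)

MIN_IMAGE_EXTENT = 9  # one local window must fit


class ImagingError(ValueError):
    """Raised for unreadable or geometrically inconsistent imaging inputs."""


@dataclass
class ADCImage:
    """A single 2D ADC map.

    Parameters
    ----------
    pixels : ndarray
        2D array of non-negative diffusion values (1e-6 mm^2/s).
    pixel_spacing : tuple of float
        (row, col) spacing in mm.
    patient_id, slice_id : str
        Opaque identifiers.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    patient_id: str = ""
    slice_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ImagingError(f"ADC image must be 2D, got shape {self.pixels.shape}")
        if min(self.pixels.shape) < MIN_IMAGE_EXTENT:
            raise ImagingError(
                f"image extent {self.pixels.shape} smaller than {MIN_IMAGE_EXTENT}x{MIN_IMAGE_EXTENT}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ImagingError("non-finite pixel values in ADC image")
        if np.any(self.pixels < 0):
            raise ImagingError("negative pixel values in ADC image")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ImagingError(f"pixel spacing must be positive, got {self.pixel_spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])


@dataclass
class ROIMask:
    """A binary region of interest aligned to an :class:`ADCImage`."""

    mask: np.ndarray
    role: Literal["gland", "lesion"]
    lesion_id: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask) != 0
        if self.mask.ndim != 2:
            raise ImagingError(f"ROI mask must be 2D, got shape {self.mask.shape}")
        if not self.mask.any():
            raise ImagingError("empty ROI")
        if self.role not in ("gland", "lesion"):
            raise ImagingError(f"unknown ROI role {self.role!r}")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def area_mm2(self, image: ADCImage) -> float:
        return self.area_px * image.pixel_area_mm2


@dataclass
class LesionRecord:
    """Histology label attached to a lesion ROI: Gleason Grade group and PIRADS."""

    lesion_id: str
    patient_id: str
    gg: int
    pirads: int
    area_mm2: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.gg not in range(1, 6):
            raise ValueError(f"Gleason Grade group must be 1..5, got {self.gg}")
        if self.pirads not in range(3, 6):
            raise ValueError(f"PIRADS must be 3..5, got {self.pirads}")

    @property
    def cspca(self) -> bool:
        """Clinically significant PCa, defined as GG >= 3."""
        return self.gg >= 3


def check_alignment(image: ADCImage, mask: ROIMask) -> None:
    """Raise unless a mask shares its image's pixel grid."""
    if mask.mask.shape != image.shape:
        raise ImagingError(
            f"mask shape {mask.mask.shape} does not match image shape {image.shape}"
        )


def clip_lesion_to_gland(lesion: ROIMask, gland: ROIMask) -> ROIMask:
    """Intersect a lesion mask with the gland mask.

    Lesion pixels outside the gland are dropped with a warning: the local
    feature maps are only defined within the gland, so stray pixels could
    never contribute to descriptors anyway.
    """
    outside = int((lesion.mask & ~gland.mask).sum())
    if outside == 0:
        return lesion
    logger.warning(
        "lesion %s: %d pixel(s) outside the gland mask were clipped",
        lesion.lesion_id, outside,
    )
    clipped = lesion.mask & gland.mask
    if not clipped.any():
        raise ImagingError(f"lesion {lesion.lesion_id}: entirely outside the gland")
    return ROIMask(clipped, role="lesion", lesion_id=lesion.lesion_id)


# ---------------------------------------------------------------------------
# readers


def _read_pixels(path: Path, slice_index: int | None) -> tuple[np.ndarray, tuple[float, float]]:
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()
        if data.ndim == 3:
            if data.shape[2] == 1:
                data = data[:, :, 0]
            elif slice_index is not None:
                data = data[:, :, slice_index]
            else:
                raise ImagingError(f"{path}: 3D volume requires a slice selector")
        # NIfTI stores (i, j) with zooms per axis; transpose to (row, col)
        return data.T.astype(float), (float(zooms[1]), float(zooms[0]))
    if suffix.endswith((".dcm", ".ima")) or suffix == "":
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        if arr.ndim == 3:
            if slice_index is None:
                raise ImagingError(f"{path}: multi-frame DICOM requires a slice selector")
            arr = arr[slice_index]
        spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
        return arr, (float(spacing[0]), float(spacing[1]))
    if suffix.endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(str(path)).astype(float)
        if arr.ndim == 3:
            if slice_index is None:
                raise ImagingError(f"{path}: TIFF stack requires a slice selector")
            arr = arr[slice_index]
        return arr, (1.0, 1.0)
    raise ImagingError(f"unsupported image format: {path}")


def read_adc(
    path: str | Path,
    *,
    slice_index: int | None = None,
    pixel_spacing: tuple[float, float] | None = None,
    patient_id: str = "",
    slice_id: str = "",
) -> ADCImage:
    """Read an ADC map from DICOM, NIfTI-1 or (16-bit) TIFF.

    DICOM rescale slope/intercept is applied.  ``pixel_spacing`` overrides
    whatever the file header carries (TIFF has none).
    """
    path = Path(path)
    if not path.exists():
        raise ImagingError(f"no such file: {path}")
    pixels, spacing = _read_pixels(path, slice_index)
    if pixel_spacing is not None:
        spacing = pixel_spacing
    return ADCImage(pixels, spacing, patient_id=patient_id, slice_id=slice_id or path.stem)


def write_adc(image: ADCImage, path: str | Path) -> None:
    """Write an ADC map as 16-bit TIFF or float NIfTI, by extension."""
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), np.round(image.pixels).astype(np.uint16))
    elif suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([image.pixel_spacing[1], image.pixel_spacing[0], 1.0, 1.0])
        nib.save(nib.Nifti1Image(image.pixels.T.astype(np.float64), affine), str(path))
    else:
        raise ImagingError(f"unsupported output format: {path}")


def read_mask(
    path: str | Path,
    role: Literal["gland", "lesion"],
    *,
    lesion_id: str | None = None,
    split_labels: bool = False,
) -> ROIMask | list[ROIMask]:
    """Read a binary (or label) mask image; any nonzero pixel is inside.

    With ``split_labels=True`` a label image yields one :class:`ROIMask`
    per distinct nonzero label, with ``lesion_id`` set to the label value.
    """
    import imageio.v3 as iio

    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(path)).dataobj)
        arr = arr.T if arr.ndim == 2 else arr[:, :, 0].T
    else:
        arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:  # RGB(A) PNG
        arr = arr[..., :3].max(axis=2)
    if not (arr != 0).any():
        raise ImagingError(f"empty ROI in {path}")
    if split_labels:
        return [
            ROIMask(arr == lab, role=role, lesion_id=str(int(lab)))
            for lab in np.unique(arr[arr != 0])
        ]
    return ROIMask(arr != 0, role=role, lesion_id=lesion_id)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(Path(path)), (mask.mask * np.uint8(255)))


def read_imagej_roi(path: str | Path, shape: tuple[int, int], role: str = "lesion") -> ROIMask:
    """Rasterize an ImageJ ``.roi`` polygon into a boolean mask.

    Only polygon/freehand/traced ROIs are supported; the polygon is filled
    with the even-odd rule on the given image grid.
    """
    from skimage.draw import polygon2mask

    raw = Path(path).read_bytes()
    if raw[:4] != b"Iout":
        raise ImagingError(f"{path}: not an ImageJ ROI file")
    roi_type = raw[6]
    if roi_type not in (0, 7, 8):  # polygon, freehand, traced
        raise ImagingError(f"{path}: unsupported ROI type {roi_type}")
    top, left = struct.unpack(">hh", raw[8:12])
    (n,) = struct.unpack(">h", raw[16:18])
    xs = struct.unpack(f">{n}h", raw[64 : 64 + 2 * n])
    ys = struct.unpack(f">{n}h", raw[64 + 2 * n : 64 + 4 * n])
    verts = np.column_stack([np.asarray(ys) + top, np.asarray(xs) + left])
    mask = polygon2mask(shape, verts)
    if not mask.any():
        raise ImagingError(f"{path}: polygon rasterized to an empty mask")
    return ROIMask(mask, role=role, lesion_id=Path(path).stem)


# ---------------------------------------------------------------------------
# label tables


def read_label_table(path: str | Path) -> list[LesionRecord]:
    """Read the lesion label CSV (lesion_id, patient_id, gg, pirads)."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"lesion_id": str, "patient_id": str})
    required = {"lesion_id", "patient_id", "gg", "pirads"}
    missing = required - set(df.columns)
    if missing:
        raise ImagingError(f"label table missing columns: {sorted(missing)}")
    return [
        LesionRecord(r.lesion_id, r.patient_id, int(r.gg), int(r.pirads))
        for r in df.itertuples()
    ]


def write_label_table(records: list[LesionRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "lesion_id": r.lesion_id,
                "patient_id": r.patient_id,
                "gg": r.gg,
                "pirads": r.pirads,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# colorimetric export


def export_colormap(
    map_values: np.ndarray,
    gland: ROIMask,
    path: str | Path,
    *,
    lesion: ROIMask | None = None,
    cmap: str = "jet",
    contour_color: tuple[int, int, int] = (255, 105, 180),
) -> np.ndarray:
    """Export a parametric map as an 8-bit color PNG for visual QC.

    The map is min-max scaled over its defined (finite, in-gland) pixels and
    run through a matplotlib colormap; pixels outside the gland are black.
    If a lesion mask is given its boundary is overlaid as a contour.
    Returns the RGB array that was written.
    """
    import imageio.v3 as iio
    import matplotlib.cm as cm
    from skimage.segmentation import find_boundaries

    values = np.asarray(map_values, dtype=float)
    defined = gland.mask & np.isfinite(values)
    if not defined.any():
        raise ImagingError("parametric map has no defined pixels inside the gland")
    lo, hi = values[defined].min(), values[defined].max()
    scaled = np.zeros_like(values)
    if hi > lo:
        scaled[defined] = (values[defined] - lo) / (hi - lo)
    else:
        scaled[defined] = 0.5
    rgb = (cm.get_cmap(cmap)(scaled)[..., :3] * 255).astype(np.uint8)
    rgb[~defined] = 0
    if lesion is not None:
        boundary = find_boundaries(lesion.mask, mode="inner")
        rgb[boundary] = contour_color
    iio.imwrite(str(Path(path)), rgb)
    return rgb
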