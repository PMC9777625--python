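"""Image / ROI input and preprocessing.

Reads 8-bit grayscale PNG (and single-frame grayscale DICOM) images,
normalizes intensities, detects and inpaints bright caliper-dot markers,
and rasterizes ROI polygons into pixel masks.

Coordinate convention (used throughout the package): 0-based ``(row, col)``
with pixel centers at integer coordinates; polygons are ordered vertex
lists, implicitly closed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely
from PIL import Image
from scipy import ndimage


class ImageFormatError(ValueError):
    """Raised when an input file is not a supported grayscale image."""


@dataclass
class UltrasoundImage:
    """A 2-D grayscale B-mode raster with acquisition metadata.

    ``pixels`` holds either raw 8-bit intensities (0-255) or normalized
    floats in [0, 1]; ``normalized`` records which.
    """

    pixels: np.ndarray
    patient_id: str = ""
    image_id: str = ""
    side: str | None = None
    angle: int | None = None
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValueError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RoiRegion:
    """A polygonal region of interest and its rasterization.

    ``mask`` marks the pixel set Omega over which all texture statistics
    are computed; ``pixel_count`` is |Omega|.
    """

    polygon: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel_count == 0:
            raise ValueError("ROI rasterizes to an empty pixel set")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def read_image(path: str | Path, *, patient_id: str = "", image_id: str = "") -> UltrasoundImage:
    """Read an 8-bit grayscale PNG or a single-frame grayscale DICOM.

    PNG pixel values are preserved exactly.  DICOM payloads wider than
    8 bits are linearly rescaled to 0-255 using the stored window
    (center/width) when present, otherwise the frame's min-max range;
    the rescaling is flagged in ``meta['rescaled']``.
    """
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        return _read_dicom(path, patient_id=patient_id, image_id=image_id)
    try:
        img = Image.open(path)
    except Exception as exc:  # noqa: BLE001
        raise ImageFormatError(f"cannot read image file: {path}") from exc
    if img.mode != "L":
        raise ImageFormatError(
            f"expected 8-bit grayscale image, got mode {img.mode!r}: {path}"
        )
    arr = np.asarray(img, dtype=np.uint8)
    return UltrasoundImage(arr, patient_id=patient_id, image_id=image_id or path.stem)


def _read_dicom(path: Path, *, patient_id: str, image_id: str) -> UltrasoundImage:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:  # noqa: BLE001
        raise ImageFormatError(f"cannot read DICOM file: {path}") from exc
    if arr.ndim != 2:
        raise ImageFormatError(f"expected a single-frame grayscale DICOM: {path}")
    meta: dict = {}
    if arr.dtype != np.uint8:
        arr = arr.astype(float)
        center = getattr(ds, "WindowCenter", None)
        width = getattr(ds, "WindowWidth", None)
        if center is not None and width is not None:
            center = float(center[0] if isinstance(center, pydicom.multival.MultiValue) else center)
            width = float(width[0] if isinstance(width, pydicom.multival.MultiValue) else width)
            lo, hi = center - width / 2.0, center + width / 2.0
        else:
            lo, hi = float(arr.min()), float(arr.max())
        if hi <= lo:
            hi = lo + 1.0
        arr = np.clip((arr - lo) / (hi - lo), 0.0, 1.0) * 255.0
        arr = np.round(arr).astype(np.uint8)
        meta["rescaled"] = True
    return UltrasoundImage(
        arr,
        patient_id=patient_id or str(getattr(ds, "PatientID", "")),
        image_id=image_id or path.stem,
        meta=meta,
    )


def normalize_intensity(
    image: UltrasoundImage, p_low: float = 1.0, p_high: float = 99.0
) -> UltrasoundImage:
    """Percentile-clipped linear rescale to [0, 1].

    The ``p_low``/``p_high`` intensity percentiles map to 0/1 and values
    beyond them are clipped.  A constant image maps to all zeros.
    Percentile normalization is robust to isolated saturated pixels
    (caliper dots), which would otherwise dominate a min-max rescale.
    """
    if not 0 <= p_low < p_high <= 100:
        raise ValueError("require 0 <= p_low < p_high <= 100")
    pix = image.pixels.astype(float)
    lo, hi = np.percentile(pix, [p_low, p_high])
    if hi <= lo:
        out = np.zeros_like(pix)
    else:
        out = np.clip((pix - lo) / (hi - lo), 0.0, 1.0)
    return replace(image, pixels=out, normalized=True)


def detect_and_inpaint_markers(
    image: UltrasoundImage,
    threshold: float = 0.98,
    max_area: int = 30,
    tol: float = 1e-6,
) -> tuple[UltrasoundImage, np.ndarray]:
    """Mask near-saturated small components and harmonically inpaint them.

    Caliper dots burnt into B-mode stills are small near-saturated blobs.
    Connected components of pixels >= ``threshold`` (of the normalized
    range) with at most ``max_area`` pixels are masked; larger saturated
    regions (e.g. the adventitia band) are left alone.  Masked pixels are
    replaced by iterated 4-neighbour averaging (discrete harmonic infill)
    from the unmasked surroundings, to convergence ``tol``.

    Returns the inpainted image and the boolean marker mask.  Idempotent:
    inpainted values lie strictly below saturation.
    """
    pix = image.pixels.astype(float)
    if not image.normalized:
        threshold = threshold * 255.0
    saturated = pix >= threshold
    labels, n = ndimage.label(saturated)
    mask = np.zeros(pix.shape, dtype=bool)
    if n:
        areas = ndimage.sum_labels(np.ones_like(pix), labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(areas <= max_area) + 1
        mask = np.isin(labels, small)
    if not mask.any():
        return replace(image, pixels=pix), mask
    out = pix.copy()
    # seed masked cells with the global unmasked mean, then relax
    out[mask] = pix[~mask].mean() if (~mask).any() else 0.0
    kernel = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    for _ in range(10000):
        neigh_sum = ndimage.convolve(out, kernel, mode="nearest")
        neigh_cnt = ndimage.convolve(np.ones_like(out), kernel, mode="nearest")
        new = neigh_sum / neigh_cnt
        delta = np.abs(new[mask] - out[mask]).max()
        out[mask] = new[mask]
        if delta < tol:
            break
    return replace(image, pixels=out), mask


def rasterize_roi(polygon: np.ndarray, image_shape: tuple[int, int]) -> RoiRegion:
    """Rasterize a closed polygon into the pixel set Omega.

    A pixel belongs to Omega when its center (integer ``(row, col)``)
    lies inside or on the boundary of the closed polygon (even-odd fill,
    boundary inclusive).  Vertices must lie within the image bounds.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (row, col) vertices")
    nrow, ncol = image_shape
    if (poly[:, 0].min() < 0 or poly[:, 1].min() < 0
            or poly[:, 0].max() > nrow - 1 or poly[:, 1].max() > ncol - 1):
        raise ValueError("polygon vertices fall outside the image bounds")
    shp = shapely.Polygon(poly[:, ::-1])  # shapely is (x, y) = (col, row)
    if shp.area == 0:
        raise ValueError("degenerate (zero-area) polygon")
    r0, r1 = int(np.floor(poly[:, 0].min())), int(np.ceil(poly[:, 0].max()))
    c0, c1 = int(np.floor(poly[:, 1].min())), int(np.ceil(poly[:, 1].max()))
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    pts = shapely.points(cc.ravel(), rr.ravel())
    inside = shapely.covers(shp, pts).reshape(rr.shape)
    mask = np.zeros(image_shape, dtype=bool)
    mask[r0:r1 + 1, c0:c1 + 1] = inside
    return RoiRegion(polygon=poly, mask=mask)


def crop_to_roi(
    image: UltrasoundImage, roi: RoiRegion, margin_px: int = 56
) -> tuple[UltrasoundImage, RoiRegion]:
    """Crop image and ROI to the ROI bounding box plus ``margin_px``.

    The margin (default 56 px, the total support of three undecimated
    Haar levels) keeps border effects of the wavelet filter bank away
    from Omega.  The crop is clamped at the image borders; Omega
    membership and |Omega| are preserved, coordinates are translated.
    """
    rows, cols = np.nonzero(roi.mask)
    r0 = max(rows.min() - margin_px, 0)
    r1 = min(rows.max() + margin_px, image.shape[0] - 1)
    c0 = max(cols.min() - margin_px, 0)
    c1 = min(cols.max() + margin_px, image.shape[1] - 1)
    sub = image.pixels[r0:r1 + 1, c0:c1 + 1]
    new_img = replace(image, pixels=sub)
    new_roi = RoiRegion(
        polygon=roi.polygon - [r0, c0],
        mask=roi.mask[r0:r1 + 1, c0:c1 + 1],
    )
    return new_img, new_roi


def load_roi_json(path: str | Path) -> np.ndarray:
    """Load a ROI polygon from ``{"image": ..., "polygon": [[row, col], ...]}``."""
    with open(path) as fh:
        data = json.load(fh)
    return np.asarray(data["polygon"], dtype=float)


def save_roi_json(path: str | Path, image_name: str, polygon: np.ndarray) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"image": image_name, "polygon": np.asarray(polygon).tolist()},
            fh, indent=None, separators=(",", ":"),
        )
        fh.write("\n")
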