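"""Texture features inside a vessel-wall ROI.

Computes the 152-feature inventory used throughout the pipeline:

* first-order statistics: intensity mean ``mu`` and standard deviation
  ``sigma`` over the ROI pixel set Omega (population formulas, divisor
  |Omega|);
* 140 Haralick descriptors ``H_{d,theta,a}`` from gray-level
  co-occurrence matrices (GLCM) at displacements d in {1..5} pixels and
  directions theta in {0, 45, 90, 135} degrees, with 7 scalar measures
  each (inverse difference moment, correlation, contrast, maximum,
  energy, dissimilarity, entropy);
* 10 undecimated (a-trous) Haar wavelet-frame energies ``W_{i,j}``
  (3 levels x 3 orientations) plus the low-pass energy ``W_0``.

All statistics use only pixels of Omega; the wavelet sub-bands are
computed on the surrounding image (so Omega pixels see true neighbours)
and then averaged over Omega.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RoiRegion, UltrasoundImage

NG_DEFAULT = 16
DISTANCES = (1, 2, 3, 4, 5)
THETAS = (0, 45, 90, 135)
N_MEASURES = 7
WAVELET_LEVELS = 3

#: unit displacement (drow, dcol) per direction; 0 deg = up, 45 = up-right,
#: 90 = right, 135 = down-right.
THETA_OFFSETS = {0: (-1, 0), 45: (-1, 1), 90: (0, 1), 135: (1, 1)}


def feature_names() -> list[str]:
    """Canonical ordering of the 152 feature names."""
    names = ["mu", "sigma"]
    names += [
        f"H_d{d}_t{t}_a{a}" for d in DISTANCES for t in THETAS for a in range(1, 8)
    ]
    names += ["W0"]
    names += [f"W_{i}_{j}" for i in range(1, 4) for j in range(1, 4)]
    return names


FEATURE_NAMES: list[str] = feature_names()


@dataclass
class TextureParams:
    """Knobs of the feature extractor; defaults match the pipeline's use."""

    ng: int = NG_DEFAULT
    distances: tuple[int, ...] = DISTANCES
    thetas: tuple[int, ...] = THETAS
    symmetric: bool = False  # directed GLCM by default
    quant_range: str = "roi"  # "roi" (min-max over Omega) or "unit" ([0, 1])
    boundary: str = "mirror"  # wavelet boundary: "mirror" or "periodic"
    levels: int = WAVELET_LEVELS


@dataclass
class QuantizedRoi:
    """Integer levels in {0..Ng-1} over Omega; values outside are ignored."""

    levels: np.ndarray
    mask: np.ndarray
    ng: int
    bin_edges: np.ndarray


@dataclass
class GlcmMatrix:
    """Normalized Ng x Ng co-occurrence matrix for one (d, theta)."""

    P: np.ndarray
    d: int
    theta: int
    Z: int
    directed: bool


@dataclass
class WaveletPyramid:
    """Undecimated Haar sub-bands; every band keeps the input shape."""

    f_levels: list[np.ndarray]  # f^(0) .. f^(levels)
    d_bands: dict[tuple[int, int], np.ndarray]  # (level i, orientation j)
    boundary: str


@dataclass
class FeatureVector:
    """The 152 named texture values for one image ROI."""

    values: dict[str, float]
    image_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        if list(self.values) != FEATURE_NAMES:
            raise ValueError("feature vector must hold the 152 canonical names in order")
        arr = np.fromiter(self.values.values(), dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature values must be finite")

    def to_array(self) -> np.ndarray:
        return np.fromiter(self.values.values(), dtype=float)


# ---------------------------------------------------------------------------
# first-order statistics and quantization


def first_order_stats(image: UltrasoundImage, roi: RoiRegion) -> tuple[float, float]:
    """Population mean and SD of the intensities over Omega."""
    vals = image.pixels[roi.mask].astype(float)
    if vals.size == 0:
        raise ValueError("empty ROI")
    mu = float(vals.mean())
    sigma = float(np.sqrt(np.mean((vals - mu) ** 2)))
    return mu, sigma


def quantize(
    image: UltrasoundImage,
    roi: RoiRegion,
    ng: int = NG_DEFAULT,
    quant_range: str = "roi",
) -> QuantizedRoi:
    """Quantize ROI intensities into ``ng`` uniform bins.

    Bins span Omega's own [min, max] by default (making the GLCM block
    invariant to intensity shifts); ``quant_range='unit'`` uses the fixed
    [0, 1] normalized range instead.  The maximum maps to level ng-1; a
    constant ROI maps wholly to level 0.
    """
    if ng < 2:
        raise ValueError("ng must be >= 2")
    vals = image.pixels[roi.mask].astype(float)
    if vals.size == 0:
        raise ValueError("empty ROI")
    if quant_range == "roi":
        lo, hi = float(vals.min()), float(vals.max())
    elif quant_range == "unit":
        lo, hi = 0.0, 1.0
    else:
        raise ValueError(f"unknown quant_range {quant_range!r}")
    edges = np.linspace(lo, hi, ng + 1)
    levels = np.zeros(image.pixels.shape, dtype=np.int64)
    if hi > lo:
        lv = np.floor((image.pixels.astype(float) - lo) / (hi - lo) * ng).astype(np.int64)
        levels = np.clip(lv, 0, ng - 1)
    return QuantizedRoi(levels=levels, mask=roi.mask.copy(), ng=ng, bin_edges=edges)


# ---------------------------------------------------------------------------
# GLCM


def compute_glcm(
    q: QuantizedRoi, d: int, theta: int, directed: bool = True
) -> GlcmMatrix:
    """Co-occurrence matrix of level pairs at displacement d along theta.

    A pair is counted when both pixels lie in Omega and the second is at
    offset ``d * u_theta`` from the first.  Directed mode counts ordered
    pairs; symmetric mode also counts the reverse.  Entries are
    normalized by the raw pair count Z to sum to 1.
    """
    if theta not in THETA_OFFSETS:
        raise ValueError(f"theta must be one of {sorted(THETA_OFFSETS)}")
    dr, dc = THETA_OFFSETS[theta]
    dr, dc = dr * d, dc * d
    lev, mask = q.levels, q.mask
    nrow, ncol = mask.shape
    # source window such that (r+dr, c+dc) stays in bounds
    r0, r1 = max(0, -dr), min(nrow, nrow - dr)
    c0, c1 = max(0, -dc), min(ncol, ncol - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"no valid pixel pair in ROI for d={d}, theta={theta}")
    src_m = mask[r0:r1, c0:c1]
    dst_m = mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = src_m & dst_m
    a = lev[r0:r1, c0:c1][valid]
    b = lev[r0 + dr:r1 + dr, c0 + dc:c1 + dc][valid]
    counts = np.bincount(a * q.ng + b, minlength=q.ng * q.ng).reshape(q.ng, q.ng)
    counts = counts.astype(float)
    if not directed:
        counts = counts + counts.T
    Z = int(counts.sum())
    if Z == 0:
        raise ValueError(f"no valid pixel pair in ROI for d={d}, theta={theta}")
    return GlcmMatrix(P=counts / Z, d=d, theta=theta, Z=Z, directed=directed)


def haralick_measures(glcm: GlcmMatrix) -> np.ndarray:
    """The 7 scalar GLCM measures H1..H7.

    H1 inverse difference moment, H2 correlation (0 when either marginal
    variance vanishes), H3 contrast, H4 maximum, H5 energy (angular
    second moment), H6 dissimilarity, H7 entropy (-sum P ln P, with
    0 ln 0 = 0).
    """
    P = glcm.P
    ng = P.shape[0]
    a = np.arange(ng)[:, None]
    b = np.arange(ng)[None, :]
    diff = np.abs(a - b)
    off = diff > 0
    h1 = float((P[off] / diff[off] ** 2).sum())
    mu_a = float((a * P).sum())
    mu_b = float((b * P).sum())
    var_a = float(((a - mu_a) ** 2 * P).sum())
    var_b = float(((b - mu_b) ** 2 * P).sum())
    if var_a <= 0 or var_b <= 0:
        h2 = 0.0  # constant marginal: correlation undefined, flagged as 0
    else:
        h2 = float((((a - mu_a) * (b - mu_b)) * P).sum() / np.sqrt(var_a * var_b))
    h3 = float((diff**2 * P).sum())
    h4 = float(P.max())
    h5 = float((P**2).sum())
    h6 = float((diff * P).sum())
    nz = P > 0
    h7 = float(-(P[nz] * np.log(P[nz])).sum())
    return np.array([h1, h2, h3, h4, h5, h6, h7])


def haralick_all(
    q: QuantizedRoi,
    distances: tuple[int, ...] = DISTANCES,
    thetas: tuple[int, ...] = THETAS,
    directed: bool = True,
) -> np.ndarray:
    """All ``H_{d,theta,a}`` values in canonical (d, theta, a) order.

    Thin ROIs can admit zero pixel pairs at large vertical displacements;
    such degenerate configurations are imputed from the largest smaller d
    available for the same theta (with a warning), so the feature
    inventory stays fixed.
    """
    per_theta: dict[int, dict[int, np.ndarray]] = {t: {} for t in thetas}
    for t in thetas:
        for d in distances:
            try:
                per_theta[t][d] = haralick_measures(compute_glcm(q, d, t, directed))
            except ValueError:
                per_theta[t][d] = None  # type: ignore[assignment]
    out = []
    for d in distances:
        for t in thetas:
            vals = per_theta[t][d]
            if vals is None:
                donors = [dd for dd in distances if dd < d and per_theta[t][dd] is not None]
                if not donors:
                    raise ValueError(
                        f"ROI admits no pixel pair at any displacement for theta={t}"
                    )
                donor = max(donors)
                warnings.warn(
                    f"no pixel pairs for d={d}, theta={t}; imputed from d={donor}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                vals = per_theta[t][donor]
            out.append(vals)
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# Haar wavelet frame (a-trous)


def _shift_index(n: int, s: int, boundary: str) -> np.ndarray:
    """Index array for x[n + s] under the chosen boundary rule."""
    idx = np.arange(n) + s
    if boundary == "periodic":
        return idx % n
    if boundary == "mirror":
        # half-sample symmetric reflection: ..., x1, x0 | x0, x1, ...
        period = 2 * n
        idx = idx % period
        return np.where(idx < n, idx, period - 1 - idx)
    raise ValueError(f"unknown boundary {boundary!r}")


def _haar_filter_pair(x: np.ndarray, axis: int, s: int, boundary: str):
    """One a-trous Haar step along ``axis``: low-pass and high-pass.

    Taps (1/2, 1/2) and (-1/2, 1/2) at offsets {0, s} with s = 2^i.
    """
    idx = _shift_index(x.shape[axis], s, boundary)
    shifted = np.take(x, idx, axis=axis)
    return (x + shifted) / 2.0, (shifted - x) / 2.0


def haar_frame_decompose(
    image: UltrasoundImage | np.ndarray,
    levels: int = WAVELET_LEVELS,
    boundary: str = "mirror",
) -> WaveletPyramid:
    """Undecimated separable Haar decomposition over ``levels`` scales.

    Per level i (0-based), the filters are upsampled by 2^i (holes
    inserted) instead of decimating the signal, so every sub-band keeps
    the input's shape.  Orientations: j=1 high-pass along rows (g_x h_y),
    j=2 along columns (h_x g_y), j=3 both (g_x g_y).
    """
    f = image.pixels if isinstance(image, UltrasoundImage) else image
    f = np.asarray(f, dtype=float)
    support = 2**levels * 2
    if f.shape[0] < support or f.shape[1] < support:
        raise ValueError(f"image smaller than the {levels}-level filter support ({support} px)")
    f_levels = [f]
    d_bands: dict[tuple[int, int], np.ndarray] = {}
    for i in range(levels):
        s = 2**i
        cur = f_levels[-1]
        lo_x, hi_x = _haar_filter_pair(cur, axis=0, s=s, boundary=boundary)
        ll, lh = _haar_filter_pair(lo_x, axis=1, s=s, boundary=boundary)
        hl, hh = _haar_filter_pair(hi_x, axis=1, s=s, boundary=boundary)
        f_levels.append(ll)
        d_bands[(i + 1, 1)] = hl  # g_x h_y
        d_bands[(i + 1, 2)] = lh  # h_x g_y
        d_bands[(i + 1, 3)] = hh  # g_x g_y
    return WaveletPyramid(f_levels=f_levels, d_bands=d_bands, boundary=boundary)


def wavelet_energies(pyr: WaveletPyramid, roi: RoiRegion | np.ndarray) -> dict[str, float]:
    """Mean sub-band energies over Omega: W0 and W_{i,j}.

    ``W_{i,j} = ||d_j^(i)||^2 / |Omega|`` with the norm restricted to
    ROI pixels; ``W0`` is the same for the deepest low-pass band.
    """
    mask = roi.mask if isinstance(roi, RoiRegion) else np.asarray(roi, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty ROI")
    out = {"W0": float((pyr.f_levels[-1][mask] ** 2).sum() / n)}
    levels = len(pyr.f_levels) - 1
    for i in range(1, levels + 1):
        for j in (1, 2, 3):
            out[f"W_{i}_{j}"] = float((pyr.d_bands[(i, j)][mask] ** 2).sum() / n)
    return out


# ---------------------------------------------------------------------------
# assembly


def extract_feature_vector(
    image: UltrasoundImage,
    roi: RoiRegion,
    params: TextureParams | None = None,
) -> FeatureVector:
    """All 152 features of one image ROI, in canonical order."""
    params = params or TextureParams()
    mu, sigma = first_order_stats(image, roi)
    q = quantize(image, roi, params.ng, params.quant_range)
    har = haralick_all(q, params.distances, params.thetas, directed=not params.symmetric)
    pyr = haar_frame_decompose(image, params.levels, params.boundary)
    wav = wavelet_energies(pyr, roi)
    values: dict[str, float] = {"mu": mu, "sigma": sigma}
    idx = 0
    for d in params.distances:
        for t in params.thetas:
            for a in range(1, 8):
                values[f"H_d{d}_t{t}_a{a}"] = float(har[idx])
                idx += 1
    values["W0"] = wav["W0"]
    for i in range(1, params.levels + 1):
        for j in (1, 2, 3):
            values[f"W_{i}_{j}"] = wav[f"W_{i}_{j}"]
    return FeatureVector(values=values, image_id=image.image_id, patient_id=image.patient_id)


def feature_table(cohort, params: TextureParams | None = None, preprocess: bool = True) -> pd.DataFrame:
    """One row per image: ids, group label, and the 152 feature columns.

    ``cohort`` is a :class:`~carotexture.synthetic.CohortDataset` (or any
    object with ``iter_images()`` yielding (image, roi_polygon,
    group_label)).  With ``preprocess=True`` each image runs through the
    standard chain (percentile normalization, marker inpainting, crop to
    the ROI with wavelet-safe margin) before extraction.
    """
    from .io import crop_to_roi, detect_and_inpaint_markers, normalize_intensity, rasterize_roi

    params = params or TextureParams()
    rows = []
    for image, polygon, group_label in cohort.iter_images():
        if polygon is None:
            raise ValueError(f"missing ROI for image {image.image_id}")
        if preprocess:
            image = normalize_intensity(image)
            image, _ = detect_and_inpaint_markers(image)
        roi = rasterize_roi(polygon, image.shape)
        image, roi = crop_to_roi(image, roi)
        fv = extract_feature_vector(image, roi, params)
        row = {"image_id": fv.image_id, "patient_id": fv.patient_id, "group_label": group_label}
        row.update(fv.values)
        rows.append(row)
    cols = ["image_id", "patient_id", "group_label"] + FEATURE_NAMES
    return pd.DataFrame(rows, columns=cols)
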