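"""Synthetic carotid-wall cohort generator.

Emulates the data the pipeline expects when real scans are unavailable:
per patient, a few longitudinal B-mode far-wall images with a thin
intima-media ROI strip (>= 10 mm long at the configured scale, 6-10 px
thick), bright caliper-dot artifacts, group labels (PA = primary
aldosteronism, EH = essential hypertension, C = normotensive control),
and a clinical covariate table whose per-group means/SDs follow the
published group characteristics of such cohorts.

The wall image is a smooth layered depth profile (dark lumen, bright
intima-media strip, brighter adventitia) multiplied by a correlated
log-normal speckle field.  Group differences are planted through the
strip's mean level, the speckle contrast (SD/mean) and the speckle
correlation length; defaults separate hypertensives from controls
strongly and PA from EH only weakly, so that no single feature screens
PA vs EH while a multivariate classifier still can.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .io import UltrasoundImage, load_roi_json, save_roi_json

GROUPS = ("PA", "EH", "C")

#: covariates measured only in hypertensive patients
HTN_ONLY = ("aldosterone", "renin", "arr")


@dataclass
class GroupTextureParams:
    """Texture process of one study group's wall strip."""

    group_label: str
    mean_level: float  # strip intensity, 0-255
    speckle_contrast: float  # SD/mean of the multiplicative speckle
    correlation_length_px: float  # Gaussian blur scale of the speckle field
    wall_thickness_px: tuple[int, int] = (6, 10)  # inclusive range

    def __post_init__(self) -> None:
        if self.group_label not in GROUPS:
            raise ValueError(f"unknown group {self.group_label!r}")
        if self.speckle_contrast < 0:
            raise ValueError("speckle_contrast must be >= 0")
        if self.correlation_length_px <= 0:
            raise ValueError("correlation_length_px must be > 0")
        if self.wall_thickness_px[0] < 6:
            raise ValueError("wall strips thinner than 6 px are not generated")


def default_texture_params() -> dict[str, GroupTextureParams]:
    """Planted group texture processes.

    Hypertensive walls (PA, EH) are brighter, noisier and finer-grained
    than control walls; PA differs from EH only marginally.
    """
    return {
        "PA": GroupTextureParams("PA", mean_level=146.0, speckle_contrast=0.36,
                                 correlation_length_px=1.12),
        "EH": GroupTextureParams("EH", mean_level=145.0, speckle_contrast=0.35,
                                 correlation_length_px=1.2),
        "C": GroupTextureParams("C", mean_level=120.0, speckle_contrast=0.25,
                                correlation_length_px=2.0),
    }


# per-group clinical covariate distributions: normal(mean, sd),
# lognormal(median, q1, q3), bernoulli(p), or missing
CLINICAL_DEFAULTS: dict[str, dict[str, tuple]] = {
    "age": {"PA": ("normal", 57, 8), "EH": ("normal", 55, 7), "C": ("normal", 54, 8)},
    "sex_female": {"PA": ("bernoulli", 0.39), "EH": ("bernoulli", 0.38), "C": ("bernoulli", 0.48)},
    "bmi": {"PA": ("normal", 29.0, 3.9), "EH": ("normal", 28.4, 4.6), "C": ("normal", 26.6, 4.2)},
    "office_sbp": {"PA": ("normal", 164, 23), "EH": ("normal", 170, 30), "C": ("normal", 125, 15)},
    "office_dbp": {"PA": ("normal", 97, 14), "EH": ("normal", 99, 17), "C": ("normal", 78, 9)},
    "smoking": {"PA": ("bernoulli", 0.33), "EH": ("bernoulli", 0.38), "C": ("bernoulli", 0.24)},
    "cholesterol": {"PA": ("normal", 4.98, 1.05), "EH": ("normal", 5.28, 1.00), "C": ("normal", 5.59, 0.97)},
    "ldl": {"PA": ("normal", 2.99, 0.87), "EH": ("normal", 3.06, 0.77), "C": ("normal", 3.19, 0.84)},
    "hdl": {"PA": ("normal", 1.30, 0.34), "EH": ("normal", 1.38, 0.33), "C": ("normal", 1.61, 0.40)},
    "triglycerides": {"PA": ("normal", 1.54, 0.54), "EH": ("normal", 1.85, 0.97), "C": ("normal", 1.73, 1.02)},
    "glucose": {"PA": ("normal", 4.9, 0.5), "EH": ("normal", 5.2, 0.9), "C": ("normal", 5.0, 0.6)},
    "cca_imt": {"PA": ("normal", 0.987, 0.152), "EH": ("normal", 0.892, 0.155), "C": ("normal", 0.812, 0.126)},
    "cb_imt": {"PA": ("normal", 1.157, 0.243), "EH": ("normal", 1.131, 0.275), "C": ("normal", 0.994, 0.203)},
    "combined_imt": {"PA": ("normal", 1.066, 0.162), "EH": ("normal", 0.974, 0.196), "C": ("normal", 0.884, 0.141)},
    # skewed humoral markers: median (Q1-Q3), log-normal; absent in controls
    "aldosterone": {"PA": ("lognormal", 38.9, 27.4, 64.9), "EH": ("lognormal", 15.7, 9.2, 23.1), "C": ("missing",)},
    "renin": {"PA": ("lognormal", 0.36, 0.25, 0.56), "EH": ("lognormal", 0.66, 0.37, 1.68), "C": ("missing",)},
    "arr": {"PA": ("lognormal", 103, 69, 157), "EH": ("lognormal", 17, 8, 41), "C": ("missing",)},
}

CLINICAL_COVARIATES = list(CLINICAL_DEFAULTS)


@dataclass
class SyntheticConfig:
    """Cohort-level generation parameters.

    Defaults mirror the study design the pipeline targets: 33 PA, 52 EH
    and 33 control patients with 4 longitudinal images each (2 angles x
    2 sides), far-wall ROI strips at least 10 mm long at 10 px/mm.
    """

    n_patients: dict[str, int] = field(default_factory=lambda: {"PA": 33, "EH": 52, "C": 33})
    images_per_patient: int = 4
    image_size: tuple[int, int] = (128, 160)  # (rows, cols)
    pixels_per_mm: float = 10.0
    roi_length_mm: float = 11.0
    marker_count: int = 3
    marker_radius: int = 2
    # between-patient variability of the texture process (random effects,
    # drawn once per patient): additive SD on the strip mean level and
    # log-normal SDs on speckle contrast and correlation length
    jitter_mean_level: float = 3.0
    jitter_log_contrast: float = 0.08
    jitter_log_corr: float = 0.08
    texture_params: dict[str, GroupTextureParams] = field(default_factory=default_texture_params)
    clinical_params: dict[str, dict[str, tuple]] = field(default_factory=lambda: dict(CLINICAL_DEFAULTS))
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_patients.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("group sizes must be >= 0")
        if sum(self.n_patients.values()) < 1:
            raise ValueError("cohort must contain at least one patient")
        if self.images_per_patient < 1:
            raise ValueError("images_per_patient must be >= 1")
        if self.roi_length_mm < 10.0:
            raise ValueError("ROI strips shorter than 10 mm are not generated")
        roi_len = int(round(self.roi_length_mm * self.pixels_per_mm))
        if roi_len + 4 > self.image_size[1]:
            raise ValueError("image too narrow for the configured ROI length")
        max_t = max(p.wall_thickness_px[1] for p in self.texture_params.values())
        if self.image_size[0] < max_t + 40:
            raise ValueError("image too short for the wall layout")

    @property
    def roi_length_px(self) -> int:
        return int(round(self.roi_length_mm * self.pixels_per_mm))


@dataclass
class Patient:
    patient_id: str
    group_label: str
    images: list[UltrasoundImage]
    polygons: list[np.ndarray]
    clinical: dict[str, float]


@dataclass
class CohortDataset:
    """Patients with labels, images, ROI polygons and clinical covariates."""

    patients: list[Patient]
    config: SyntheticConfig | None = None

    @property
    def n_images(self) -> int:
        return sum(len(p.images) for p in self.patients)

    def iter_images(self):
        for p in self.patients:
            for img, poly in zip(p.images, p.polygons):
                yield img, poly, p.group_label

    def clinical_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {"patient_id": p.patient_id, "group_label": p.group_label}
            row.update(p.clinical)
            rows.append(row)
        return pd.DataFrame(rows, columns=["patient_id", "group_label"] + CLINICAL_COVARIATES)

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"patient_id": p.patient_id, "group_label": p.group_label} for p in self.patients]
        )

    def save(self, outdir: str | Path) -> None:
        """Write images/*.png, rois/*.json, clinical.csv, labels.csv, manifest.json."""
        outdir = Path(outdir)
        (outdir / "images").mkdir(parents=True, exist_ok=True)
        (outdir / "rois").mkdir(exist_ok=True)
        image_names = []
        for p in self.patients:
            for img, poly in zip(p.images, p.polygons):
                name = f"{img.image_id}.png"
                Image.fromarray(img.pixels.astype(np.uint8), mode="L").save(outdir / "images" / name)
                save_roi_json(outdir / "rois" / f"{img.image_id}.json", name, poly)
                image_names.append({"image": name, "patient_id": p.patient_id})
        self.clinical_frame().to_csv(outdir / "clinical.csv", index=False)
        self.labels_frame().to_csv(outdir / "labels.csv", index=False)
        manifest = {"images": image_names}
        if self.config is not None:
            cfg = asdict(self.config)
            cfg["texture_params"] = {g: asdict(tp) for g, tp in self.config.texture_params.items()}
            manifest["config"] = cfg
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=list)

    @classmethod
    def load(cls, indir: str | Path) -> "CohortDataset":
        indir = Path(indir)
        with open(indir / "manifest.json") as fh:
            manifest = json.load(fh)
        labels = pd.read_csv(indir / "labels.csv").set_index("patient_id")["group_label"]
        clinical = pd.read_csv(indir / "clinical.csv").set_index("patient_id")
        by_patient: dict[str, Patient] = {}
        for entry in manifest["images"]:
            pid = entry["patient_id"]
            stem = Path(entry["image"]).stem
            img = Image.open(indir / "images" / entry["image"])
            arr = np.asarray(img, dtype=np.uint8)
            poly = load_roi_json(indir / "rois" / f"{stem}.json")
            if pid not in by_patient:
                crow = clinical.loc[pid]
                clin = {c: float(crow[c]) if pd.notna(crow[c]) else float("nan")
                        for c in CLINICAL_COVARIATES}
                by_patient[pid] = Patient(pid, str(labels.loc[pid]), [], [], clin)
            by_patient[pid].images.append(
                UltrasoundImage(arr, patient_id=pid, image_id=stem))
            by_patient[pid].polygons.append(poly)
        return cls(patients=list(by_patient.values()))


# ---------------------------------------------------------------------------
# image synthesis


def _speckle_field(shape, contrast: float, corr_len: float, rng: np.random.Generator) -> np.ndarray:
    """Correlated multiplicative log-normal speckle with mean 1, SD/mean = contrast."""
    if contrast == 0:
        return np.ones(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=corr_len, mode="wrap")
    z = (smooth - smooth.mean()) / smooth.std()
    s = np.sqrt(np.log1p(contrast**2))
    return np.exp(s * z - s**2 / 2.0)


def synth_wall_image(
    params: GroupTextureParams,
    size: tuple[int, int] = (128, 160),
    pixels_per_mm: float = 10.0,
    seed: int | np.random.Generator = 0,
    roi_length_px: int | None = None,
) -> tuple[UltrasoundImage, np.ndarray]:
    """One longitudinal far-wall image plus its ROI polygon.

    Depth layout (top to bottom): anechoic lumen, the bright intima-media
    strip whose texture carries the group signal, a brighter adventitia
    band, then homogeneous tissue.  The ROI polygon traces the strip with
    thickness drawn from ``params.wall_thickness_px`` and length at least
    10 mm at the given scale.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nrow, ncol = size
    roi_len = roi_length_px or int(round(11.0 * pixels_per_mm))
    if roi_len < int(round(10.0 * pixels_per_mm)):
        raise ValueError("ROI length below the 10 mm minimum")
    if roi_len + 4 > ncol:
        raise ValueError("image too narrow for the wall strip")
    tmin, tmax = params.wall_thickness_px
    thickness = int(rng.integers(tmin, tmax + 1))
    adv_h = 6
    r0_nominal = int(0.55 * nrow)
    r0 = r0_nominal + int(rng.integers(-3, 4))
    if r0 < 12 or r0 + thickness + adv_h + 10 > nrow:
        raise ValueError("wall strip does not fit the image height")

    profile = np.full(nrow, 80.0)  # deep tissue
    profile[:r0] = 25.0  # lumen
    profile[r0:r0 + thickness] = params.mean_level  # intima-media strip
    profile[r0 + thickness:r0 + thickness + adv_h] = 210.0  # adventitia
    profile = ndimage.gaussian_filter1d(profile, sigma=1.0, mode="nearest")
    base = np.tile(profile[:, None], (1, ncol))

    speckle = _speckle_field(size, params.speckle_contrast, params.correlation_length_px, rng)
    img = np.clip(base * speckle, 0.0, 255.0)
    img = np.round(img).astype(np.uint8)

    c0 = (ncol - roi_len) // 2
    polygon = np.array([
        [r0, c0],
        [r0, c0 + roi_len - 1],
        [r0 + thickness - 1, c0 + roi_len - 1],
        [r0 + thickness - 1, c0],
    ], dtype=float)
    return UltrasoundImage(np.asarray(img)), polygon


def plant_markers(
    image: UltrasoundImage,
    n: int,
    seed: int | np.random.Generator = 0,
    radius: int = 2,
) -> tuple[UltrasoundImage, np.ndarray]:
    """Stamp ``n`` near-saturated caliper dots; return image and truth mask."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pix = image.pixels.copy()
    mask = np.zeros(pix.shape, dtype=bool)
    if n == 0:
        return UltrasoundImage(pix, patient_id=image.patient_id, image_id=image.image_id,
                               normalized=image.normalized), mask
    nrow, ncol = pix.shape
    margin = radius + 2
    centers: list[tuple[int, int]] = []
    min_sep = 2 * radius + 3  # keep dots as distinct components
    for _ in range(10000):
        if len(centers) == n:
            break
        r = int(rng.integers(margin, nrow - margin))
        c = int(rng.integers(margin, ncol - margin))
        if all(abs(r - rr) + abs(c - cc) >= min_sep for rr, cc in centers):
            centers.append((r, c))
    if len(centers) < n:
        raise ValueError("could not place the requested number of markers")
    rr, cc = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    sat = 1.0 if image.normalized else 255
    for r, c in centers:
        disk = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
        mask |= disk
    pix[mask] = sat
    return UltrasoundImage(pix, patient_id=image.patient_id, image_id=image.image_id,
                           normalized=image.normalized), mask


# ---------------------------------------------------------------------------
# clinical covariates


def _draw_covariate(spec: tuple, rng: np.random.Generator) -> float:
    kind = spec[0]
    if kind == "normal":
        _, mean, sd = spec
        return float(rng.normal(mean, sd))
    if kind == "bernoulli":
        return float(rng.random() < spec[1])
    if kind == "lognormal":
        _, median, q1, q3 = spec
        mu = np.log(median)
        sigma = np.log(q3 / q1) / (2 * 0.6744897501960817)  # IQR of a standard normal
        return float(np.exp(rng.normal(mu, sigma)))
    if kind == "missing":
        return float("nan")
    raise ValueError(f"unknown covariate distribution {kind!r}")


def generate_clinical(
    group_label: str,
    clinical_params: dict[str, dict[str, tuple]] | None = None,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Draw one patient's covariates from the per-group marginals.

    Covariates are sampled independently; controls get missing
    aldosterone / renin / ARR (those assays are not run on
    normotensives).
    """
    if group_label not in GROUPS:
        raise ValueError(f"unknown group {group_label!r}")
    clinical_params = clinical_params or CLINICAL_DEFAULTS
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    record: dict[str, float] = {}
    for cov, per_group in clinical_params.items():
        if group_label not in per_group and cov in HTN_ONLY:
            record[cov] = float("nan")
            continue
        record[cov] = _draw_covariate(per_group[group_label], rng)
    return record


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(config: SyntheticConfig | None = None) -> CohortDataset:
    """Deterministically generate the full synthetic cohort.

    Every patient draws from an independent child stream of the config
    seed, so the cohort is bit-identical across calls with the same
    config and unchanged when unrelated parameters move.
    """
    config = config or SyntheticConfig()
    total = sum(config.n_patients.values())
    children = np.random.SeedSequence(config.seed).spawn(total)
    patients: list[Patient] = []
    k = 0
    for group in GROUPS:
        n = config.n_patients.get(group, 0)
        for i in range(n):
            rng = np.random.default_rng(children[k])
            k += 1
            pid = f"{group}{i + 1:03d}"
            base = config.texture_params[group]
            # patient-level random effects on the texture process
            tex = GroupTextureParams(
                group_label=group,
                mean_level=float(np.clip(
                    base.mean_level + config.jitter_mean_level * rng.standard_normal(),
                    40.0, 240.0)),
                speckle_contrast=float(base.speckle_contrast
                                       * np.exp(config.jitter_log_contrast * rng.standard_normal()))
                if base.speckle_contrast > 0 else 0.0,
                correlation_length_px=float(base.correlation_length_px
                                            * np.exp(config.jitter_log_corr * rng.standard_normal())),
                wall_thickness_px=base.wall_thickness_px,
            )
            images, polys = [], []
            for j in range(config.images_per_patient):
                img, poly = synth_wall_image(
                    tex, config.image_size, config.pixels_per_mm,
                    seed=rng, roi_length_px=config.roi_length_px,
                )
                img.patient_id = pid
                img.image_id = f"{pid}_img{j + 1}"
                if config.marker_count > 0:
                    img, _ = plant_markers(img, config.marker_count, seed=rng,
                                           radius=config.marker_radius)
                images.append(img)
                polys.append(poly)
            clinical = generate_clinical(group, config.clinical_params, seed=rng)
            patients.append(Patient(pid, group, images, polys, clinical))
    return CohortDataset(patients=patients, config=config)
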