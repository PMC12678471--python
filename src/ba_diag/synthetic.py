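"""Synthetic cohorts and ultrasound-like phantom images with ground truth.

Real sonograms and patient data for infant cholestasis work-ups are not
publicly distributable, so this module fabricates both at configurable
class separation:

- :func:`generate_cohort` draws a two-class (BA / non-BA) patient table:
  age in days, serum MMP-7 (log-normal per class, right-skewed like a real
  biomarker), and routine biochemistry.
- :func:`generate_image` renders a speckled gray-scale image containing
  one embedded structure — a hypoechoic (dark) gallbladder-like ellipse,
  or an echogenic (bright) triangular-cord-like triangle/band — whose
  contrast and size differ by class.  The exact rendered mask and its
  bounding box are returned as ground truth.
- :func:`generate_dataset` writes a complete on-disk dataset (PNG images,
  cohort CSV, ROI annotation JSON, ground-truth JSON, checksum manifest).

All randomness flows from ``numpy.random.SeedSequence(seed, patient_index,
view_index)`` so any subset of patients is reproducible independently.
The speckle model is Gaussian noise on a flat background, lightly blurred
to emulate the spatial correlation of ultrasound speckle; it is a test
phantom, not an acoustic simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import draw

from .errors import ConfigurationError
from .images import VIEWS

LABEL_BA = "BA"
LABEL_NON_BA = "non-BA"

#: Class-conditional log-normal MMP-7 parameters (natural-log median, sigma),
#: in ng/mL.  Medians 60 vs 8 straddle the 18 ng/mL clinical threshold and
#: give stratum positivity rates in the mid-90s% (BA) / low-teens% (non-BA).
DEFAULT_MMP7_PARAMS = {
    LABEL_BA: {"median": 60.0, "sigma": 0.7},
    LABEL_NON_BA: {"median": 8.0, "sigma": 0.7},
}

#: Uniform integer age range in days; spans both MMP-7 age strata
#: (≤30 d and >30 d) while respecting the <150 d eligibility window.
DEFAULT_AGE_PARAMS = {
    LABEL_BA: {"low": 20, "high": 120},
    LABEL_NON_BA: {"low": 20, "high": 120},
}

#: Log-normal biochemistry medians (units as in routine liver panels);
#: BA patients run higher GGT and conjugated bilirubin.
DEFAULT_BIOCHEM_PARAMS = {
    "tb": {LABEL_BA: (160.0, 0.35), LABEL_NON_BA: (140.0, 0.35)},
    "db": {LABEL_BA: (120.0, 0.40), LABEL_NON_BA: (95.0, 0.40)},
    "ggt": {LABEL_BA: (400.0, 0.80), LABEL_NON_BA: (130.0, 0.80)},
    "alt": {LABEL_BA: (130.0, 0.70), LABEL_NON_BA: (130.0, 0.70)},
    "ast": {LABEL_BA: (190.0, 0.70), LABEL_NON_BA: (180.0, 0.70)},
    "tba": {LABEL_BA: (100.0, 0.30), LABEL_NON_BA: (98.0, 0.30)},
}

COHORT_COLUMNS = [
    "patient_id", "age_days", "mmp7_ng_ml", "label", "center_id",
    "tb", "db", "ggt", "alt", "ast", "tba",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic two-class cohort."""

    n_patients: int = 187
    prevalence: float = 0.299
    seed: int = 0
    mmp7_params: Mapping = field(default_factory=lambda: DEFAULT_MMP7_PARAMS)
    age_params: Mapping = field(default_factory=lambda: DEFAULT_AGE_PARAMS)
    biochem_params: Mapping = field(default_factory=lambda: DEFAULT_BIOCHEM_PARAMS)
    missing_view_rate: float = 0.0
    n_centers: int = 1

    def __post_init__(self):
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError("prevalence must lie in [0, 1]")
        if not 0.0 <= self.missing_view_rate < 1.0:
            raise ConfigurationError("missing_view_rate must lie in [0, 1)")
        for label, p in self.mmp7_params.items():
            if p["median"] <= 0 or p["sigma"] <= 0:
                raise ConfigurationError(f"mmp7 scale for {label} must be positive")
        for label, p in self.age_params.items():
            if not (1 <= p["low"] <= p["high"] <= 150):
                raise ConfigurationError("ages must lie within [1, 150] days")


# Per-view geometry defaults, as fractions of the image side so any
# image_size >= 32 px works.  Gallbladder: elongated dark ellipse.
# tc_branches: bright triangle (apex of fibrous cord at the portal
# bifurcation).  tc_transverse: bright oblique band anterior to the
# right portal vein.
_DEFAULT_GEOMETRY = {
    "gallbladder": {"kind": "ellipse", "axes_frac": (0.12, 0.22), "rotation_deg": 20.0},
    "tc_branches": {"kind": "triangle", "base_frac": 0.30, "height_frac": 0.18},
    "tc_transverse": {"kind": "band", "length_frac": 0.45, "thickness_frac": 0.07,
                      "angle_deg": 15.0},
}

_DEFAULT_CONTRAST = {"gallbladder": -45.0, "tc_branches": 35.0, "tc_transverse": 35.0}

#: Class effects on structure contrast and size.  In BA the gallbladder is
#: small/collapsed and less conspicuous; the triangular cord is prominent.
_DEFAULT_CLASS_EFFECT = {
    "gallbladder": {
        LABEL_BA: {"contrast": 0.45, "size": 0.55},
        LABEL_NON_BA: {"contrast": 1.0, "size": 1.0},
    },
    "tc_branches": {
        LABEL_BA: {"contrast": 1.6, "size": 1.2},
        LABEL_NON_BA: {"contrast": 0.35, "size": 0.8},
    },
    "tc_transverse": {
        LABEL_BA: {"contrast": 1.6, "size": 1.2},
        LABEL_NON_BA: {"contrast": 0.35, "size": 0.8},
    },
}


@dataclass(frozen=True)
class ImageSceneConfig:
    """Parameters of one synthetic ultrasound-like scene."""

    view: str = "gallbladder"
    image_size: tuple[int, int] = (128, 128)
    background_mean: float = 90.0
    background_std: float = 12.0
    structure_contrast: float | None = None  # default per view
    structure_geometry: Mapping | None = None  # default per view
    class_effect: Mapping | None = None  # default per view
    center_jitter_frac: float = 0.06
    speckle_blur_sigma: float = 0.8
    crop_pad: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ConfigurationError(f"unknown view {self.view!r}")
        r, c = self.image_size
        if r < 32 or c < 32:
            raise ConfigurationError("image_size must be at least 32x32")
        if self.background_std <= 0:
            raise ConfigurationError("background_std must be positive")
        if self.structure_contrast is None:
            object.__setattr__(self, "structure_contrast", _DEFAULT_CONTRAST[self.view])
        if self.structure_geometry is None:
            object.__setattr__(self, "structure_geometry", _DEFAULT_GEOMETRY[self.view])
        if self.class_effect is None:
            object.__setattr__(self, "class_effect", _DEFAULT_CLASS_EFFECT[self.view])


@dataclass(frozen=True)
class GroundTruth:
    """Known truth for one rendered image."""

    label: str
    true_mask: np.ndarray
    true_crop: tuple[int, int, int, int]
    geometry: dict
    true_mmp7: float | None = None
    age_days: int | None = None


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _patient_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, index, stream)))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic cohort table, one row per patient.

    Labels are independent Bernoulli(prevalence); MMP-7 and biochemistry
    are class-conditional log-normals; ages are class-conditional uniform
    integers.  Deterministic given ``config.seed``: each patient has an
    independent RNG stream keyed by (seed, index).
    """
    rows = []
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        label = LABEL_BA if rng.random() < config.prevalence else LABEL_NON_BA
        mp = config.mmp7_params[label]
        ap = config.age_params[label]
        row = {
            "patient_id": f"p{i:05d}",
            "age_days": int(rng.integers(ap["low"], ap["high"] + 1)),
            "mmp7_ng_ml": float(np.exp(rng.normal(np.log(mp["median"]), mp["sigma"]))),
            "label": label,
            "center_id": f"c{int(rng.integers(config.n_centers)):02d}",
        }
        for col, per_class in config.biochem_params.items():
            median, sigma = per_class[label]
            row[col] = float(np.exp(rng.normal(np.log(median), sigma)))
        rows.append(row)
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return df


# ---------------------------------------------------------------------------
# image generation
# ---------------------------------------------------------------------------

def _realize_geometry(scene: ImageSceneConfig, label: str, rng: np.random.Generator) -> dict:
    """Instantiate concrete geometry (pixels) from fractions + class size effect."""
    rows, cols = scene.image_size
    side = min(rows, cols)
    size_mult = scene.class_effect[label]["size"]
    jitter = scene.center_jitter_frac
    cr = rows / 2 + rng.uniform(-jitter, jitter) * rows
    cc = cols / 2 + rng.uniform(-jitter, jitter) * cols
    g = dict(scene.structure_geometry)
    out: dict = {"kind": g["kind"], "center": (float(cr), float(cc))}
    if g["kind"] == "ellipse":
        out["axes"] = (g["axes_frac"][0] * side * size_mult,
                       g["axes_frac"][1] * side * size_mult)
        out["rotation_deg"] = float(g.get("rotation_deg", 0.0) + rng.uniform(-10, 10))
    elif g["kind"] == "triangle":
        out["base"] = g["base_frac"] * side * size_mult
        out["height"] = g["height_frac"] * side * size_mult
        out["rotation_deg"] = float(rng.uniform(-15, 15))
    elif g["kind"] == "band":
        out["length"] = g["length_frac"] * side * size_mult
        out["thickness"] = g["thickness_frac"] * side * size_mult
        out["angle_deg"] = float(g.get("angle_deg", 0.0) + rng.uniform(-10, 10))
    else:
        raise ConfigurationError(f"unknown geometry kind {g['kind']!r}")
    return out


def _rotate(points: np.ndarray, center: tuple[float, float], deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return (points - center) @ rot.T + center


def render_mask(geometry: Mapping, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize stored geometry into a boolean mask (exactly reproducible)."""
    mask = np.zeros(shape, dtype=bool)
    cr, cc = geometry["center"]
    kind = geometry["kind"]
    if kind == "ellipse":
        a, b = geometry["axes"]
        rr, ccc = draw.ellipse(cr, cc, a, b, shape=shape,
                               rotation=np.deg2rad(geometry.get("rotation_deg", 0.0)))
    elif kind == "triangle":
        base, h = geometry["base"], geometry["height"]
        pts = np.array([
            [cr - h / 2, cc],             # apex up
            [cr + h / 2, cc - base / 2],
            [cr + h / 2, cc + base / 2],
        ])
        pts = _rotate(pts, (cr, cc), geometry.get("rotation_deg", 0.0))
        rr, ccc = draw.polygon(pts[:, 0], pts[:, 1], shape=shape)
    elif kind == "band":
        length, t = geometry["length"], geometry["thickness"]
        pts = np.array([
            [cr - t / 2, cc - length / 2],
            [cr - t / 2, cc + length / 2],
            [cr + t / 2, cc + length / 2],
            [cr + t / 2, cc - length / 2],
        ])
        pts = _rotate(pts, (cr, cc), geometry.get("angle_deg", 0.0))
        rr, ccc = draw.polygon(pts[:, 0], pts[:, 1], shape=shape)
    else:
        raise ConfigurationError(f"unknown geometry kind {kind!r}")
    mask[rr, ccc] = True
    return mask


def _bounding_box(mask: np.ndarray, pad: int, shape: tuple[int, int]) -> tuple[int, int, int, int]:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return (max(0, int(r0) - pad), max(0, int(c0) - pad),
            min(shape[0], int(r1) + 1 + pad), min(shape[1], int(c1) + 1 + pad))


def generate_image(scene: ImageSceneConfig, truth_label: str):
    """Render one speckled scene with an embedded class-dependent structure.

    Returns ``(GrayImage, GroundTruth)``.  The ground-truth mask is exactly
    the rasterized geometry; the crop box is the mask's bounding box padded
    by ``scene.crop_pad`` pixels (standing in for a manual ROI crop).
    """
    from .images import GrayImage  # local import to avoid cycle at module load

    if truth_label not in (LABEL_BA, LABEL_NON_BA):
        raise ConfigurationError(f"unknown label {truth_label!r}")
    rng = np.random.default_rng(scene.seed)
    geometry = _realize_geometry(scene, truth_label, rng)
    mask = render_mask(geometry, scene.image_size)
    if not mask.any():
        raise ConfigurationError("structure geometry fell outside the image")

    contrast = scene.structure_contrast * scene.class_effect[truth_label]["contrast"]
    img = np.full(scene.image_size, scene.background_mean, dtype=float)
    img[mask] += contrast
    img += rng.normal(0.0, scene.background_std, size=scene.image_size)
    if scene.speckle_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, scene.speckle_blur_sigma)
    img = np.clip(img, 0.0, 255.0)

    truth = GroundTruth(
        label=truth_label,
        true_mask=mask,
        true_crop=_bounding_box(mask, scene.crop_pad, scene.image_size),
        geometry=geometry,
    )
    return GrayImage(img, state="raw", source_id=f"synthetic-{scene.view}"), truth


# ---------------------------------------------------------------------------
# dataset on disk
# ---------------------------------------------------------------------------

def default_scene_configs(
    image_size: tuple[int, int] = (128, 128), **overrides
) -> dict[str, ImageSceneConfig]:
    return {v: ImageSceneConfig(view=v, image_size=image_size, **overrides)
            for v in VIEWS}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def iter_cohort_images(
    cohort_config: CohortConfig,
    scene_configs: Mapping[str, ImageSceneConfig] | None = None,
    cohort: pd.DataFrame | None = None,
):
    """Yield ``(patient_id, label, view, GrayImage, GroundTruth)`` lazily.

    Applies the per-view dropout at ``missing_view_rate`` and derives one
    image seed per (cohort seed, patient index, view index), identically
    to :func:`generate_dataset` — which is implemented on top of this.
    """
    scene_configs = scene_configs or default_scene_configs()
    if cohort is None:
        cohort = generate_cohort(cohort_config)
    for i, rec in cohort.iterrows():
        for j, view in enumerate(VIEWS):
            drop_rng = _patient_rng(cohort_config.seed, i, stream=100 + j)
            if drop_rng.random() < cohort_config.missing_view_rate:
                continue
            scene = scene_configs[view]
            seed = int(np.random.SeedSequence(
                entropy=(cohort_config.seed, i, j)).generate_state(1)[0] % (2**31))
            scene_i = replace(scene, view=view, seed=seed)
            img, truth = generate_image(scene_i, rec["label"])
            truth = replace(truth, true_mmp7=float(rec["mmp7_ng_ml"]),
                            age_days=int(rec["age_days"]))
            yield rec["patient_id"], rec["label"], view, img, truth


def generate_dataset(
    cohort_config: CohortConfig,
    scene_configs: Mapping[str, ImageSceneConfig] | None = None,
    out_dir: str | Path = "dataset",
) -> dict:
    """Write a full synthetic dataset to ``out_dir`` and return its manifest.

    Files: ``images/<pid>_<view>.png`` (8-bit gray PNG, clipped+rounded at
    write time), ``cohort.csv``, ``annotations.json``, ``ground_truth.json``
    (stored geometry, crops, labels — masks are re-renderable via
    :func:`render_mask`), and ``manifest.json`` with SHA-256 checksums.
    Per-view dropout at ``cohort_config.missing_view_rate`` exercises the
    "at least one ROI visible" inclusion rule downstream.  The manifest
    carries no timestamps, so re-running with the same seeds reproduces
    every file byte-for-byte.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    scene_configs = scene_configs or default_scene_configs()

    cohort = generate_cohort(cohort_config)
    annotations: list[dict] = []
    truths: list[dict] = []
    files: dict[str, str] = {}

    for pid, label, view, img, truth in iter_cohort_images(
            cohort_config, scene_configs, cohort):
        rel = f"images/{pid}_{view}.png"
        arr8 = np.clip(np.rint(img.values), 0, 255).astype(np.uint8)
        Image.fromarray(arr8, mode="L").save(out / rel)
        annotations.append({
            "patient_id": pid, "view": view, "path": rel,
            "crop": list(truth.true_crop),
        })
        truths.append({
            "patient_id": pid, "view": view, "label": label,
            "geometry": truth.geometry, "crop": list(truth.true_crop),
            "image_size": list(scene_configs[view].image_size),
        })
        files[rel] = _sha256(out / rel)

    cohort.to_csv(out / "cohort.csv", index=False)
    (out / "annotations.json").write_text(json.dumps(annotations, indent=1))
    (out / "ground_truth.json").write_text(json.dumps(truths, indent=1))
    for name in ("cohort.csv", "annotations.json", "ground_truth.json"):
        files[name] = _sha256(out / name)

    manifest = {
        "n_patients": int(len(cohort)),
        "n_images": sum(1 for f in files if f.endswith(".png")),
        "seed": cohort_config.seed,
        "prevalence": cohort_config.prevalence,
        "missing_view_rate": cohort_config.missing_view_rate,
        "files": dict(sorted(files.items())),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
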