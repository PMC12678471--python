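"""Ultrasound image preprocessing and quantitative ROI feature extraction.

The pipeline mirrors how gray-scale sonograms are prepared for a
feature-based diagnostic model:

1. :func:`to_gray` — decode the image to a matrix of gray-scale values in
   [0, 255];
2. :func:`normalize_intensity` — harmonize images from different ultrasound
   devices by mapping every image to pixel mean 55 and interquartile range
   40 (an affine rescaling; no clipping, so the guarantee is exact);
3. :func:`crop` — apply the manual region-of-interest (ROI) crop box;
4. :func:`delineate_mask` — morphological delineation of the structure
   inside the crop (gallbladder: hypoechoic/dark; triangular cord:
   echogenic/bright), producing a single-component binary mask;
5. :func:`extract_features` — gray-scale quantiles, mean/median/std,
   absolute and relative ROI area, for both the masked ROI and the whole
   crop;
6. :func:`assemble_patient_features` — concatenate up to three views per
   patient with availability indicators, imputing missing views from
   training medians.

Coordinates are 0-based, row-major; crop boxes are half-open
``[r0, c0, r1, c1]`` (rows ``r0 ≤ r < r1``, columns ``c0 ≤ c < c1``).
Standard deviations use the population convention (``ddof=0``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import filters, morphology

from .errors import (
    AnnotationError,
    DegenerateImageError,
    DelineationFailure,
    InputError,
    PatientExcluded,
)

VIEWS = ("gallbladder", "tc_branches", "tc_transverse")

#: Default structure polarity per view: the gallbladder lumen is
#: fluid-filled and dark; the triangular cord is echogenic (bright).
DEFAULT_POLARITY = {
    "gallbladder": "dark_structure",
    "tc_branches": "bright_structure",
    "tc_transverse": "bright_structure",
}

#: Rec. 601 luminance weights used to collapse RGB to gray.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

DEFAULT_QUANTILE_LEVELS = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrayImage:
    """A real-valued gray-scale intensity matrix with provenance.

    ``state`` records whether the values are raw device intensities
    (guaranteed within [0, 255]) or normalized values (mean 55, IQR 40;
    may leave [0, 255]).
    """

    values: np.ndarray
    state: str = "raw"  # "raw" | "normalized"
    source_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise InputError(f"image must be at least 2x2, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise InputError("image contains non-finite values")
        if self.state == "raw" and (v.min() < 0 or v.max() > 255):
            raise InputError("raw image values must lie in [0, 255]")
        if self.state not in ("raw", "normalized"):
            raise InputError(f"unknown image state {self.state!r}")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class NormalizationConfig:
    """Targets of the per-image intensity harmonization."""

    target_mean: float = 55.0
    target_iqr: float = 40.0
    quartile_method: str = "linear"  # numpy percentile interpolation rule

    def __post_init__(self):
        if self.target_iqr <= 0:
            raise InputError("target_iqr must be positive")


@dataclass(frozen=True)
class RoiAnnotation:
    """Per-image ROI annotation: view label, crop box and polarity.

    ``crop`` is ``[r0, c0, r1, c1]``, 0-based and half-open.  ``polarity``
    says whether the structure of interest is darker or brighter than its
    surroundings; it defaults per view (see :data:`DEFAULT_POLARITY`).
    """

    view: str
    crop: tuple[int, int, int, int]
    polarity: str | None = None

    def __post_init__(self):
        if self.view not in VIEWS:
            raise AnnotationError(f"unknown view {self.view!r}; expected one of {VIEWS}")
        r0, c0, r1, c1 = self.crop
        if not (r0 < r1 and c0 < c1):
            raise AnnotationError(f"degenerate crop box {self.crop}")
        if min(r0, c0) < 0:
            raise AnnotationError(f"negative crop coordinates {self.crop}")
        pol = self.polarity if self.polarity is not None else DEFAULT_POLARITY[self.view]
        if pol not in ("dark_structure", "bright_structure"):
            raise AnnotationError(f"unknown polarity {pol!r}")
        object.__setattr__(self, "polarity", pol)


@dataclass(frozen=True)
class MorphologyConfig:
    """Knobs of the delineation pipeline (all artifact choices)."""

    smoothing_sigma: float = 2.0   # px, Gaussian pre-smoothing
    disk_radius: int = 3           # px, opening/closing structuring element
    connectivity: int = 2          # scikit-image convention: 2 == 8-connectivity


@dataclass(frozen=True)
class BinaryMask:
    """Binary ROI mask with the same shape as its crop."""

    values: np.ndarray
    component_count: int = 1

    def __post_init__(self):
        v = np.asarray(self.values, dtype=bool)
        object.__setattr__(self, "values", v)

    @property
    def area(self) -> int:
        return int(self.values.sum())

    def boundary(self) -> np.ndarray:
        """Mask boundary as mask minus its erosion."""
        eroded = morphology.erosion(self.values, morphology.disk(1))
        return self.values & ~eroded


@dataclass(frozen=True)
class ViewFeatures:
    """Named quantitative features of one view."""

    view: str
    features: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, float]:
        """Flat dict with the view name prefixed to every feature."""
        return {f"{self.view}__{k}": float(v) for k, v in self.features.items()}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def to_gray(image_file: str | Path | np.ndarray) -> GrayImage:
    """Load an image file and convert it to a gray-scale matrix in [0, 255].

    RGB(A) inputs are collapsed with the Rec. 601 luminance weighting
    ``0.299 R + 0.587 G + 0.114 B``.  PNG and TIFF are read through
    Pillow; DICOM files (suffix ``.dcm``) through pydicom when available
    (pixel data only).  An ndarray is accepted directly for convenience.
    """
    if isinstance(image_file, np.ndarray):
        return GrayImage(np.asarray(image_file, dtype=float), state="raw", source_id="<array>")

    path = Path(image_file)
    if not path.exists():
        raise InputError(f"image file not found: {path}")

    if path.suffix.lower() == ".dcm":
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover - env dependent
            raise InputError("DICOM input requires pydicom") from exc
        arr = np.asarray(pydicom.dcmread(path).pixel_array, dtype=float)
    else:
        try:
            with Image.open(path) as im:
                arr = np.asarray(im, dtype=float)
        except Exception as exc:
            raise InputError(f"cannot read image {path}: {exc}") from exc

    if arr.size == 0:
        raise InputError(f"empty image file: {path}")
    if arr.ndim == 3:
        w = np.asarray(LUMA_WEIGHTS)
        arr = arr[..., :3] @ w
    elif arr.ndim != 2:
        raise InputError(f"unsupported image dimensionality {arr.ndim} in {path}")
    arr = np.clip(arr, 0.0, 255.0)
    return GrayImage(arr, state="raw", source_id=path.name)


def normalize_intensity(
    img: GrayImage, cfg: NormalizationConfig | None = None
) -> GrayImage:
    """Affinely rescale an image to pixel mean 55 and IQR 40.

    ``out = (in − mean(in)) / IQR(in) × target_iqr + target_mean``.

    The output is stored as real values without clipping or rounding, so
    the mean and IQR of the result equal the targets exactly (to floating
    point); the operation is idempotent.  The quartile rule is the
    interpolation method named in ``cfg.quartile_method`` (numpy
    percentile conventions; default linear interpolation).
    """
    cfg = cfg or NormalizationConfig()
    v = img.values
    q1, q3 = np.percentile(v, [25.0, 75.0], method=cfg.quartile_method)
    iqr = q3 - q1
    if iqr <= 0:
        raise DegenerateImageError(img.source_id or "<unnamed>")
    out = (v - v.mean()) / iqr * cfg.target_iqr + cfg.target_mean
    return GrayImage(out, state="normalized", source_id=img.source_id)


def crop(img: GrayImage, ann: RoiAnnotation) -> GrayImage:
    """Extract the crop-box submatrix (no resampling)."""
    r0, c0, r1, c1 = ann.crop
    rows, cols = img.shape
    if r1 > rows or c1 > cols:
        raise AnnotationError(
            f"crop box {ann.crop} exceeds image bounds {img.shape}"
        )
    return replace(img, values=img.values[r0:r1, c0:c1])


def delineate_mask(
    cropped: GrayImage,
    ann: RoiAnnotation,
    morph_cfg: MorphologyConfig | None = None,
) -> BinaryMask:
    """Delineate the anatomical structure inside a cropped image.

    Fixed pipeline: Gaussian smoothing → global Otsu threshold → keep the
    dark (or bright, per ``ann.polarity``) side → morphological opening
    then closing with a disk → keep the largest 8-connected component →
    fill holes.  Raises :class:`DelineationFailure` when nothing remains;
    callers treat the view as missing.
    """
    morph_cfg = morph_cfg or MorphologyConfig()
    v = cropped.values
    smoothed = ndimage.gaussian_filter(v, sigma=morph_cfg.smoothing_sigma)
    if np.ptp(smoothed) == 0:
        raise DelineationFailure("constant crop: nothing to segment")
    thr = filters.threshold_otsu(smoothed)
    raw = smoothed < thr if ann.polarity == "dark_structure" else smoothed > thr

    selem = morphology.disk(morph_cfg.disk_radius)
    mask = morphology.opening(raw, selem)
    mask = morphology.closing(mask, selem)
    if not mask.any():
        raise DelineationFailure("empty mask after morphological filtering")

    labels, n = ndimage.label(
        mask, structure=ndimage.generate_binary_structure(2, morph_cfg.connectivity)
    )
    if n == 0:
        raise DelineationFailure("no connected component survived")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    mask = labels == (int(np.argmax(sizes)) + 1)
    mask = ndimage.binary_fill_holes(mask)
    return BinaryMask(mask, component_count=1)


def _region_stats(pixels: np.ndarray, prefix: str, levels: Sequence[float]) -> dict[str, float]:
    stats = {
        f"{prefix}_mean": float(pixels.mean()),
        f"{prefix}_median": float(np.median(pixels)),
        f"{prefix}_std": float(pixels.std(ddof=0)),
    }
    qs = np.quantile(pixels, levels)
    for lev, q in zip(levels, qs):
        stats[f"{prefix}_q{int(round(lev * 100)):02d}"] = float(q)
    return stats


def extract_features(
    cropped: GrayImage,
    mask: BinaryMask,
    levels: Sequence[float] = DEFAULT_QUANTILE_LEVELS,
    view: str | None = None,
) -> ViewFeatures:
    """Compute gray-scale, size and texture features for one view.

    Gray-scale: quantiles at ``levels`` plus mean/median for the masked
    ROI and the whole crop.  Size: absolute mask area in pixels and the
    ratio of mask pixels to crop pixels.  Texture: population standard
    deviation of intensities in the ROI and the full crop.
    """
    if mask.values.shape != cropped.shape:
        raise InputError(
            f"mask shape {mask.values.shape} != crop shape {cropped.shape}"
        )
    roi = cropped.values[mask.values]
    if roi.size == 0:
        raise InputError("empty mask: no ROI pixels to summarize")

    feats: dict[str, float] = {}
    feats.update(_region_stats(roi, "roi", levels))
    feats.update(_region_stats(cropped.values.ravel(), "crop", levels))
    feats["area_abs"] = float(mask.area)
    feats["area_ratio"] = float(mask.area) / cropped.values.size
    return ViewFeatures(view=view or "view", features=feats)


def feature_names(
    levels: Sequence[float] = DEFAULT_QUANTILE_LEVELS,
    views: Sequence[str] = VIEWS,
) -> list[str]:
    """Names of the assembled per-patient feature columns, in order."""
    per_view = (
        [f"{p}_{s}" for p in ("roi", "crop") for s in ("mean", "median", "std")]
        + [f"{p}_q{int(round(l * 100)):02d}" for p in ("roi", "crop") for l in levels]
        + ["area_abs", "area_ratio"]
    )
    names: list[str] = []
    for view in views:
        names.extend(f"{view}__{k}" for k in per_view)
        names.append(f"{view}__available")
    return names


def compute_training_medians(
    per_patient_views: Mapping[str, Mapping[str, ViewFeatures | None]],
) -> dict[str, float]:
    """Per-feature medians over available training views, for imputation."""
    columns: dict[str, list[float]] = {}
    for views in per_patient_views.values():
        for vf in views.values():
            if vf is None:
                continue
            for name, value in vf.to_dict().items():
                columns.setdefault(name, []).append(value)
    return {name: float(np.median(vals)) for name, vals in columns.items()}


def assemble_patient_features(
    patient_id: str,
    views: Mapping[str, ViewFeatures | None],
    medians: Mapping[str, float] | None = None,
    levels: Sequence[float] = DEFAULT_QUANTILE_LEVELS,
) -> dict[str, float]:
    """Concatenate the three views into one named feature vector.

    A patient qualifies when at least one view has a delineated ROI;
    otherwise :class:`PatientExcluded` is raised (the caller logs it).
    Missing views get availability indicator 0 and are imputed from the
    training medians (``medians``); features whose medians are unknown
    are filled with 0 only in the degenerate case of an empty median map.
    """
    available = {v: vf for v, vf in views.items() if vf is not None}
    if not available:
        raise PatientExcluded(patient_id, "no ROI visible in any view")
    medians = medians or {}

    row: dict[str, float] = {}
    for view in VIEWS:
        vf = views.get(view)
        if vf is not None:
            row.update(vf.to_dict())
            row[f"{view}__available"] = 1.0
        else:
            for name in feature_names(levels, views=(view,)):
                if name.endswith("__available"):
                    continue
                row[name] = float(medians.get(name, 0.0))
            row[f"{view}__available"] = 0.0
    return row


# ---------------------------------------------------------------------------
# cohort-level convenience pipeline
# ---------------------------------------------------------------------------

def extract_view_features(
    annotations: Sequence[Mapping],
    images_root: str | Path,
    norm_cfg: NormalizationConfig | None = None,
    morph_cfg: MorphologyConfig | None = None,
    levels: Sequence[float] = DEFAULT_QUANTILE_LEVELS,
) -> tuple[dict[str, dict[str, ViewFeatures | None]], list[dict]]:
    """Run steps 1–5 for every annotated image of a cohort.

    ``annotations`` follows the annotation-JSON schema: dicts with
    ``patient_id``, ``view``, ``path`` (relative to ``images_root``) and
    ``crop``.  Returns ``(per_patient_views, failures)`` where failed
    delineations are recorded (patient, view, reason) and the view set to
    ``None``.
    """
    root = Path(images_root)
    per_patient: dict[str, dict[str, ViewFeatures | None]] = {}
    failures: list[dict] = []
    for ann_rec in annotations:
        pid = str(ann_rec["patient_id"])
        view = ann_rec["view"]
        ann = RoiAnnotation(
            view=view,
            crop=tuple(ann_rec["crop"]),
            polarity=ann_rec.get("polarity"),
        )
        views = per_patient.setdefault(pid, {v: None for v in VIEWS})
        try:
            img = normalize_intensity(to_gray(root / ann_rec["path"]), norm_cfg)
            cropped = crop(img, ann)
            mask = delineate_mask(cropped, ann, morph_cfg)
            views[view] = extract_features(cropped, mask, levels, view=view)
        except (DelineationFailure, DegenerateImageError) as exc:
            failures.append({"patient_id": pid, "view": view, "reason": str(exc)})
            views[view] = None
    return per_patient, failures


def assemble_cohort_features(
    per_patient_views: Mapping[str, Mapping[str, ViewFeatures | None]],
    medians: Mapping[str, float] | None = None,
    levels: Sequence[float] = DEFAULT_QUANTILE_LEVELS,
):
    """Build the tidy per-patient feature table.

    When ``medians`` is None they are computed from the given cohort
    (training behaviour) and returned for reuse on validation data.
    Returns ``(DataFrame indexed by patient_id, medians, excluded_ids)``.
    """
    import pandas as pd

    if medians is None:
        medians = compute_training_medians(per_patient_views)
    rows, excluded = {}, []
    for pid, views in per_patient_views.items():
        try:
            rows[pid] = assemble_patient_features(pid, views, medians, levels)
        except PatientExcluded:
            excluded.append(pid)
    cols = feature_names(levels)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=cols) if len(df) else pd.DataFrame(columns=cols)
    df.index.name = "patient_id"
    return df, dict(medians), excluded
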