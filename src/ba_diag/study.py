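"""End-to-end synthetic study: generate, extract, train, validate.

Convenience layer that mirrors a two-cohort diagnostic-accuracy study
design — a training cohort at one disease prevalence and an independent
validation cohort at another — entirely on synthetic data, and trains
the three diagnostic models (ultrasound-only, MMP-7-only, combined) on
identical patients.  Used by the test-suite recovery experiments and by
the worked example in the README.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateImageError, DelineationFailure
from .evaluate import evaluate_scores
from .images import (
    VIEWS,
    MorphologyConfig,
    NormalizationConfig,
    RoiAnnotation,
    assemble_cohort_features,
    crop,
    delineate_mask,
    extract_features,
    normalize_intensity,
)
from .model import ModelConfig, build_combined, mmp7_design, train_model
from .synthetic import CohortConfig, default_scene_configs, iter_cohort_images


def extract_cohort_features_in_memory(
    cohort_cfg: CohortConfig,
    scene_cfgs=None,
    medians=None,
    norm_cfg: NormalizationConfig | None = None,
    morph_cfg: MorphologyConfig | None = None,
):
    """Generate images in memory and run the full feature pipeline.

    Equivalent to ``generate_dataset`` + ``extract_view_features`` +
    ``assemble_cohort_features`` without touching disk (PNG quantization
    aside).  Returns ``(cohort_df, features_df, medians, excluded_ids)``.
    """
    from .synthetic import generate_cohort

    cohort = generate_cohort(cohort_cfg)
    per_patient = {pid: {v: None for v in VIEWS} for pid in cohort["patient_id"]}
    for pid, _label, view, img, truth in iter_cohort_images(
            cohort_cfg, scene_cfgs, cohort):
        ann = RoiAnnotation(view=view, crop=truth.true_crop)
        try:
            norm = normalize_intensity(img, norm_cfg)
            cropped = crop(norm, ann)
            mask = delineate_mask(cropped, ann, morph_cfg)
            per_patient[pid][view] = extract_features(cropped, mask, view=view)
        except (DelineationFailure, DegenerateImageError):
            per_patient[pid][view] = None
    feats, medians, excluded = assemble_cohort_features(per_patient, medians)
    return cohort, feats, medians, excluded


@dataclass
class StudyResult:
    """Held-out performance of the three models for one study replicate."""

    train_auc: dict[str, float] = field(default_factory=dict)
    valid_auc: dict[str, float] = field(default_factory=dict)
    valid_reports: dict = field(default_factory=dict)
    n_train: int = 0
    n_valid: int = 0


def run_synthetic_study(
    seed: int = 0,
    n_train: int = 187,
    prevalence_train: float = 0.299,
    n_valid: int = 161,
    prevalence_valid: float = 0.621,
    image_size: tuple[int, int] = (128, 128),
    model_cfg: ModelConfig | None = None,
    model_kinds: tuple[str, ...] = ("us_only", "mmp7_only", "combined"),
) -> StudyResult:
    """One full study replicate at the default study conditions.

    Cohort sizes and prevalences default to a 187-patient training cohort
    at 29.9% BA and a 161-patient validation cohort at 62.1% BA.  The two
    cohorts use independent seeds derived from ``seed``.
    """
    s_train, s_valid = (int(s % (2**31)) for s in
                        np.random.SeedSequence(seed).generate_state(2))
    scene_cfgs = default_scene_configs(image_size)
    model_cfg = model_cfg or ModelConfig(seed=seed)

    tr_cohort, tr_feats, medians, _ = extract_cohort_features_in_memory(
        CohortConfig(n_patients=n_train, prevalence=prevalence_train, seed=s_train),
        scene_cfgs)
    va_cohort, va_feats, _, _ = extract_cohort_features_in_memory(
        CohortConfig(n_patients=n_valid, prevalence=prevalence_valid, seed=s_valid),
        scene_cfgs, medians=medians)

    tr = tr_cohort.set_index("patient_id").loc[tr_feats.index]
    va = va_cohort.set_index("patient_id").loc[va_feats.index]
    y_tr = (tr["label"] == "BA").astype(int).to_numpy()
    y_va = (va["label"] == "BA").astype(int).to_numpy()

    result = StudyResult(n_train=len(y_tr), n_valid=len(y_va))
    designs_va: dict[str, pd.DataFrame] = {}
    for kind in model_kinds:
        if kind == "us_only":
            model = train_model(tr_feats, y_tr, "us_only", model_cfg, medians)
            design_va = va_feats
            design_tr = tr_feats
        elif kind == "mmp7_only":
            design_tr = mmp7_design(tr["mmp7_ng_ml"], tr["age_days"], index=tr.index)
            model = train_model(design_tr, y_tr, "mmp7_only", model_cfg)
            design_va = mmp7_design(va["mmp7_ng_ml"], va["age_days"], index=va.index)
        else:
            model, _ = build_combined(
                tr_feats, tr["mmp7_ng_ml"], tr["age_days"], y_tr, model_cfg, medians)
            design_tr = pd.concat(
                [tr_feats, mmp7_design(tr["mmp7_ng_ml"], tr["age_days"],
                                       index=tr.index)], axis=1)
            design_va = pd.concat(
                [va_feats, mmp7_design(va["mmp7_ng_ml"], va["age_days"],
                                       index=va.index)], axis=1)
        designs_va[kind] = design_va
        p_tr = model.predict_proba(design_tr)
        p_va = model.predict_proba(design_va)
        rep = evaluate_scores(p_va, y_va, model.decision_threshold)
        result.train_auc[kind] = evaluate_scores(
            p_tr, y_tr, model.decision_threshold).auc
        result.valid_auc[kind] = rep.auc
        result.valid_reports[kind] = rep
    return result
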