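"""Serum MMP-7 measurement handling and the age-stratified positivity rule.

MMP-7 (matrix metalloproteinase-7) is a serum biomarker elevated in
biliary atresia.  It is assayed by ELISA on 20-fold diluted serum, in
triplicate, with the replicate mean used for analysis.  Positivity is
age-stratified with strict inequalities:

- infants older than 30 days: positive when concentration > 18 ng/mL;
- infants 30 days old or younger: positive when concentration > 28.1 ng/mL.

Inputs are assumed to be final serum concentrations; replicates measured
before back-calculation can be flagged ``pre_dilution`` so the dilution
factor is applied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class Mmp7Measurement:
    """One patient's MMP-7 assay: 1–3 replicates plus assay metadata."""

    replicate_values: Sequence[float]
    dilution_factor: float = 20.0
    age_days: int = 0
    pre_dilution: bool = False  # replicates are raw diluted-well readings

    def __post_init__(self):
        if len(self.replicate_values) == 0:
            raise InputError("at least one MMP-7 replicate is required")
        if any(v < 0 for v in self.replicate_values):
            raise InputError("MMP-7 concentrations must be non-negative")
        if self.dilution_factor <= 0:
            raise InputError("dilution_factor must be positive")
        if self.age_days < 0:
            raise InputError("age_days must be non-negative")


@dataclass(frozen=True)
class Mmp7Thresholds:
    """Age-stratified positivity thresholds (ng/mL)."""

    threshold_older: float = 18.0    # age > age_cut
    threshold_younger: float = 28.1  # age <= age_cut
    age_cut: int = 30                # days

    def __post_init__(self):
        if self.threshold_older <= 0 or self.threshold_younger <= 0:
            raise InputError("thresholds must be positive")


DEFAULT_THRESHOLDS = Mmp7Thresholds()


def summarize_replicates(m: Mmp7Measurement) -> float:
    """Arithmetic mean of the replicates, in ng/mL serum.

    The dilution factor is applied only when the replicates are flagged
    as pre-dilution well readings.
    """
    mean = float(np.mean(np.asarray(m.replicate_values, dtype=float)))
    return mean * m.dilution_factor if m.pre_dilution else mean


def mmp7_positive(
    concentration: float,
    age_days: int,
    thresholds: Mmp7Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Apply the age-stratified rule (strict '>' at both thresholds).

    Age exactly ``age_cut`` (30 days) uses the younger-stratum threshold.
    """
    if concentration < 0:
        raise InputError("concentration must be non-negative")
    if age_days < 0:
        raise InputError("age_days must be non-negative")
    cut = (
        thresholds.threshold_younger
        if age_days <= thresholds.age_cut
        else thresholds.threshold_older
    )
    return concentration > cut
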