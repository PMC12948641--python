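"""Five-parameter bedside difficult-airway score.

The score sums five binary predictor flags assessed at the bedside of a
conscious patient before emergency intubation:

* BMI  > 30 kg/m2          (obesity)
* retrognathia present      (receding mandible)
* ULBT class 3              (cannot bite the upper lip at all)
* TMD  < 7 cm               (short thyromental distance)
* HMD <= 6 cm               (hyomental distance grade 2 or 3)

Each positive predictor contributes one point, so the score ranges 0-5; a
total of >= 1 is read as "difficult airway predicted".  The reference
standard is the Modified Mallampati classification (MMC), dichotomised as
class 3/4 = difficult, class 1/2 = easy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


class ValidationError(ValueError):
    """Raised when a record or threshold field is out of its domain."""


def _require(condition: bool, field_name: str, message: str) -> None:
    if not condition:
        raise ValidationError(f"{field_name}: {message}")


@dataclass(frozen=True)
class ScoreThresholds:
    """Dichotomisation cutoffs for the five predictors.

    Defaults are the published operating points.  Boundary conventions:
    BMI exactly at the cutoff scores 0 (strict >), TMD exactly at the
    cutoff scores 0 (strict <), HMD exactly at the cutoff scores 1
    (inclusive <=, since grade 2 spans 4-6 cm).
    """

    bmi_cutoff: float = 30.0
    tmd_cutoff: float = 7.0
    hmd_cutoff: float = 6.0
    ulbt_positive_class: int = 3
    positivity_threshold: int = 1

    def __post_init__(self) -> None:
        for name in ("bmi_cutoff", "tmd_cutoff", "hmd_cutoff"):
            value = getattr(self, name)
            _require(
                isinstance(value, (int, float)) and math.isfinite(value) and value > 0,
                name, "must be a positive finite number",
            )
        _require(self.ulbt_positive_class in (1, 2, 3), "ulbt_positive_class", "must be 1, 2 or 3")
        _require(0 <= self.positivity_threshold <= 5, "positivity_threshold", "must lie in 0..5")


DEFAULT_THRESHOLDS = ScoreThresholds()


@dataclass(frozen=True)
class PatientAirwayRecord:
    """One patient's raw bedside measurements plus the MMC reference class."""

    id: str
    bmi: float
    retrognathia: bool
    ulbt_class: int
    tmd_cm: float
    hmd_cm: float
    mmc_class: int

    def __post_init__(self) -> None:
        for name in ("bmi", "tmd_cm", "hmd_cm"):
            value = getattr(self, name)
            _require(
                isinstance(value, (int, float)) and math.isfinite(value) and value > 0,
                name, f"must be a positive finite number, got {value!r}",
            )
        _require(self.ulbt_class in (1, 2, 3), "ulbt_class", f"must be in {{1,2,3}}, got {self.ulbt_class!r}")
        _require(self.mmc_class in (1, 2, 3, 4), "mmc_class", f"must be in {{1,2,3,4}}, got {self.mmc_class!r}")


PREDICTOR_NAMES = ("bmi", "retrognathia", "ulbt", "tmd", "hmd")


@dataclass(frozen=True)
class PredictorFlags:
    """The five binary predictor indicators for one patient."""

    bmi_flag: int
    retrognathia_flag: int
    ulbt_flag: int
    tmd_flag: int
    hmd_flag: int

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) in (0, 1), f.name, "must be 0 or 1")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.bmi_flag, self.retrognathia_flag, self.ulbt_flag,
                self.tmd_flag, self.hmd_flag)

    @classmethod
    def from_tuple(cls, flags: tuple[int, int, int, int, int]) -> "PredictorFlags":
        return cls(*flags)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


@dataclass(frozen=True)
class CompositeScore:
    """Flag sum (0-5) and its positive/negative dichotomy."""

    score: int
    positive: bool

    def __post_init__(self) -> None:
        _require(0 <= self.score <= 5, "score", "must lie in 0..5")


def evaluate_predictors(
    record: PatientAirwayRecord,
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
) -> PredictorFlags:
    """Dichotomise the five raw measurements into 0/1 predictor flags."""
    return PredictorFlags(
        bmi_flag=int(record.bmi > thresholds.bmi_cutoff),
        retrognathia_flag=int(bool(record.retrognathia)),
        ulbt_flag=int(record.ulbt_class == thresholds.ulbt_positive_class),
        tmd_flag=int(record.tmd_cm < thresholds.tmd_cutoff),
        hmd_flag=int(record.hmd_cm <= thresholds.hmd_cutoff),
    )


def composite_score(
    flags: PredictorFlags,
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
) -> CompositeScore:
    """Sum the five flags; positive iff the sum reaches the positivity threshold."""
    total = flags.total
    return CompositeScore(score=total, positive=total >= thresholds.positivity_threshold)


def mmc_reference(mmc_class: int) -> bool:
    """Dichotomise the Mallampati class: True (difficult) iff class 3 or 4."""
    _require(mmc_class in (1, 2, 3, 4), "mmc_class", f"must be in {{1,2,3,4}}, got {mmc_class!r}")
    return mmc_class >= 3


def score_record(
    record: PatientAirwayRecord,
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
) -> CompositeScore:
    """Convenience: flags then composite in one call."""
    return composite_score(evaluate_predictors(record, thresholds), thresholds)
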