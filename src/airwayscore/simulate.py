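"""Stochastic cohort generator with the statistical structure the analysis assumes.

Each synthetic patient is drawn as: reference status ~ Bernoulli(prevalence),
mapped to an MMC class (3/4 if difficult, 1/2 if easy, sub-class uniform);
then each of the five predictor flags ~ Bernoulli with probability equal to
that predictor's sensitivity (difficult) or false-positive rate
1 - specificity (easy).  Defaults are the published per-predictor operating
points and the observed 41% prevalence.

Conditional independence of the flags given reference status is the
``dependence = 0`` case.  Real predictors of a difficult airway co-occur
(they share anatomical causes), so a ``dependence`` weight d in [0,1)
mixes each flag probability toward a patient-level latent severity
u ~ Uniform(0,1):  p_i' = (1-d) * p_i + d * u.  The shared u correlates
the flags (and pulls each marginal toward 1/2 as d grows); it is a
qualitative stand-in, not an inferred joint model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import DiagnosticMetrics, build_contingency, compute_metrics
from .reconstruct import realize_measurements
from .scoring import (
    DEFAULT_THRESHOLDS,
    PREDICTOR_NAMES,
    PatientAirwayRecord,
    PredictorFlags,
    ScoreThresholds,
    evaluate_predictors,
    mmc_reference,
    score_record,
)
from . import study

_DEFAULT_SENS = tuple(
    t.tp / t.reference_positive for t in study.PREDICTOR_TABLES.values()
)
_DEFAULT_SPEC = tuple(
    t.tn / t.reference_negative for t in study.PREDICTOR_TABLES.values()
)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n: int = 200
    prevalence: float = study.N_DIFFICULT / study.N_TOTAL  # 0.41
    sensitivities: tuple[float, ...] = _DEFAULT_SENS
    specificities: tuple[float, ...] = _DEFAULT_SPEC
    dependence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0,1]")
        if len(self.sensitivities) != 5 or len(self.specificities) != 5:
            raise ValueError("five sensitivities and five specificities required")
        for p in (*self.sensitivities, *self.specificities):
            if not 0.0 <= p <= 1.0:
                raise ValueError("operating characteristics must lie in [0,1]")
        if not 0.0 <= self.dependence < 1.0:
            raise ValueError("dependence must lie in [0,1)")


def generate(
    config: SyntheticCohortConfig,
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
) -> list[PatientAirwayRecord]:
    """Draw a reproducible synthetic cohort of raw bedside records."""
    rng = np.random.default_rng(config.seed)
    difficult = rng.random(config.n) < config.prevalence
    u = rng.random(config.n)
    sens = np.asarray(config.sensitivities)
    fpr = 1.0 - np.asarray(config.specificities)
    base = np.where(difficult[:, None], sens[None, :], fpr[None, :])
    d = config.dependence
    p_eff = (1.0 - d) * base + d * u[:, None]
    flags = rng.random((config.n, 5)) < p_eff
    records = []
    for i in range(config.n):
        pf = PredictorFlags(*(int(v) for v in flags[i]))
        records.append(
            realize_measurements(
                pf, bool(difficult[i]), rng, f"S{i + 1:04d}", thresholds
            )
        )
    return records


@dataclass(frozen=True)
class RecoveredParameters:
    """Estimated operating characteristics: one entry per predictor plus the composite."""

    per_predictor: dict[str, DiagnosticMetrics]
    composite: DiagnosticMetrics


def recover_parameters(
    records: list[PatientAirwayRecord],
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
) -> RecoveredParameters:
    """Re-estimate the six classifiers' (sensitivity, specificity) from a cohort."""
    references = [mmc_reference(r.mmc_class) for r in records]
    if all(references) or not any(references):
        raise ValueError("cohort must contain both reference groups")
    all_flags = [evaluate_predictors(r, thresholds).as_tuple() for r in records]
    per_predictor = {
        name: compute_metrics(
            build_contingency([f[j] for f in all_flags], references)
        )
        for j, name in enumerate(PREDICTOR_NAMES)
    }
    composite = compute_metrics(
        build_contingency(
            [score_record(r, thresholds).positive for r in records], references
        )
    )
    return RecoveredParameters(per_predictor=per_predictor, composite=composite)


def analytic_composite_sensitivity(sensitivities: tuple[float, ...] = _DEFAULT_SENS) -> float:
    """Composite (any-flag) sensitivity under conditional independence: 1 - prod(1 - s_i)."""
    return 1.0 - float(np.prod([1.0 - s for s in sensitivities]))


def analytic_composite_specificity(specificities: tuple[float, ...] = _DEFAULT_SPEC) -> float:
    """Composite specificity under conditional independence: prod(spec_i)."""
    return float(np.prod(specificities))
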