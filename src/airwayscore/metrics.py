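"""2x2 contingency tables and diagnostic-accuracy indices with CIs.

Conventions: the *reference* (MMC difficult/easy) defines the columns,
the binary *prediction* the rows, so

    tp  prediction +, reference +        fp  prediction +, reference -
    fn  prediction -, reference +        tn  prediction -, reference -

A metric whose denominator is empty (e.g. PPV with no positive
predictions) is reported as ``None`` — explicitly undefined, never 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ContingencyTable2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def reference_positive(self) -> int:
        return self.tp + self.fn

    @property
    def reference_negative(self) -> int:
        return self.fp + self.tn

    @property
    def predicted_positive(self) -> int:
        return self.tp + self.fp

    @property
    def predicted_negative(self) -> int:
        return self.fn + self.tn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)

    def scaled(self, k: int) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.tp * k, self.fp * k, self.fn * k, self.tn * k)


def build_contingency(
    predictions: Sequence[bool | int],
    references: Sequence[bool | int],
) -> ContingencyTable2x2:
    """Cross-tabulate a binary prediction against the binary reference."""
    if len(predictions) != len(references):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(references)} references"
        )
    if len(predictions) == 0:
        raise ValueError("empty input")
    tp = fp = fn = tn = 0
    for p, r in zip(predictions, references):
        if p and r:
            tp += 1
        elif p and not r:
            fp += 1
        elif not p and r:
            fn += 1
        else:
            tn += 1
    return ContingencyTable2x2(tp, fp, fn, tn)


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion k/n with a two-sided confidence interval."""

    value: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int
    ci_level: float = 0.95

    @property
    def percent(self) -> float:
        return 100.0 * self.value


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: Optional[ProportionEstimate]
    specificity: Optional[ProportionEstimate]
    ppv: Optional[ProportionEstimate]
    npv: Optional[ProportionEstimate]
    accuracy: ProportionEstimate
    prevalence: ProportionEstimate
    table: ContingencyTable2x2
    ci_level: float = 0.95
    ci_method: str = "wilson"


def proportion_ci(
    k: int, n: int, ci_level: float = 0.95, method: str = "wilson"
) -> ProportionEstimate:
    """Point estimate and CI for k successes out of n.

    ``method`` is "wilson" (default; score interval, stays inside [0,1])
    or "clopper-pearson" (exact beta interval).
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"numerator {k} outside 0..{n}")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
    low, high = proportion_confint(k, n, alpha=1 - ci_level, method=sm_method)
    # both interval types live in [0,1] and bracket k/n; remove rounding fuzz
    # of order 1e-16 at the k=0 and k=n boundaries
    p = k / n
    return ProportionEstimate(
        value=p, ci_low=min(max(float(low), 0.0), p),
        ci_high=max(min(float(high), 1.0), p),
        numerator=k, denominator=n, ci_level=ci_level,
    )


def compute_metrics(
    table: ContingencyTable2x2,
    ci_level: float = 0.95,
    ci_method: str = "wilson",
) -> DiagnosticMetrics:
    """All standard diagnostic indices of a 2x2 table.

    sensitivity = tp/(tp+fn), specificity = tn/(fp+tn), ppv = tp/(tp+fp),
    npv = tn/(fn+tn), accuracy = (tp+tn)/n, prevalence = (tp+fn)/n.
    """
    if table.n == 0:
        raise ValueError("empty table")

    def maybe(k: int, n: int) -> Optional[ProportionEstimate]:
        if n == 0:
            return None
        return proportion_ci(k, n, ci_level, ci_method)

    return DiagnosticMetrics(
        sensitivity=maybe(table.tp, table.reference_positive),
        specificity=maybe(table.tn, table.reference_negative),
        ppv=maybe(table.tp, table.predicted_positive),
        npv=maybe(table.tn, table.predicted_negative),
        accuracy=proportion_ci(table.tp + table.tn, table.n, ci_level, ci_method),
        prevalence=proportion_ci(table.reference_positive, table.n, ci_level, ci_method),
        table=table,
        ci_level=ci_level,
        ci_method=ci_method,
    )


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero, matching how clinical tables print."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent_str(value: float, decimals: int = 2) -> str:
    """Format a proportion as a percentage string at fixed precision."""
    return f"{round_half_up(100.0 * value, decimals):.{decimals}f}"
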