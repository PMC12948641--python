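"""Paired agreement between the composite score and the MMC reference.

The two classifications are applied to the same patients, so their 2x2
cross-tabulation is a paired (matched) table.  McNemar's test asks whether
the two discordant cells b = fp (score positive / MMC easy) and
c = fn (score negative / MMC difficult) are symmetric; Cohen's kappa
measures chance-corrected agreement; Cohen's g is the paired effect size.

Two g variants are provided because the classical definition
(max(b,c)/(b+c) - 1/2) and the marginal-difference form (|b-c|/n) answer
slightly different questions; both are always reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .metrics import ContingencyTable2x2

G_VARIANTS = ("classic", "marginal_difference")


@dataclass(frozen=True)
class McNemarResult:
    chi2: float
    df: int
    p_value: float
    continuity_corrected: bool
    b: int
    c: int
    undefined: bool = False


def mcnemar_test(table: ContingencyTable2x2, continuity: bool = False) -> McNemarResult:
    """McNemar chi-square on the discordant cells of a paired 2x2 table.

    Without correction chi2 = (b-c)^2/(b+c); with Edwards' continuity
    correction chi2 = (|b-c|-1)^2/(b+c).  p is from chi-square with df=1
    (two-tailed by construction).  If b+c == 0 the test is undefined and
    (chi2=0, p=1) is returned with the ``undefined`` flag set.
    """
    b, c = table.fp, table.fn
    if b + c == 0:
        return McNemarResult(0.0, 1, 1.0, continuity, b, c, undefined=True)
    if continuity:
        chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        chi2 = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(float(chi2), 1, p, continuity, b, c)


def cohens_kappa(table: ContingencyTable2x2) -> float:
    """Cohen's kappa of a 2x2 agreement table.

    kappa = (p_o - p_e)/(1 - p_e) with p_o the observed agreement and p_e
    the chance agreement from the marginal products.  A degenerate table
    concentrated in one agreement cell has p_e = 1 and is returned as
    perfect agreement (1.0).
    """
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    tp, fp, fn, tn = table.as_tuple()
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa_closed_form(table: ContingencyTable2x2) -> float:
    """Algebraically equivalent kappa: 2(tp*tn - fp*fn) / ((tp+fp)(fp+tn) + (tp+fn)(fn+tn))."""
    tp, fp, fn, tn = table.as_tuple()
    denom = (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)
    if denom == 0:
        return 1.0
    return 2.0 * (tp * tn - fp * fn) / denom


@dataclass(frozen=True)
class CohensG:
    value: Optional[float]
    variant: str
    undefined: bool = False


def cohens_g(table: ContingencyTable2x2, variant: str = "classic") -> CohensG:
    """Effect size for the paired comparison.

    classic:              g = max(b,c)/(b+c) - 1/2   (undefined when b+c=0)
    marginal_difference:  g = |b-c|/n                (discordance imbalance
                          as a share of the whole cohort)
    """
    if variant not in G_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {G_VARIANTS}")
    b, c = table.fp, table.fn
    if variant == "classic":
        if b + c == 0:
            return CohensG(None, variant, undefined=True)
        return CohensG(max(b, c) / (b + c) - 0.5, variant)
    return CohensG(abs(b - c) / table.n, variant)


@dataclass(frozen=True)
class AgreementResult:
    mcnemar: McNemarResult
    kappa: float
    g_classic: CohensG
    g_marginal_difference: CohensG


def agreement_summary(table: ContingencyTable2x2, continuity: bool = False) -> AgreementResult:
    """McNemar, kappa and both g variants in one bundle."""
    return AgreementResult(
        mcnemar=mcnemar_test(table, continuity=continuity),
        kappa=cohens_kappa(table),
        g_classic=cohens_g(table, "classic"),
        g_marginal_difference=cohens_g(table, "marginal_difference"),
    )
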