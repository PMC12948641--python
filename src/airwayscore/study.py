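"""Printed summary statistics of the published 200-patient ED cohort.

These integers and percentages are the complete statistical footprint of
the study: every reported accuracy, agreement and ROC figure is a
deterministic function of them.  They are the inputs to the cohort
reconstruction and the ground truth for the reproduction harness.
"""

from __future__ import annotations

from .metrics import ContingencyTable2x2

N_TOTAL = 200
N_DIFFICULT = 82   # MMC class 3/4
N_EASY = 118       # MMC class 1/2

#: Per-predictor 2x2 tables against the MMC reference (tp, fp, fn, tn).
PREDICTOR_TABLES: dict[str, ContingencyTable2x2] = {
    "bmi": ContingencyTable2x2(39, 9, 43, 109),
    "retrognathia": ContingencyTable2x2(17, 11, 65, 107),
    "ulbt": ContingencyTable2x2(17, 6, 65, 112),
    "tmd": ContingencyTable2x2(40, 19, 42, 99),
    "hmd": ContingencyTable2x2(39, 17, 43, 101),
}

#: Composite (score >= 1) classifier against the MMC reference.
COMPOSITE_TABLE = ContingencyTable2x2(65, 34, 17, 84)

#: Cumulative percentages over cutoffs 1..5: sensitivity (difficult group)
#: and 1 - specificity (easy group), at 1 printed decimal.
CUMULATIVE_SENSITIVITY_PCT = (79.3, 62.2, 36.6, 7.3, 0.0)
CUMULATIVE_FPR_PCT = (28.8, 19.5, 3.4, 0.8, 0.0)

#: Overall frequency of each positive predictor (= tp + fp).
PREDICTOR_FREQUENCIES = {name: t.tp + t.fp for name, t in PREDICTOR_TABLES.items()}

#: Column-sum targets for the flag assignment, per reference group.
DIFFICULT_MARGINALS = {name: t.tp for name, t in PREDICTOR_TABLES.items()}
EASY_MARGINALS = {name: t.fp for name, t in PREDICTOR_TABLES.items()}
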