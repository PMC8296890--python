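"""2x2 contingency statistics linking alert/dose flags to AD labels.

Each binary flag (a single alert, the high-dose rule, an alert AND-ed with
the dose rule, or the any-alert union) is crossed with the AD label to give
a 2x2 table: AD-positive flagged drugs are true positives, AD-negative
flagged drugs false positives. The table summary mirrors toxicology
screening practice: sensitivity, PPV, FPR (plus specificity and NPV), the
uncorrected cross-product odds ratio — with a Haldane-Anscombe +0.5
correction only when a cell is zero — and a two-sided Fisher exact p-value.

No multiple-testing correction is applied by default (association tables
report raw per-alert p-values); a Benjamini-Hochberg column is available
on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .screening import ADLabel, AlertMatchMatrix, DoseRule

__all__ = [
    "ContingencyTable",
    "ConfusionMetrics",
    "AssociationResult",
    "contingency_from_flags",
    "sample_odds_ratio",
    "fisher_exact_p",
    "confusion_metrics",
    "cofactor_flag",
    "any_alert_flag",
    "associate_all",
    "round_percent",
    "round_or",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of flag vs AD label.

    tp: AD-positive and flagged; fn: AD-positive, unflagged;
    fp: AD-negative and flagged; tn: AD-negative, unflagged.
    Counts may be real-valued to hold expectations from the synthetic
    generator's closed forms.
    """

    tp: float
    fn: float
    fp: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise DataError(f"contingency counts must be >= 0, got {self}")

    @property
    def n_positive(self) -> float:
        return self.tp + self.fn

    @property
    def n_negative(self) -> float:
        return self.fp + self.tn

    @property
    def total(self) -> float:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.tp, self.fn, self.fp, self.tn)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Screening ratios of a 2x2 table; None where the denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    fpr: float | None


@dataclass(frozen=True)
class AssociationResult:
    """One association-table row: a flag's 2x2 table and its statistics."""

    flag_id: str
    description: str
    table: ContingencyTable
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    fpr: float | None
    odds_ratio: float
    p_value: float
    zero_cell_corrected: bool


def contingency_from_flags(
    labels: Sequence[ADLabel] | np.ndarray, flags: Sequence[bool] | np.ndarray
) -> ContingencyTable:
    """Cross-tabulate per-drug boolean flags against AD labels.

    ``labels`` may be :class:`ADLabel` values or a 0/1 array. Requires both
    classes to be present (a single-class vector cannot form a valid
    screen).
    """
    y = np.asarray(
        [lab.value if isinstance(lab, ADLabel) else int(lab) for lab in labels], dtype=int
    )
    f = np.asarray(flags, dtype=bool)
    if y.shape != f.shape:
        raise DataError(f"labels ({y.shape}) and flags ({f.shape}) differ in length")
    if y.all() or not y.any():
        raise DataError("labels contain a single class; need both AD-positive and -negative")
    pos = y == 1
    return ContingencyTable(
        tp=int(np.sum(pos & f)),
        fn=int(np.sum(pos & ~f)),
        fp=int(np.sum(~pos & f)),
        tn=int(np.sum(~pos & ~f)),
    )


def sample_odds_ratio(table: ContingencyTable) -> float:
    """Uncorrected cross-product odds ratio (tp*tn)/(fn*fp).

    When any cell is zero, the Haldane-Anscombe correction adds 0.5 to all
    four cells; :attr:`ContingencyTable.has_zero_cell` tells whether the
    correction applied.
    """
    tp, fn, fp, tn = table.tp, table.fn, table.fp, table.tn
    if table.has_zero_cell:
        tp, fn, fp, tn = tp + 0.5, fn + 0.5, fp + 0.5, tn + 0.5
    return (tp * tn) / (fn * fp)


def fisher_exact_p(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (point-probability / minimum-likelihood rule).

    Sums hypergeometric probabilities of every margin-fixed table whose
    point probability does not exceed that of the observed table.
    """
    tab = [[int(table.tp), int(table.fp)], [int(table.fn), int(table.tn)]]
    return float(stats.fisher_exact(tab, alternative="two-sided")[1])


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(table: ContingencyTable) -> ConfusionMetrics:
    """Sensitivity, specificity, PPV, NPV and FPR; undefined ratios are None."""
    return ConfusionMetrics(
        sensitivity=_ratio(table.tp, table.tp + table.fn),
        specificity=_ratio(table.tn, table.tn + table.fp),
        ppv=_ratio(table.tp, table.tp + table.fp),
        npv=_ratio(table.tn, table.tn + table.fn),
        fpr=_ratio(table.fp, table.fp + table.tn),
    )


def cofactor_flag(alert_flag, dose_flag):
    """Alert AND high-dose: the dose-co-factored flag. Accepts scalars or arrays."""
    return np.logical_and(alert_flag, dose_flag)


def any_alert_flag(match_row: Sequence[bool] | np.ndarray) -> np.ndarray | bool:
    """Union flag: True iff any alert matches.

    Accepts one drug's row (1-D, returns bool) or a full drugs x alerts
    matrix (2-D, returns the per-drug vector).
    """
    row = np.asarray(match_row, dtype=bool)
    if row.size == 0 or (row.ndim == 2 and row.shape[1] == 0):
        raise DataError("any_alert_flag needs at least one alert column")
    if row.ndim == 1:
        return bool(row.any())
    return row.any(axis=1)


def round_percent(x: float) -> int:
    """Nearest-percent rounding, half away from zero (table convention)."""
    return int(math.floor(100.0 * x + 0.5)) if x >= 0 else -int(math.floor(-100.0 * x + 0.5))


def round_or(x: float) -> float:
    """Odds ratio rounded to 2 decimals, half away from zero."""
    return math.floor(100.0 * x + 0.5) / 100.0 if x >= 0 else -math.floor(-100.0 * x + 0.5) / 100.0


def _result(flag_id: str, description: str, labels, flags) -> AssociationResult:
    table = contingency_from_flags(labels, flags)
    m = confusion_metrics(table)
    return AssociationResult(
        flag_id=flag_id,
        description=description,
        table=table,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        ppv=m.ppv,
        npv=m.npv,
        fpr=m.fpr,
        odds_ratio=sample_odds_ratio(table),
        p_value=fisher_exact_p(table),
        zero_cell_corrected=table.has_zero_cell,
    )


def associate_all(
    matrix: AlertMatchMatrix,
    doses: Sequence[float | None],
    labels: Sequence[ADLabel],
    rule: DoseRule = DoseRule(),
    descriptions: dict[str, str] | None = None,
    sort_by: str = "n_pos_matched",
) -> list[AssociationResult]:
    """Full association sweep: per-alert, per-alert AND dose, dose alone, any-alert.

    ``doses`` and ``labels`` must align with ``matrix.drug_ids``. Drugs with
    a missing dose keep their alert-only rows but count as below-cutoff for
    the dose-co-factored rows. ``sort_by`` is ``'n_pos_matched'`` (descending
    AD-positive match count, the headline-table ordering) or ``'p_value'``
    (ascending).
    """
    n = len(matrix.drug_ids)
    if len(doses) != n or len(labels) != n:
        raise DataError("doses and labels must align with the match matrix drugs")
    descriptions = descriptions or {}
    dose_vec = np.array(
        [d is not None and d >= rule.cutoff_mg for d in doses], dtype=bool
    )
    results: list[AssociationResult] = []
    for j, alert_id in enumerate(matrix.alert_ids):
        col = matrix.matches[:, j]
        desc = descriptions.get(alert_id, alert_id)
        results.append(_result(alert_id, desc, labels, col))
        results.append(
            _result(
                f"{alert_id}+dose",
                f"{desc} + daily dose >= {rule.cutoff_mg:g} mg",
                labels,
                cofactor_flag(col, dose_vec),
            )
        )
    results.append(
        _result(
            "any_alert",
            "all structural alerts combined",
            labels,
            any_alert_flag(matrix.matches),
        )
    )
    results.append(
        _result(
            "high_dose",
            f"high daily dose (>= {rule.cutoff_mg:g} mg)",
            labels,
            dose_vec,
        )
    )
    if sort_by == "n_pos_matched":
        results.sort(key=lambda r: -r.table.tp)
    elif sort_by == "p_value":
        results.sort(key=lambda r: r.p_value)
    else:
        raise DataError(f"unknown sort key {sort_by!r}")
    return results


def results_to_frame(
    results: Sequence[AssociationResult],
    rounded: bool = True,
    fdr_column: bool = False,
) -> pd.DataFrame:
    """Association results as a DataFrame mirroring the screening-table layout.

    With ``rounded=True`` percentages are nearest-integer and ORs 2-decimal
    (printing convention); raw ratios otherwise. ``fdr_column=True`` appends
    Benjamini-Hochberg adjusted p-values (off by default: the headline
    analysis reports raw per-alert p-values).
    """
    rows = []
    for r in results:
        pct = (lambda v: (round_percent(v) if rounded else v) if v is not None else None)
        rows.append(
            {
                "flag_id": r.flag_id,
                "description": r.description,
                "n_pos_matched": r.table.tp,
                "n_neg_matched": r.table.fp,
                "sensitivity": pct(r.sensitivity),
                "ppv": pct(r.ppv),
                "fpr": pct(r.fpr),
                "or": round_or(r.odds_ratio) if rounded else r.odds_ratio,
                "p_value": r.p_value,
                "zero_cell_corrected": r.zero_cell_corrected,
            }
        )
    frame = pd.DataFrame(rows)
    if fdr_column and len(frame):
        frame["p_bh"] = stats.false_discovery_control(frame["p_value"].to_numpy(), method="bh")
    return frame
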