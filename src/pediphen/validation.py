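"""Chart-review validation: confusion matrices and operating characteristics.

Validation is one-vs-rest per target category: for the T1DM target, every
patient whose gold label is not T1DM counts as a negative, whatever their
actual label (T2DM, other DM, or no diagnosis).  INDETERMINATE assignments
(tied diagnosis ratios) are excluded from all denominators, mirroring how
tied cases were dropped before review.  Percentages round half away from
zero to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ValidationMetrics",
    "confusion_from_labels",
    "metrics_from_confusion",
    "validation_report",
    "percent_agreement",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    target_category: str

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def round_pct(proportion: float | None, decimals: int = 1) -> float | None:
    """Percent rendering: half-away-from-zero rounding to ``decimals``."""
    if proportion is None:
        return None
    scaled = proportion * 100.0 * 10**decimals
    return math.floor(scaled + 0.5) / 10**decimals


@dataclass(frozen=True)
class ValidationMetrics:
    """Sensitivity, specificity, PPV, NPV as proportions in [0, 1].

    A metric whose denominator is zero is None (undefined), never silent NaN.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    matrix: ConfusionMatrix

    def as_percents(self) -> dict[str, float | None]:
        return {
            "sensitivity_pct": round_pct(self.sensitivity),
            "specificity_pct": round_pct(self.specificity),
            "ppv_pct": round_pct(self.ppv),
            "npv_pct": round_pct(self.npv),
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def metrics_from_confusion(matrix: ConfusionMatrix) -> ValidationMetrics:
    """sens = tp/(tp+fn); spec = tn/(tn+fp); ppv = tp/(tp+fp); npv = tn/(tn+fn)."""
    if matrix.n == 0:
        raise ValueError("all-zero confusion matrix")
    return ValidationMetrics(
        sensitivity=_ratio(matrix.tp, matrix.tp + matrix.fn),
        specificity=_ratio(matrix.tn, matrix.tn + matrix.fp),
        ppv=_ratio(matrix.tp, matrix.tp + matrix.fp),
        npv=_ratio(matrix.tn, matrix.tn + matrix.fn),
        matrix=matrix,
    )


_GOLD_ALLOWED = {"T1DM", "T2DM", "OTHER_DM", "NO_DX"}


def _merge(assignments: pd.DataFrame, gold_labels: pd.DataFrame) -> pd.DataFrame:
    bad = sorted(set(gold_labels["reviewed_label"]) - _GOLD_ALLOWED)
    if bad:
        raise ValueError(f"gold label values outside {sorted(_GOLD_ALLOWED)}: {bad}")
    merged = gold_labels.merge(
        assignments[["patient_id", "category"]], on="patient_id", how="left", validate="1:1"
    )
    unmatched = merged.loc[merged["category"].isna(), "patient_id"].tolist()
    if unmatched:
        raise ValueError(f"gold-labeled patients with no assignment: {unmatched}")
    return merged


def confusion_from_labels(
    assignments: pd.DataFrame, gold_labels: pd.DataFrame, target_category: str
) -> ConfusionMatrix:
    """One-vs-rest confusion matrix over evaluable (non-INDETERMINATE) patients.

    ``assignments`` needs columns patient_id and category; ``gold_labels``
    needs patient_id and reviewed_label.
    """
    merged = _merge(assignments, gold_labels)
    merged = merged[merged["category"] != "INDETERMINATE"]
    pred = merged["category"] == target_category
    truth = merged["reviewed_label"] == target_category
    return ConfusionMatrix(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
        target_category=target_category,
    )


def validation_report(
    assignments: pd.DataFrame,
    gold_labels: pd.DataFrame,
    targets: tuple[str, ...] = ("T1DM", "T2DM"),
) -> pd.DataFrame:
    """Per-target operating characteristics as a review-table-style frame.

    Columns: category, n_reviewed (assigned positive), n_confirmed (true
    positive), the four percent metrics, and the INDETERMINATE exclusion count.
    """
    if gold_labels.empty:
        raise ValueError("empty gold label set")
    merged = _merge(assignments, gold_labels)
    n_indet = int((merged["category"] == "INDETERMINATE").sum())
    rows = []
    for target in targets:
        cm = confusion_from_labels(assignments, gold_labels, target)
        m = metrics_from_confusion(cm)
        rows.append(
            {
                "category": target,
                "n_reviewed": cm.tp + cm.fp,
                "n_confirmed": cm.tp,
                **m.as_percents(),
                "n_indeterminate_excluded": n_indet,
            }
        )
    return pd.DataFrame(rows)


def percent_agreement(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Plain percent agreement between two reviewers' label vectors."""
    if len(labels_a) != len(labels_b) or len(labels_a) == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    return float((labels_a.to_numpy() == labels_b.to_numpy()).mean())
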