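"""Diagnostic-accuracy evaluation and privacy-masked reporting.

SCLC is the positive class throughout. From a confusion matrix
(TP, FP, TN, FN) the module derives sensitivity TP/(TP+FN), specificity
TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN) and the SCLC:NSCLC case-mix ratio
TP/FP, carrying any zero-denominator metric as undefined rather than 0.

Reported tables apply registry-style small-cell suppression: any cell below
the threshold (default 11) is replaced by "NR", and when a label margin is
public, the complement cell within that margin is suppressed too, so that no
masked cell can be recovered by subtraction from displayed integers and
margins. When TP is masked, sensitivity is shown as an upper bound
"< threshold/(TP+FN)" (rounded up to 2 decimals); when FP is masked,
specificity is shown as a lower bound "> 1 - threshold/(FP+TN)" (rounded
down). PPV and NPV are displayed as computed, matching published practice.
The bound formulae are an interpretation of the published display pattern,
not a documented rule; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._util import bound_lower, bound_upper, ratio_display
from .phenotype import AlgorithmRule, apply_rule
from .synth import NSCLC, SCLC

NR = "NR"


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts with SCLC as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def gold_positive(self) -> int:
        return self.tp + self.fn

    @property
    def gold_negative(self) -> int:
        return self.fp + self.tn


def confusion_matrix(predictions: pd.Series, gold_labels: pd.Series) -> ConfusionMatrix:
    """Count agreement between predicted and gold labels over one patient set."""
    pred = pd.Series(predictions)
    gold = pd.Series(gold_labels)
    if len(pred) != len(gold) or not pred.index.sort_values().equals(gold.index.sort_values()):
        raise ValueError("predictions and gold labels must cover the same patients")
    gold = gold.reindex(pred.index)
    p_pos = pred == SCLC
    g_pos = gold == SCLC
    return ConfusionMatrix(
        tp=int((p_pos & g_pos).sum()),
        fp=int((p_pos & ~g_pos).sum()),
        tn=int((~p_pos & ~g_pos).sum()),
        fn=int((~p_pos & g_pos).sum()),
    )


@dataclass(frozen=True)
class MetricSet:
    """Accuracy metrics; ``None`` marks an undefined (0/0) metric."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    case_ratio: float | None


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return MetricSet(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        case_ratio=_ratio(cm.tp, cm.fp),
    )


def invert_target(m: MetricSet) -> MetricSet:
    """Re-target the metrics at NSCLC (swap sens/spec and PPV/NPV).

    A display transform only: classifying NSCLC with the complement rule has
    sensitivity equal to the SCLC rule's specificity, and so on.
    """
    return MetricSet(
        sensitivity=m.specificity,
        specificity=m.sensitivity,
        ppv=m.npv,
        npv=m.ppv,
        case_ratio=None,
    )


def case_ratio_report(cm: ConfusionMatrix) -> float | None:
    """SCLC-per-NSCLC ratio TP/FP among algorithm-positives, 1-decimal display."""
    if cm.fp == 0:
        return None
    return round(cm.tp / cm.fp, 1)


@dataclass(frozen=True)
class MaskedReport:
    """Display form of one confusion matrix + metrics after suppression.

    Cells are ints or the string ``"NR"``; metrics are display strings
    (3-decimal values, bound strings, or ``""`` when undefined).
    """

    tp: int | str
    fp: int | str
    tn: int | str
    fn: int | str
    sensitivity: str
    specificity: str
    ppv: str
    npv: str

    def cells(self) -> dict[str, int | str]:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def apply_nr_masking(
    cm: ConfusionMatrix,
    metrics: MetricSet | None = None,
    threshold: int = 11,
    public_margins: Iterable[str] = (SCLC, NSCLC),
) -> MaskedReport:
    """Suppress sub-threshold cells and their derivable complements.

    ``public_margins`` names the gold-label margins a reader is assumed to
    know (from population tables published elsewhere); the complement of a
    suppressed cell is itself suppressed only within a public margin. With no
    public margins, only primary (< threshold) cells are masked.
    """
    public = set(public_margins)
    mask_tp = cm.tp < threshold
    mask_fn = cm.fn < threshold
    mask_fp = cm.fp < threshold
    mask_tn = cm.tn < threshold
    if SCLC in public:
        mask_tp = mask_fn = mask_tp or mask_fn
    if NSCLC in public:
        mask_fp = mask_tn = mask_fp or mask_tn

    tp_disp: int | str = NR if mask_tp else cm.tp
    fn_disp: int | str = NR if mask_fn else cm.fn
    fp_disp: int | str = NR if mask_fp else cm.fp
    tn_disp: int | str = NR if mask_tn else cm.tn

    if mask_tp and cm.gold_positive > 0:
        sens = bound_upper(threshold, cm.gold_positive)
    else:
        sens = ratio_display(cm.tp, cm.gold_positive)
    if mask_fp and cm.gold_negative > 0:
        spec = bound_lower(threshold, cm.gold_negative)
    else:
        spec = ratio_display(cm.tn, cm.gold_negative)

    return MaskedReport(
        tp=tp_disp,
        fp=fp_disp,
        tn=tn_disp,
        fn=fn_disp,
        sensitivity=sens,
        specificity=spec,
        ppv=ratio_display(cm.tp, cm.tp + cm.fp),
        npv=ratio_display(cm.tn, cm.tn + cm.fn),
    )


@dataclass(frozen=True)
class RuleResult:
    """One (algorithm, population) evaluation."""

    rule: str
    population: str
    n: int
    cm: ConfusionMatrix
    metrics: MetricSet


def evaluate_rules(
    rules: Sequence[AlgorithmRule],
    cohort: pd.DataFrame,
    flags: pd.DataFrame,
    populations: Sequence[str] = ("full", "treated"),
) -> list[RuleResult]:
    """Evaluate each rule on each population of one cohort split.

    ``"full"`` is every cohort member; ``"treated"`` restricts to the
    outpatient systemic-therapy subset. Because all built-in rules key on
    treatment exposures, TP and FP are identical between the two populations
    (only TN/FN — hence specificity, NPV, never PPV — change).
    """
    results: list[RuleResult] = []
    gold = cohort.set_index("patient_id")["gold_label"]
    treated = cohort.set_index("patient_id")["treated"].astype(bool)
    flags = flags.reindex(gold.index)
    for rule in rules:
        pred = apply_rule(rule, flags)
        for population in populations:
            if population == "full":
                sel = gold.index
            elif population == "treated":
                sel = gold.index[treated]
            else:
                raise ValueError(f"unknown population {population!r}")
            cm = confusion_matrix(pred.loc[sel], gold.loc[sel])
            results.append(RuleResult(rule.name, population, len(sel), cm, compute_metrics(cm)))
    return results


REPORT_COLUMNS = [
    "Algorithm",
    "Population",
    "True Positive",
    "False Positive",
    "True Negative",
    "False Negative",
    "Sensitivity",
    "Specificity",
    "PPV",
    "NPV",
]


def render_report(
    results: Sequence[RuleResult],
    mask: bool = True,
    threshold: int = 11,
    public_margins: Iterable[str] = (SCLC, NSCLC),
) -> pd.DataFrame:
    """Result table in the published column layout (optionally unmasked)."""
    rows = []
    for r in results:
        if mask:
            rep = apply_nr_masking(r.cm, r.metrics, threshold, public_margins)
            cells = (rep.tp, rep.fp, rep.tn, rep.fn)
            metrics = (rep.sensitivity, rep.specificity, rep.ppv, rep.npv)
        else:
            cells = (r.cm.tp, r.cm.fp, r.cm.tn, r.cm.fn)
            metrics = (
                ratio_display(r.cm.tp, r.cm.gold_positive),
                ratio_display(r.cm.tn, r.cm.gold_negative),
                ratio_display(r.cm.tp, r.cm.tp + r.cm.fp),
                ratio_display(r.cm.tn, r.cm.tn + r.cm.fn),
            )
        rows.append([r.rule, r.population, *cells, *metrics])
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
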