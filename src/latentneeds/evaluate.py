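"""Confusion matrices, the four derived metrics, and comparison reports.

The positive class is "latent need = yes" throughout: TP counts needs
records correctly found.  Display rounding is half away from zero at two
decimals, matching the precision of the published tables this layout
mirrors (rows Accuracy/Precision/Recall/F-measure then TN/FP/FN/TP,
columns with/without selection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

METRIC_NAMES = ("accuracy", "precision", "recall", "f_measure")


def round2(x: float) -> float:
    """Round to 2 decimals, halves away from zero."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    precision_undefined: bool = False
    recall_undefined: bool = False

    @property
    def rounded(self) -> dict[str, float]:
        return {name: round2(getattr(self, name)) for name in METRIC_NAMES}


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    positive_class: str = "yes",
) -> ConfusionMatrix:
    """Standard 2x2 counts with ``positive_class`` as positive."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label list lengths differ: {len(true_labels)} true vs "
            f"{len(predicted_labels)} predicted"
        )
    if not true_labels:
        raise ValueError("empty label lists")
    tp = fp = fn = tn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall and F-measure from a 2x2 matrix.

    A zero denominator (no predicted positives, or no true positives in
    the test fold) sets the corresponding undefined flag and reports 0
    rather than raising.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is all zero")
    accuracy = (cm.tp + cm.tn) / cm.total
    precision_undef = (cm.tp + cm.fp) == 0
    recall_undef = (cm.tp + cm.fn) == 0
    precision = 0.0 if precision_undef else cm.tp / (cm.tp + cm.fp)
    recall = 0.0 if recall_undef else cm.tp / (cm.tp + cm.fn)
    f = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f_measure=f,
        precision_undefined=precision_undef,
        recall_undefined=recall_undef,
    )


# ---------------------------------------------------------------------------
# Comparison report

@dataclass
class CellResult:
    """One (condition, family, role) evaluation cell."""

    cm: ConfusionMatrix
    report: MetricsReport


def compare_report(
    results: dict,
    config: Optional[dict] = None,
) -> dict:
    """Tabulate with/without-selection results side by side.

    ``results`` maps ``(condition, role, family)`` — condition in
    ``{"with_z", "without_z"}`` — to a :class:`CellResult`.  For every
    (role, family) pair present in both conditions, the condition with
    the higher rounded F-measure is marked the winner ("tie" on equality,
    "absent" when one side is missing).  The embedded config records the
    seeds and mode so every number is traceable to a run.
    """
    pairs = sorted({(role, fam) for (_c, role, fam) in results})
    if not any(
        ("with_z", role, fam) in results and ("without_z", role, fam) in results
        for role, fam in pairs
    ):
        raise ValueError("need at least one complete (with, without) pair")
    cells = []
    for role, fam in pairs:
        entry: dict = {"role": role, "family": fam}
        fs = {}
        for cond in ("with_z", "without_z"):
            cell = results.get((cond, role, fam))
            if cell is None:
                entry[cond] = None
                continue
            entry[cond] = {
                **cell.report.rounded,
                "TN": cell.cm.tn,
                "FP": cell.cm.fp,
                "FN": cell.cm.fn,
                "TP": cell.cm.tp,
            }
            fs[cond] = cell.report.rounded["f_measure"]
        if len(fs) < 2:
            entry["higher_f"] = "absent"
        elif fs["with_z"] > fs["without_z"]:
            entry["higher_f"] = "with_z"
        elif fs["with_z"] < fs["without_z"]:
            entry["higher_f"] = "without_z"
        else:
            entry["higher_f"] = "tie"
        cells.append(entry)
    return {"cells": cells, "config": config or {}}


_ROW_ORDER = ["accuracy", "precision", "recall", "f_measure", "TN", "FP", "FN", "TP"]
_ROW_TITLES = {
    "accuracy": "Accuracy",
    "precision": "Precision",
    "recall": "Recall",
    "f_measure": "F-measure",
}


def report_to_markdown(report: dict) -> str:
    """Human-readable table: one block per (role, family) cell."""
    lines = []
    for cell in report["cells"]:
        lines.append(f"### {cell['role']} / {cell['family']}")
        lines.append("")
        lines.append("| measure | with selection | without selection |")
        lines.append("|---|---|---|")
        for row in _ROW_ORDER:
            vals = []
            for cond in ("with_z", "without_z"):
                block = cell.get(cond)
                vals.append("—" if block is None else f"{block[row]}")
            title = _ROW_TITLES.get(row, row)
            lines.append(f"| {title} | {vals[0]} | {vals[1]} |")
        lines.append("")
        lines.append(f"Higher F-measure: {cell['higher_f']}")
        lines.append("")
    cfg = report.get("config") or {}
    if cfg:
        lines.append("Run configuration: " + json.dumps(cfg, ensure_ascii=False))
        lines.append("")
    return "\n".join(lines)


def write_report(report: dict, path_json: str | Path, path_md: Optional[str | Path] = None) -> None:
    Path(path_json).write_text(
        json.dumps(report, indent=2, ensure_ascii=False), encoding="utf-8"
    )
    if path_md is not None:
        Path(path_md).write_text(report_to_markdown(report), encoding="utf-8")
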