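"""Scoring predicted lifting zones against motion-capture-style truth.

A trial is scored all-or-nothing: the predicted 12-grid zone either
matches the reference zone (100%) or it does not (0%); overall accuracy
is the fraction of matching trials.  Coarser views are also computed:
per-axis band accuracy, a per-subject agreement grid (0-3 matches over
the three repetitions of each zone), and 3x3 grouped-risk confusion
matrices with row-normalized rates, precision, recall and F-scores.

Precision is computed from raw counts (diagonal / column total), recall
from raw counts (diagonal / row total); row rates are counts divided by
the true-class totals so that every reference row sums to 1.  Macro
averages are unweighted means over the three risk classes; the
class-size-weighted recall equals trace/total and is the single-number
"overall accuracy" view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .zoning import DEFAULT_GROUPING, RISK_LEVELS, Zone, group_from_zone

__all__ = [
    "TrialRecord",
    "AgreementGrid",
    "ConfusionSummary",
    "f_score",
    "agreement_grid",
    "zone12_accuracy",
    "vh_band_accuracy",
    "confusion_counts",
    "metrics",
    "mean_error",
]


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class TrialRecord:
    """One scored lifting trial."""

    subject: str
    repetition: int
    true_zone: int
    predicted_zone: int
    model: str = ""

    def __post_init__(self) -> None:
        if self.repetition not in (1, 2, 3):
            raise ValueError(f"repetition must be 1-3, got {self.repetition}")
        for z in (self.true_zone, self.predicted_zone):
            if not 1 <= z <= 12:
                raise ValueError(f"zone index must be 1-12, got {z}")


@dataclass
class AgreementGrid:
    """Subject x zone matrix of exact-match counts (0-3 of 3 trials)."""

    counts: pd.DataFrame  # index: subject, columns: zone 1..12

    @property
    def total_matches(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class ConfusionSummary:
    """3x3 grouped-risk confusion counts and the derived metrics."""

    counts: pd.DataFrame          # rows: true group, cols: predicted group
    row_rates: pd.DataFrame       # counts / true-class totals
    precision: pd.Series
    recall: pd.Series
    f_score: pd.Series
    macro_precision: float
    macro_recall: float
    macro_f: float
    weighted_recall: float        # trace / total
    undefined_precision: list[str] = field(default_factory=list)


def _check_nonempty(records) -> list:
    records = list(records)
    if not records:
        raise ValueError("no trial records")
    return records


def agreement_grid(records: list[TrialRecord]) -> AgreementGrid:
    """Count, per subject and true zone, how many of the (up to 3)
    repetitions were predicted exactly right."""
    records = _check_nonempty(records)
    subjects = sorted({r.subject for r in records})
    counts = pd.DataFrame(0, index=subjects, columns=range(1, 13))
    reps = pd.DataFrame(0, index=subjects, columns=range(1, 13))
    for r in records:
        reps.loc[r.subject, r.true_zone] += 1
        if reps.loc[r.subject, r.true_zone] > 3:
            raise ValueError(
                f"more than 3 repetitions for subject {r.subject}, zone {r.true_zone}"
            )
        if r.predicted_zone == r.true_zone:
            counts.loc[r.subject, r.true_zone] += 1
    return AgreementGrid(counts=counts)


def zone12_accuracy(records: list[TrialRecord]) -> float:
    """Proportion of trials whose predicted zone matches exactly.

    Each trial contributes 0 or 1; report as a percentage rounded to
    the nearest integer at presentation time (15/360 -> 4%)."""
    records = _check_nonempty(records)
    matches = sum(r.predicted_zone == r.true_zone for r in records)
    return matches / len(records)


def vh_band_accuracy(records: list[TrialRecord]) -> tuple[float, float]:
    """Per-axis accuracies: proportion of trials with the correct
    vertical band and, independently, the correct horizontal band."""
    records = _check_nonempty(records)
    v_ok = h_ok = 0
    for r in records:
        zt, zp = Zone.from_index(r.true_zone), Zone.from_index(r.predicted_zone)
        v_ok += zt.v_band == zp.v_band
        h_ok += zt.h_band == zp.h_band
    n = len(records)
    return v_ok / n, h_ok / n


def confusion_counts(
    records: list[TrialRecord], grouping: dict[int, str] = DEFAULT_GROUPING
) -> pd.DataFrame:
    """3x3 grouped-risk confusion counts.

    Rows are the true (reference) risk group, columns the predicted
    group.  With the full balanced design (10 subjects x 3 reps x 12
    zones) the row totals are 60/120/180 for low/medium/high."""
    records = _check_nonempty(records)
    counts = pd.DataFrame(0, index=list(RISK_LEVELS), columns=list(RISK_LEVELS))
    for r in records:
        counts.loc[
            group_from_zone(r.true_zone, grouping),
            group_from_zone(r.predicted_zone, grouping),
        ] += 1
    return counts


def metrics(counts: pd.DataFrame) -> ConfusionSummary:
    """Precision/recall/F-score summary of a 3x3 confusion matrix.

    A zero column total makes that class's precision undefined; it is
    reported as 0 and the class is listed in ``undefined_precision``.
    """
    counts = counts.astype(int)
    if (counts.to_numpy() < 0).any():
        raise ValueError("confusion counts must be non-negative")
    mat = counts.to_numpy(dtype=float)
    row_totals = mat.sum(axis=1)
    col_totals = mat.sum(axis=0)
    diag = np.diag(mat)

    undefined = [c for c, tot in zip(counts.columns, col_totals) if tot == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col_totals > 0, diag / np.where(col_totals > 0, col_totals, 1), 0.0)
        recall = np.where(row_totals > 0, diag / np.where(row_totals > 0, row_totals, 1), 0.0)
        pr = precision + recall
        f_score = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
        rates = mat / np.where(row_totals[:, None] > 0, row_totals[:, None], 1)

    total = mat.sum()
    return ConfusionSummary(
        counts=counts,
        row_rates=pd.DataFrame(rates, index=counts.index, columns=counts.columns),
        precision=pd.Series(precision, index=counts.columns),
        recall=pd.Series(recall, index=counts.index),
        f_score=pd.Series(f_score, index=counts.index),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f=float(f_score.mean()),
        weighted_recall=float(diag.sum() / total) if total > 0 else 0.0,
        undefined_precision=undefined,
    )


def mean_error(results: pd.DataFrame, v_bands=None, h_bands=None) -> dict:
    """Mean signed errors (predicted - true) in metres, overall and per
    true band.

    ``results`` needs columns true_v, true_h, pred_v, pred_h and,
    for the per-band breakdown, true_v_band / true_h_band (1-based).
    """
    if len(results) == 0:
        raise ValueError("no paired results")
    for col in ("true_v", "true_h", "pred_v", "pred_h"):
        if col not in results.columns:
            raise ValueError(f"missing column {col!r}")
    ev = results["pred_v"] - results["true_v"]
    eh = results["pred_h"] - results["true_h"]
    out = {"v": float(ev.mean()), "h": float(eh.mean()), "v_by_band": {}, "h_by_band": {}}
    if "true_v_band" in results.columns:
        out["v_by_band"] = {
            int(b): float(ev[results["true_v_band"] == b].mean())
            for b in sorted(results["true_v_band"].unique())
        }
    if "true_h_band" in results.columns:
        out["h_by_band"] = {
            int(b): float(eh[results["true_h_band"] == b].mean())
            for b in sorted(results["true_h_band"].unique())
        }
    return out
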