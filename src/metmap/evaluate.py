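"""Metrics, binomial half-widths, comparison tables, metastases maps.

Accuracy, precision, recall and F1 (the harmonic mean of precision and
recall, the study's headline metric) are computed from confusion counts.
Published accuracy cells carry ±95% margins that are Wald binomial
half-widths, 1.96·sqrt(p(1−p)/n) with n the split size; precision/recall
margins use their own denominators (predicted-positive and actual-positive
counts).

A *metastases map* is the corpus-scale product of weak labeling: for every
patient, per organ, the predicted label and confidence at each exam date,
with the first predicted-positive date derived per organ.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .organs import OrganSite
from .preprocess import HistoryDocument, build_documents
from .reports import POSITIVE, StructuredReport, build_timelines


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred must have the same length")
        return cls(
            tp=int(((yt == 1) & (yp == 1)).sum()),
            fp=int(((yt == 0) & (yp == 1)).sum()),
            tn=int(((yt == 0) & (yp == 0)).sum()),
            fn=int(((yt == 1) & (yp == 0)).sum()),
        )


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    accuracy_halfwidth: float
    n: int
    degenerate: bool = False  # precision/recall denominators were zero


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def wald_halfwidth(p: float, n: int) -> float:
    """95% Wald binomial half-width 1.96·sqrt(p(1−p)/n).

    Returned on the same scale as ``p`` (a proportion); multiply by 100 to
    match percentage cells.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0,1], got {p}")
    return 1.96 * math.sqrt(p * (1.0 - p) / n)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy/precision/recall/F1 with a 95% accuracy half-width.

    Precision (recall) is defined as 0 with a degenerate flag when there
    are no predicted (actual) positives.
    """
    n = counts.n
    if n == 0:
        raise ValueError("cannot compute metrics on zero evaluated documents")
    accuracy = (counts.tp + counts.tn) / n
    degenerate = False
    if counts.tp + counts.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        accuracy_halfwidth=wald_halfwidth(accuracy, n),
        n=n,
        degenerate=degenerate,
    )


def prevalence(labels: Sequence[int]) -> tuple[int, int, float]:
    """(positive count, total, percentage rounded to one decimal)."""
    labels = np.asarray(labels, dtype=int)
    total = labels.size
    if total == 0:
        raise ValueError("cannot compute prevalence of an empty label set")
    pos = int((labels == 1).sum())
    return pos, total, round(100.0 * pos / total, 1)


# ---------------------------------------------------------------------------
# comparison table
# ---------------------------------------------------------------------------

_METRICS = ("accuracy", "precision", "recall", "f1")


def comparison_table(
    results: Mapping[str, Mapping[tuple[str, str], ConfusionCounts]],
) -> pd.DataFrame:
    """Table-style comparison of models over (organ, split) cells.

    ``results[model][(organ, split)]`` holds the confusion counts of one
    evaluation.  Every model must cover the same (organ, split) cells with
    the same n (same data splits), otherwise a ValueError is raised.
    Returns a DataFrame indexed by (model, metric) with (organ, split)
    columns; each cell is the metric value, with a companion
    ``attrs['halfwidth']`` frame and ``attrs['best']`` boolean frame
    flagging per-column maxima (ties flagged jointly).
    """
    models = list(results)
    if not models:
        raise ValueError("no model results supplied")
    cells = list(results[models[0]])
    for m in models[1:]:
        if list(results[m]) != cells:
            raise ValueError(f"model {m!r} evaluated on different (organ, split) cells")
        for cell in cells:
            if results[m][cell].n != results[models[0]][cell].n:
                raise ValueError(
                    f"model {m!r} evaluated on a different split size at {cell}"
                )

    index = pd.MultiIndex.from_product([models, _METRICS], names=["model", "metric"])
    columns = pd.MultiIndex.from_tuples(cells, names=["organ", "split"])
    values = pd.DataFrame(index=index, columns=columns, dtype=float)
    halfw = pd.DataFrame(index=index, columns=columns, dtype=float)
    for m in models:
        for cell in cells:
            counts = results[m][cell]
            rep = compute_metrics(counts)
            values.loc[(m, "accuracy"), cell] = rep.accuracy
            values.loc[(m, "precision"), cell] = rep.precision
            values.loc[(m, "recall"), cell] = rep.recall
            values.loc[(m, "f1"), cell] = rep.f1
            halfw.loc[(m, "accuracy"), cell] = rep.accuracy_halfwidth
            halfw.loc[(m, "precision"), cell] = (
                wald_halfwidth(rep.precision, counts.tp + counts.fp)
                if counts.tp + counts.fp > 0
                else 0.0
            )
            halfw.loc[(m, "recall"), cell] = (
                wald_halfwidth(rep.recall, counts.tp + counts.fn)
                if counts.tp + counts.fn > 0
                else 0.0
            )
            halfw.loc[(m, "f1"), cell] = 0.0

    best = pd.DataFrame(False, index=index, columns=columns)
    for metric in _METRICS:
        sub = values.xs(metric, level="metric")
        for col in columns:
            colmax = sub[col].max()
            for m in models:
                if np.isclose(sub.loc[m, col], colmax):
                    best.loc[(m, metric), col] = True
    values.attrs["halfwidth"] = halfw
    values.attrs["best"] = best
    return values


def format_comparison(values: pd.DataFrame, kind: str = "tsv") -> str:
    """Serialize a comparison table as TSV or markdown.

    Accuracy cells print as percentages with the half-width in parentheses
    ("93.80% (±1.39%)"); other metrics print to 4 decimals with ±2-decimal
    margins.  Per-column best values are starred in markdown.
    """
    halfw = values.attrs["halfwidth"]
    best = values.attrs["best"]
    formatted = pd.DataFrame(index=values.index, columns=values.columns, dtype=object)
    for idx in values.index:
        metric = idx[1]
        for col in values.columns:
            v, h = values.loc[idx, col], halfw.loc[idx, col]
            if metric == "accuracy":
                cell = f"{100 * v:.2f}% (±{100 * h:.2f}%)"
            else:
                cell = f"{v:.4f} (±{h:.2f})"
            if kind == "markdown" and best.loc[idx, col]:
                cell = f"**{cell}**"
            formatted.loc[idx, col] = cell
    if kind == "tsv":
        return formatted.to_csv(sep="\t")
    if kind == "markdown":
        return formatted.to_markdown()
    raise ValueError(f"unknown table format {kind!r}")


# ---------------------------------------------------------------------------
# corpus-scale weak labeling and metastases maps
# ---------------------------------------------------------------------------


class OracleClassifier:
    """Labelbook-lookup "classifier" for validating the map machinery."""

    uses_history = True

    def __init__(self, labelbook: Mapping) -> None:
        self.labelbook = labelbook

    def predict_docs(self, docs: Sequence[HistoryDocument]):
        labels = np.array(
            [
                int(
                    self.labelbook[(d.patient_id, d.target_index, d.organ)]
                    == POSITIVE
                )
                for d in docs
            ]
        )
        return labels.astype(float), labels


@dataclasses.dataclass
class MetastasesMap:
    """patient × organ × exam-date weak labels with confidences."""

    table: pd.DataFrame  # patient_id, organ, exam_date, report_id, label, confidence

    def first_positive_dates(self) -> pd.DataFrame:
        """Earliest positive-labeled exam date per (patient, organ).

        Patient/organ pairs with no positive exam are absent.
        """
        pos = self.table[self.table["label"] == 1]
        if pos.empty:
            return pd.DataFrame(columns=["patient_id", "organ", "first_positive_date"])
        return (
            pos.groupby(["patient_id", "organ"], as_index=False)["exam_date"]
            .min()
            .rename(columns={"exam_date": "first_positive_date"})
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_patient_json(self, path) -> None:
        """One JSON object per patient: organ time series + first positives."""
        out = {}
        firsts = self.first_positive_dates()
        for pid, group in self.table.groupby("patient_id"):
            organs = {}
            for organ, og in group.groupby("organ"):
                og = og.sort_values("exam_date")
                fp = firsts[
                    (firsts["patient_id"] == pid) & (firsts["organ"] == organ)
                ]
                organs[organ] = {
                    "dates": og["exam_date"].tolist(),
                    "labels": og["label"].astype(int).tolist(),
                    "confidence": [round(c, 6) for c in og["confidence"]],
                    "first_positive_date": (
                        fp["first_positive_date"].iloc[0] if len(fp) else None
                    ),
                }
            out[pid] = organs
        Path(path).write_text(json.dumps(out, indent=1, sort_keys=True))


def build_metastases_map(
    corpus: Sequence[StructuredReport],
    classifiers: Mapping[OrganSite, object],
    *,
    include_impression: bool = False,
) -> MetastasesMap:
    """Weak-label every report of a corpus for each requested organ.

    Each classifier labels its organ's history documents (or single-report
    documents if it declares ``uses_history = False``); rows cover every
    report × organ.

    Raises
    ------
    KeyError
        If a requested organ has no fitted classifier (mapping access).
    """
    if not classifiers:
        raise ValueError("no classifiers supplied")
    timelines = build_timelines(corpus)
    rows = []
    for organ, clf in classifiers.items():
        history = getattr(clf, "uses_history", True)
        docs = build_documents(
            timelines, organ, history=history, include_impression=include_impression
        )
        probs, labels = clf.predict_docs(docs)
        date_of = {r.report_id: r.exam_date.isoformat() for r in corpus}
        for doc, p, lab in zip(docs, probs, labels):
            rows.append(
                {
                    "patient_id": doc.patient_id,
                    "organ": organ.value,
                    "exam_date": date_of[doc.target_report_id],
                    "report_id": doc.target_report_id,
                    "label": int(lab),
                    "confidence": float(p),
                }
            )
    table = pd.DataFrame(rows).sort_values(
        ["patient_id", "organ", "exam_date", "report_id"], ignore_index=True
    )
    return MetastasesMap(table=table)
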