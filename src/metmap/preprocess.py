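"""Text normalization, longitudinal document construction, labels, splits.

Two text patterns carry concept-level signal but explode the vocabulary:
lesion measurements ("1.2 x 0.8 cm") and dates ("3/14/2019", "March 26,
2021").  Normalization replaces them with the literal tokens
``measurement`` and ``date`` — the *presence* of a measurement is highly
informative for metastasis, its value is not.

The unit classified by the multi-report models is the *history document*:
the chronological concatenation of a patient's organ-specific findings text
from the first exam up to and including the target exam.
"""

from __future__ import annotations

import dataclasses
import math
import re
from typing import Iterable, Sequence

import numpy as np

from .organs import OrganSite
from .reports import NEGATIVE, POSITIVE, PatientTimeline, UNANNOTATED

# Measurement: decimal number, optionally "x" two more, then mm/cm.
_MEASUREMENT_RE = re.compile(
    r"\d+(?:\.\d+)?(?:\s*[x×]\s*\d+(?:\.\d+)?){0,2}\s*(?:mm|cm)\b",
    re.IGNORECASE,
)
_MONTHS = (
    "january|february|march|april|may|june|july|august|september|october|"
    "november|december|jan|feb|mar|apr|jun|jul|aug|sep|sept|oct|nov|dec"
)
# Numeric d/m/y with / or - separators (2- or 4-digit year), y-m-d ISO
# forms, and month-name dates like "March 26, 2021".
_DATE_RE = re.compile(
    rf"(?:\b\d{{1,2}}[/-]\d{{1,2}}[/-]\d{{2,4}}\b"
    rf"|\b\d{{4}}[/-]\d{{1,2}}[/-]\d{{1,2}}\b"
    rf"|\b(?:{_MONTHS})\.?\s+\d{{1,2}}(?:,\s*|\s+)\d{{2,4}}\b)",
    re.IGNORECASE,
)


def normalize_text(text: str) -> str:
    """Replace measurement and date patterns with concept tokens.

    Measurements are substituted first (their numbers would otherwise be
    half-eaten by the date pattern), then dates.  Idempotent: the
    replacement tokens contain no digits.
    """
    text = _MEASUREMENT_RE.sub("measurement", text)
    return _DATE_RE.sub("date", text)


def contains_measurement(text: str) -> bool:
    """True if a measurement pattern is present in (unnormalized) text."""
    return _MEASUREMENT_RE.search(text) is not None


# ---------------------------------------------------------------------------
# history documents
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class HistoryDocument:
    """Concatenated organ findings of reports 0..t for one patient/organ.

    ``label`` is 1/0 for annotated target reports, None when unannotated.
    The document for target index t is a prefix of the one for t+1.
    """

    patient_id: str
    target_report_id: str
    target_index: int
    organ: OrganSite
    text: str
    label: int | None = None


def build_history_document(
    timeline: PatientTimeline,
    target_index: int,
    organ: OrganSite,
    *,
    history: bool = True,
    include_impression: bool = False,
) -> HistoryDocument:
    """Build the classification document for one target report.

    With ``history=True`` the text is the normalized organ findings of
    reports 0..target_index joined oldest-to-newest with single newlines;
    with ``history=False`` only the target report's own findings (the
    single-report baseline's view).  ``include_impression`` appends the
    normalized impression of each included report after its findings.

    Raises
    ------
    IndexError
        If target_index is out of range.
    """
    if not 0 <= target_index < len(timeline.reports):
        raise IndexError(
            f"target_index {target_index} out of range for timeline of "
            f"length {len(timeline.reports)}"
        )
    start = 0 if history else target_index
    pieces = []
    for report in timeline.reports[start : target_index + 1]:
        piece = normalize_text(report.findings[organ])
        if include_impression:
            piece = (piece + "\n" + normalize_text(report.impression)).strip("\n")
        pieces.append(piece)
    target = timeline.reports[target_index]
    annotation = target.label_of(organ)
    label = None if annotation == UNANNOTATED else int(annotation == POSITIVE)
    return HistoryDocument(
        patient_id=timeline.patient_id,
        target_report_id=target.report_id,
        target_index=target_index,
        organ=organ,
        text="\n".join(pieces),
        label=label,
    )


def build_documents(
    timelines: Iterable[PatientTimeline],
    organ: OrganSite,
    *,
    history: bool = True,
    include_impression: bool = False,
) -> list[HistoryDocument]:
    """History documents for every report of every timeline, in order."""
    docs = []
    for tl in timelines:
        for t in range(len(tl.reports)):
            docs.append(
                build_history_document(
                    tl, t, organ, history=history,
                    include_impression=include_impression,
                )
            )
    return docs


# ---------------------------------------------------------------------------
# labels and splits
# ---------------------------------------------------------------------------


def encode_labels(annotations: Sequence[str]) -> list[int]:
    """Map "Yes"/"No" annotations to 1/0, order-preserving.

    Raises
    ------
    ValueError
        On any value other than "Yes"/"No" (also accepts the internal
        ``positive``/``negative`` spellings).
    """
    mapping = {"Yes": 1, "No": 0, POSITIVE: 1, NEGATIVE: 0}
    out = []
    for i, value in enumerate(annotations):
        if value not in mapping:
            raise ValueError(f"annotation #{i}: expected Yes/No, got {value!r}")
        out.append(mapping[value])
    return out


@dataclasses.dataclass
class SplitAssignment:
    """Partition of report ids into train / test / validation."""

    assignment: dict[str, str]
    counts: dict[str, int]

    def ids(self, split: str) -> list[str]:
        return [rid for rid, s in self.assignment.items() if s == split]


def split_sizes(n: int) -> tuple[int, int, int]:
    """(train, test, validation) counts for an N-report dataset.

    70/15/15 via: holdout = ceil(0.30 N); test = ceil(holdout/2);
    validation = holdout - test; train = N - holdout.  This arithmetic
    reproduces the published per-organ split sizes exactly.
    """
    holdout = math.ceil(0.30 * n)
    test = math.ceil(holdout / 2)
    return n - holdout, test, holdout - test


def split_dataset(
    report_ids: Sequence[str],
    seed: int,
    *,
    patient_of: dict[str, str] | None = None,
) -> SplitAssignment:
    """Randomly partition report ids into train/test/validation (70/15/15).

    Membership comes from a seeded uniform shuffle, so the assignment is
    deterministic under ``seed``.  When ``patient_of`` is given, whole
    patients are assigned to a split (no patient straddles splits); counts
    then only approximate the 70/15/15 targets.

    Raises
    ------
    ValueError
        If fewer than 3 report ids are supplied.
    """
    n = len(report_ids)
    if n < 3:
        raise ValueError(f"need at least 3 reports to split, got {n}")
    n_train, n_test, n_val = split_sizes(n)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    if patient_of is None:
        order = rng.permutation(n)
        shuffled = [report_ids[i] for i in order]
        for rid in shuffled[:n_train]:
            assignment[rid] = "train"
        for rid in shuffled[n_train : n_train + n_test]:
            assignment[rid] = "test"
        for rid in shuffled[n_train + n_test :]:
            assignment[rid] = "validation"
    else:
        by_patient: dict[str, list[str]] = {}
        for rid in report_ids:
            by_patient.setdefault(patient_of[rid], []).append(rid)
        patients = sorted(by_patient)
        order = rng.permutation(len(patients))
        remaining = {"train": n_train, "test": n_test, "validation": n_val}
        for idx in order:
            pid = patients[idx]
            split = max(remaining, key=lambda s: remaining[s])
            for rid in by_patient[pid]:
                assignment[rid] = split
            remaining[split] -= len(by_patient[pid])
    counts = {"train": 0, "test": 0, "validation": 0}
    for s in assignment.values():
        counts[s] += 1
    return SplitAssignment(assignment=assignment, counts=counts)


def write_split_tsv(split: SplitAssignment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("report_id\tsplit\n")
        for rid, s in split.assignment.items():
            fh.write(f"{rid}\t{s}\n")
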