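"""Data model and I/O for template-structured radiology reports.

A :class:`StructuredReport` is one CT exam: a patient identifier, an exam
date, one free-text findings paragraph per :class:`~metmap.organs.OrganSite`,
an impression paragraph, and (optionally) per-organ metastasis annotations.
Corpora are stored as JSONL (one report per line, UTF-8); the plain-text
template produced by the reporting system is supported as an import/export
dialect.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .organs import OrganSite

#: Annotation values an organ label can take.
POSITIVE = "positive"
NEGATIVE = "negative"
UNANNOTATED = "unannotated"
_LABEL_VALUES = {POSITIVE, NEGATIVE, UNANNOTATED}


class MalformedReportError(ValueError):
    """A plain-text report that cannot be parsed against the template."""


class CorpusError(ValueError):
    """A corpus-level consistency failure (duplicate ids, bad dates...)."""


@dataclasses.dataclass
class StructuredReport:
    """One structured CT exam report.

    ``findings`` always has an entry for every organ site (empty string
    allowed).  ``labels`` maps organ sites to ``"positive"``/``"negative"``/
    ``"unannotated"``; sites absent from ``labels`` are unannotated.
    """

    patient_id: str
    report_id: str
    exam_date: datetime.date
    findings: dict[OrganSite, str]
    impression: str = ""
    labels: dict[OrganSite, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for organ in OrganSite:
            self.findings.setdefault(organ, "")
        for organ, value in self.labels.items():
            if value not in _LABEL_VALUES:
                raise ValueError(
                    f"report {self.report_id}: label for {organ.value} must be "
                    f"one of {sorted(_LABEL_VALUES)}, got {value!r}"
                )

    def label_of(self, organ: OrganSite) -> str:
        return self.labels.get(organ, UNANNOTATED)


@dataclasses.dataclass
class PatientTimeline:
    """All reports of one patient, ascending by (exam_date, report_id)."""

    patient_id: str
    reports: list[StructuredReport]

    def __len__(self) -> int:
        return len(self.reports)


# ---------------------------------------------------------------------------
# plain-text template dialect
# ---------------------------------------------------------------------------

_HEADINGS = {organ.heading.lower(): organ for organ in OrganSite}


def parse_template_text(
    raw: str,
    *,
    patient_id: str = "",
    report_id: str = "",
    exam_date: datetime.date | None = None,
) -> StructuredReport:
    """Parse one plain-text report in the structured template dialect.

    The dialect: a ``Findings:`` block containing one heading line per organ
    (heading ends with ``:``; matching is case-insensitive), followed by an
    ``Impression:`` block.  Text under an unrecognized heading is appended to
    the preceding section with a warning.

    Raises
    ------
    MalformedReportError
        If no ``Impression`` heading is present.
    """
    findings: dict[OrganSite, str] = {o: "" for o in OrganSite}
    impression_parts: list[str] = []
    current: OrganSite | None = None
    in_impression = False
    saw_impression = False

    for line in raw.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        head, sep, rest = stripped.partition(":")
        key = head.strip().lower()
        if sep:
            if key == "impression":
                in_impression = True
                saw_impression = True
                current = None
                if rest.strip():
                    impression_parts.append(rest.strip())
                continue
            if key == "findings":
                continue
            if key in _HEADINGS:
                current = _HEADINGS[key]
                in_impression = False
                if rest.strip():
                    findings[current] = rest.strip()
                continue
            if not in_impression and head and not any(ch.isdigit() for ch in head):
                warnings.warn(
                    f"report {report_id or '<unknown>'}: unrecognized heading "
                    f"{head.strip()!r}; text appended to preceding section",
                    stacklevel=2,
                )
                # fall through: treat the whole line as body text
        if in_impression:
            impression_parts.append(stripped)
        elif current is not None:
            body = findings[current]
            findings[current] = (body + " " + stripped).strip() if body else stripped

    if not saw_impression:
        raise MalformedReportError(
            f"report {report_id or '<unknown>'}: missing Impression heading"
        )
    return StructuredReport(
        patient_id=patient_id,
        report_id=report_id,
        exam_date=exam_date or datetime.date(1970, 1, 1),
        findings=findings,
        impression=" ".join(impression_parts),
    )


def write_template_text(report: StructuredReport) -> str:
    """Render a report back into the plain-text template dialect."""
    lines = ["Findings:", ""]
    for organ in OrganSite:
        lines.append(f"{organ.heading}: {report.findings[organ]}".rstrip())
    lines += ["", f"Impression: {report.impression}".rstrip()]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSONL corpus I/O
# ---------------------------------------------------------------------------


def _report_to_json(report: StructuredReport) -> dict:
    rec: dict = {
        "patient_id": report.patient_id,
        "report_id": report.report_id,
        "exam_date": report.exam_date.isoformat(),
        "findings": {o.value: report.findings[o] for o in OrganSite},
        "impression": report.impression,
    }
    labels = {
        o.value: ("Yes" if v == POSITIVE else "No")
        for o, v in sorted(report.labels.items(), key=lambda kv: kv[0].value)
        if v != UNANNOTATED
    }
    if labels:
        rec["labels"] = labels
    return rec


def _report_from_json(rec: Mapping, lineno: int) -> StructuredReport:
    try:
        exam_date = datetime.date.fromisoformat(rec["exam_date"])
    except (KeyError, ValueError) as exc:
        raise CorpusError(f"line {lineno}: unparseable exam_date: {exc}") from exc
    findings = {OrganSite(k): v for k, v in rec.get("findings", {}).items()}
    labels = {
        OrganSite(k): (POSITIVE if v == "Yes" else NEGATIVE)
        for k, v in rec.get("labels", {}).items()
    }
    return StructuredReport(
        patient_id=rec["patient_id"],
        report_id=rec["report_id"],
        exam_date=exam_date,
        findings=findings,
        impression=rec.get("impression", ""),
        labels=labels,
    )


def write_corpus(reports: Iterable[StructuredReport], path: str | Path) -> None:
    """Write reports as JSONL, one report per line, keys in fixed order."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for report in reports:
            fh.write(json.dumps(_report_to_json(report), ensure_ascii=False))
            fh.write("\n")


def read_corpus(path: str | Path, format: str = "jsonl") -> list[StructuredReport]:
    """Read a corpus from JSONL or from a directory of template .txt files.

    Ordering is deterministic: file order for JSONL, sorted filename order
    for a template directory.

    Raises
    ------
    CorpusError
        On duplicate report ids or unparseable dates.
    """
    path = Path(path)
    reports: list[StructuredReport] = []
    if format == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                reports.append(_report_from_json(json.loads(line), lineno))
    elif format == "template_text_dir":
        for txt in sorted(path.glob("*.txt")):
            reports.append(
                parse_template_text(txt.read_text(encoding="utf-8"),
                                    report_id=txt.stem)
            )
    else:
        raise ValueError(f"unknown corpus format {format!r}")

    seen: dict[str, int] = {}
    dups = []
    for r in reports:
        seen[r.report_id] = seen.get(r.report_id, 0) + 1
    dups = sorted(rid for rid, n in seen.items() if n > 1)
    if dups:
        raise CorpusError(f"duplicate report_id(s): {', '.join(dups)}")
    return reports


def build_timelines(reports: Sequence[StructuredReport]) -> list[PatientTimeline]:
    """Group reports by patient and sort each group chronologically.

    Sort key is (exam_date, report_id); report_id breaks same-day ties so
    ordering is total and deterministic.  Timelines come back sorted by
    patient_id.  Report count is conserved.
    """
    by_patient: dict[str, list[StructuredReport]] = {}
    for r in reports:
        by_patient.setdefault(r.patient_id, []).append(r)
    timelines = []
    for pid in sorted(by_patient):
        group = sorted(by_patient[pid], key=lambda r: (r.exam_date, r.report_id))
        timelines.append(PatientTimeline(patient_id=pid, reports=group))
    return timelines
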