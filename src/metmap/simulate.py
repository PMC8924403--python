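"""Seeded simulator for labeled longitudinal structured-report corpora.

The clinical corpus the models were built for is restricted, so testing and
calibration run on a simulator that reproduces the *statistical* structure
the multi-report method exploits:

* per-organ metastasis trajectories are Markov: a patient starts negative,
  converts with a per-exam onset hazard, and — by default irreversibly —
  stays positive (``resolution_prob`` lets lesions resolve if wanted);
* a *new* metastasis is reported with an explicit lesion measurement, while
  a persisting one is, with probability ``q_stable``, reported only as
  "stable / no significant change" wording that is verbatim identical to
  benign follow-up phrasing — the information asymmetry that makes patient
  history necessary;
* negative lung sections occasionally mention a *measured benign nodule*
  (granuloma), the confounder that degrades measurement-token precision in
  the lungs.

Report-level positivity is calibrated to requested prevalences (e.g. the
published 16.6% lung / 30.5% liver / 7.1% adrenal rates) by bisection on
the onset hazard (:func:`solve_onset_hazard`).
"""

from __future__ import annotations

import dataclasses
import datetime
import importlib.resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .organs import OrganSite, TARGET_ORGANS
from .reports import NEGATIVE, POSITIVE, StructuredReport


class LexiconError(ValueError):
    """A phrase bank needed by the renderer is missing or empty."""


def load_default_lexicons() -> dict:
    """The phrase banks shipped with the package (YAML)."""
    text = (
        importlib.resources.files("metmap.data")
        .joinpath("default_lexicon.yaml")
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


def load_lexicons(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@dataclasses.dataclass
class TrajectoryParams:
    """Markov trajectory and rendering-noise parameters.

    onset_hazard
        Per-organ probability of metastasis onset at each exam.  Organs
        absent from the mapping never convert.
    resolution_prob
        Per-organ probability an established metastasis disappears at the
        next exam (default 0: irreversible).
    q_stable
        Probability a *persisting* positive finding is rendered with
        "stable / no change" wording and no measurement.
    benign_measurement_rate
        Per-organ probability a negative section nevertheless mentions a
        measured benign nodule (lungs only by default).
    """

    onset_hazard: dict[OrganSite, float] = dataclasses.field(default_factory=dict)
    resolution_prob: dict[OrganSite, float] = dataclasses.field(default_factory=dict)
    q_stable: float = 0.7
    benign_measurement_rate: dict[OrganSite, float] = dataclasses.field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        probs = (
            list(self.onset_hazard.values())
            + list(self.resolution_prob.values())
            + [self.q_stable]
            + list(self.benign_measurement_rate.values())
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all trajectory probabilities must lie in [0, 1]")


@dataclasses.dataclass
class GeneratorConfig:
    """Corpus-level generator settings.

    Exams per patient default to 1 + Geometric(p = 0.5) capped at
    ``max_exams`` — mean about 3 serial CTs per patient.  Identical
    (config, params, seed) yields a byte-identical corpus.
    """

    n_patients: int = 100
    seed: int = 0
    exam_geometric_p: float = 0.5
    max_exams: int = 12
    date_mention_prob: float = 0.3
    target_organs: tuple[OrganSite, ...] = TARGET_ORGANS
    lexicons: dict | None = None

    def resolved_lexicons(self) -> dict:
        return self.lexicons if self.lexicons is not None else load_default_lexicons()


class LabelBook(dict):
    """Ground truth: (patient_id, report_index, organ) -> POSITIVE/NEGATIVE."""


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def simulate_trajectory(
    params: TrajectoryParams,
    n_exams: int,
    rng: np.random.Generator,
    organs: Sequence[OrganSite] = TARGET_ORGANS,
) -> dict[OrganSite, np.ndarray]:
    """Per-organ binary state sequences over ``n_exams`` exams.

    Each organ starts negative, converts negative->positive with its onset
    hazard at each exam, and reverts positive->negative with its resolution
    probability.
    """
    if n_exams < 1:
        raise ValueError("n_exams must be >= 1")
    out: dict[OrganSite, np.ndarray] = {}
    for organ in organs:
        h = params.onset_hazard.get(organ, 0.0)
        r = params.resolution_prob.get(organ, 0.0)
        states = np.zeros(n_exams, dtype=np.int8)
        state = 0
        for t in range(n_exams):
            u = rng.random()
            state = int(u < h) if state == 0 else int(u >= r)
            states[t] = state
        out[organ] = states
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _pick(rng: np.random.Generator, bank: list[str]) -> str:
    if not bank:
        raise LexiconError("empty phrase bank")
    return bank[int(rng.integers(len(bank)))]


def _measurement_string(rng: np.random.Generator) -> str:
    kind = int(rng.integers(3))
    if kind == 0:
        return f"{rng.integers(2, 30)} mm"
    if kind == 1:
        return f"{0.1 * rng.integers(3, 60):.1f} cm"
    return f"{0.1 * rng.integers(5, 60):.1f} x {0.1 * rng.integers(3, 50):.1f} cm"


def _date_string(rng: np.random.Generator) -> str:
    return (
        f"{rng.integers(1, 13)}/{rng.integers(1, 29)}/{rng.integers(2009, 2022)}"
    )


def _organ_bank(lex: dict, category: str, organ: OrganSite) -> list[str]:
    entry = lex.get(category)
    if entry is None:
        raise LexiconError(f"lexicon lacks category {category!r}")
    if isinstance(entry, dict):
        bank = entry.get(organ.value, entry.get("default"))
        if bank is None:
            raise LexiconError(f"lexicon {category!r} has no bank for {organ.value}")
        return bank
    return entry


def render_report(
    states: Mapping[OrganSite, int],
    prior_states: Mapping[OrganSite, int],
    lexicons: dict,
    rng: np.random.Generator,
    *,
    params: TrajectoryParams,
    patient_id: str,
    report_id: str,
    exam_date: datetime.date,
    date_mention_prob: float = 0.3,
    label_organs: Sequence[OrganSite] = TARGET_ORGANS,
) -> StructuredReport:
    """Render one exam's report from current and prior organ states.

    A negative->positive transition produces a phrase containing a lesion
    measurement; a persisting positive produces stable wording without a
    measurement with probability ``params.q_stable`` (else a re-measured
    phrase); a negative organ produces negative wording, with a measured
    benign mention at that organ's ``benign_measurement_rate``.  The
    impression summarizes currently positive organs; labels are set from
    the true states for ``label_organs``.
    """
    findings: dict[OrganSite, str] = {}
    for organ in OrganSite:
        state = int(states.get(organ, 0))
        prior = int(prior_states.get(organ, 0))
        if state == 1 and prior == 0:
            phrase = _pick(rng, _organ_bank(lexicons, "new_positive", organ))
            phrase = phrase.format(m=_measurement_string(rng))
            if rng.random() < date_mention_prob:
                phrase += " " + _pick(rng, lexicons["date_mention"]).format(
                    date=_date_string(rng)
                )
        elif state == 1:
            if rng.random() < params.q_stable:
                phrase = _pick(rng, _organ_bank(lexicons, "stable_positive", organ))
                if rng.random() < date_mention_prob:
                    phrase += " " + _pick(rng, lexicons["date_mention"]).format(
                        date=_date_string(rng)
                    )
            else:
                phrase = _pick(
                    rng, _organ_bank(lexicons, "remeasured_positive", organ)
                ).format(m=_measurement_string(rng))
        else:
            benign_rate = params.benign_measurement_rate.get(organ, 0.0)
            if benign_rate > 0.0 and rng.random() < benign_rate:
                phrase = _pick(rng, _organ_bank(lexicons, "benign", organ)).format(
                    m=_measurement_string(rng)
                )
            else:
                # baseline (first) exams read as plain negatives; follow-up
                # negatives may also use the ambiguous stable wording
                bank = list(lexicons["negative_common"])
                if prior_states:
                    bank += list(lexicons["negative_stable"])
                phrase = _pick(rng, bank)
        findings[organ] = phrase

    positive_now = [o for o in OrganSite if int(states.get(o, 0)) == 1]
    if positive_now:
        organs_txt = ", ".join(o.heading.lower() for o in positive_now)
        impression = _pick(rng, lexicons["impression_positive"]).format(
            organs=organs_txt
        )
    else:
        impression = _pick(rng, lexicons["impression_negative"])

    labels = {
        o: (POSITIVE if int(states.get(o, 0)) == 1 else NEGATIVE)
        for o in label_organs
    }
    return StructuredReport(
        patient_id=patient_id,
        report_id=report_id,
        exam_date=exam_date,
        findings=findings,
        impression=impression,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def _draw_n_exams(config: GeneratorConfig, rng: np.random.Generator) -> int:
    return int(min(1 + rng.geometric(config.exam_geometric_p), config.max_exams))


def generate_corpus(
    config: GeneratorConfig, params: TrajectoryParams
) -> tuple[list[StructuredReport], LabelBook]:
    """Generate a fully labeled longitudinal corpus plus its ground truth.

    One global RNG stream seeded from ``config.seed`` drives everything, so
    identical (config, params, seed) produce a byte-identical JSONL corpus.
    """
    rng = np.random.default_rng(config.seed)
    lexicons = config.resolved_lexicons()
    reports: list[StructuredReport] = []
    book = LabelBook()
    width = max(5, len(str(max(config.n_patients, 1))))
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        n_exams = _draw_n_exams(config, rng)
        traj = simulate_trajectory(params, n_exams, rng, config.target_organs)
        date = datetime.date(2010, 1, 1) + datetime.timedelta(
            days=int(rng.integers(0, 3000))
        )
        prior: dict[OrganSite, int] = {}
        for t in range(n_exams):
            states = {o: int(traj[o][t]) for o in config.target_organs}
            rid = f"{pid}-{t:02d}"
            reports.append(
                render_report(
                    states,
                    prior,
                    lexicons,
                    rng,
                    params=params,
                    patient_id=pid,
                    report_id=rid,
                    exam_date=date,
                    date_mention_prob=config.date_mention_prob,
                    label_organs=config.target_organs,
                )
            )
            for o in config.target_organs:
                book[(pid, t, o)] = POSITIVE if states[o] else NEGATIVE
            prior = states
            date = date + datetime.timedelta(days=int(rng.integers(60, 121)))
    return reports, book


def write_labelbook(book: LabelBook, path) -> None:
    """Persist ground truth as a JSONL side file."""
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for (pid, idx, organ), state in book.items():
            fh.write(
                json.dumps(
                    {
                        "patient_id": pid,
                        "report_index": idx,
                        "organ": organ.value,
                        "state": state,
                    }
                )
                + "\n"
            )


def read_labelbook(path) -> LabelBook:
    import json

    book = LabelBook()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            book[
                (rec["patient_id"], rec["report_index"], OrganSite(rec["organ"]))
            ] = rec["state"]
    return book


# ---------------------------------------------------------------------------
# prevalence calibration
# ---------------------------------------------------------------------------


def solve_onset_hazard(
    target_prevalence: float,
    *,
    exam_geometric_p: float = 0.5,
    max_exams: int = 12,
    resolution_prob: float = 0.0,
    rng: np.random.Generator | None = None,
    n_patients: int = 10_000,
    tol: float = 0.01,
) -> float:
    """Onset hazard whose report-level positive fraction hits a target.

    Bisection on the hazard, evaluating the report-level positive fraction
    by Monte Carlo over ``n_patients`` simulated timelines.  Common random
    numbers (one pre-drawn uniform panel reused for every candidate hazard)
    make the objective exactly monotone, so bisection converges cleanly.

    Raises
    ------
    ValueError
        If the target is outside (0, 1) or unattainable.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError(f"target prevalence must lie in (0,1), got {target_prevalence}")
    rng = np.random.default_rng(0) if rng is None else rng
    n_exams = np.minimum(1 + rng.geometric(exam_geometric_p, n_patients), max_exams)
    kmax = int(n_exams.max())
    onset_u = rng.random((n_patients, kmax))
    resolve_u = rng.random((n_patients, kmax))
    active = np.arange(kmax)[None, :] < n_exams[:, None]
    total_reports = int(n_exams.sum())

    def prevalence_at(h: float) -> float:
        state = np.zeros(n_patients, dtype=bool)
        positives = 0
        for t in range(kmax):
            onset = ~state & (onset_u[:, t] < h)
            resolve = state & (resolve_u[:, t] < resolution_prob)
            state = (state | onset) & ~resolve
            positives += int((state & active[:, t]).sum())
        return positives / total_reports

    lo, hi = 0.0, 1.0
    if prevalence_at(hi) < target_prevalence - tol:
        raise ValueError(
            f"target prevalence {target_prevalence} unattainable under this "
            "exam distribution"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f = prevalence_at(mid)
        if abs(f - target_prevalence) <= 0.25 * tol or hi - lo < 1e-6:
            return mid
        if f < target_prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
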