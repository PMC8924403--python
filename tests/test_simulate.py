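"""Trajectory simulation, report rendering, calibration, determinism."""

import json

import numpy as np
import pytest

from metmap import (
    GeneratorConfig,
    OrganSite,
    TrajectoryParams,
    generate_corpus,
    normalize_text,
    simulate_trajectory,
    solve_onset_hazard,
)
from metmap.preprocess import _MEASUREMENT_RE, contains_measurement
from metmap.reports import POSITIVE, _report_to_json, build_timelines
from metmap.simulate import LexiconError, load_default_lexicons, render_report

LUNG = OrganSite.LUNGS


class TestTrajectory:
    def test_zero_hazard_stays_negative(self, rng):
        params = TrajectoryParams(onset_hazard={LUNG: 0.0})
        states = simulate_trajectory(params, 20, rng)[LUNG]
        assert not states.any()

    def test_certain_onset_persists(self, rng):
        params = TrajectoryParams(onset_hazard={LUNG: 1.0})
        states = simulate_trajectory(params, 3, rng)[LUNG]
        assert states.tolist() == [1, 1, 1]

    def test_single_exam_positive_fraction_matches_hazard(self):
        # one exam per patient: prevalence is a plain binomial draw at p=0.2
        rng = np.random.default_rng(123)
        params = TrajectoryParams(onset_hazard={LUNG: 0.2})
        n = 100_000
        hits = sum(
            int(simulate_trajectory(params, 1, rng)[LUNG][0]) for _ in range(n)
        )
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(hits / n - 0.2) < 3 * se

    def test_resolution_reverts_states(self, rng):
        params = TrajectoryParams(
            onset_hazard={LUNG: 1.0}, resolution_prob={LUNG: 1.0}
        )
        states = simulate_trajectory(params, 4, rng)[LUNG]
        # onset at exam 1, then guaranteed resolution/re-onset alternation
        assert states[0] == 1 and set(states.tolist()) <= {0, 1}

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryParams(onset_hazard={LUNG: 1.5})


class TestRenderReport:
    def setup_method(self):
        self.lex = load_default_lexicons()
        self.params = TrajectoryParams(
            onset_hazard={LUNG: 0.5},
            benign_measurement_rate={LUNG: 0.0},
        )

    def render(self, states, prior, params=None, rng_seed=0):
        import datetime

        return render_report(
            states,
            prior,
            self.lex,
            np.random.default_rng(rng_seed),
            params=params or self.params,
            patient_id="P1",
            report_id="P1-01",
            exam_date=datetime.date(2012, 3, 1),
        )

    def test_new_positive_contains_measurement(self):
        rep = self.render({LUNG: 1}, {})
        text = rep.findings[LUNG]
        assert contains_measurement(text)
        assert "measurement" in normalize_text(text)

    def test_stable_positive_has_no_measurement_when_forced(self):
        params = TrajectoryParams(onset_hazard={LUNG: 0.5}, q_stable=1.0)
        for seed in range(10):
            rep = self.render({LUNG: 1}, {LUNG: 1}, params=params, rng_seed=seed)
            assert not contains_measurement(rep.findings[LUNG])

    def test_all_negative_without_confounder_has_no_measurements(self):
        for seed in range(10):
            rep = self.render({o: 0 for o in OrganSite}, {}, rng_seed=seed)
            for organ in OrganSite:
                assert not contains_measurement(rep.findings[organ])

    def test_impression_names_positive_organs(self):
        rep = self.render({LUNG: 1}, {})
        assert "lungs" in rep.impression.lower() or "metasta" in rep.impression.lower()

    def test_labels_follow_states(self):
        rep = self.render({LUNG: 1}, {})
        assert rep.labels[LUNG] == POSITIVE

    def test_empty_lexicon_bank_raises(self):
        bad = dict(self.lex, negative_common=[])
        import datetime

        with pytest.raises(LexiconError):
            render_report(
                {o: 0 for o in OrganSite},
                {},
                bad,
                np.random.default_rng(0),
                params=self.params,
                patient_id="P1",
                report_id="P1-00",
                exam_date=datetime.date(2012, 3, 1),
            )


class TestGenerateCorpus:
    def test_same_seed_is_byte_identical(self, default_params):
        config = GeneratorConfig(n_patients=40, seed=5)
        a, _ = generate_corpus(config, default_params)
        b, _ = generate_corpus(config, default_params)
        dump = lambda reports: [json.dumps(_report_to_json(r)) for r in reports]
        assert dump(a) == dump(b)

    def test_different_seed_differs(self, default_params):
        a, _ = generate_corpus(GeneratorConfig(n_patients=40, seed=5), default_params)
        b, _ = generate_corpus(GeneratorConfig(n_patients=40, seed=6), default_params)
        assert [r.findings for r in a] != [r.findings for r in b]

    def test_zero_patients_empty_corpus(self, default_params):
        corpus, book = generate_corpus(
            GeneratorConfig(n_patients=0, seed=0), default_params
        )
        assert corpus == [] and not book

    def test_every_target_organ_labeled(self, small_corpus):
        corpus, book = small_corpus
        for report in corpus:
            for organ in (OrganSite.LUNGS, OrganSite.LIVER, OrganSite.ADRENAL_GLANDS):
                assert report.labels[organ] in ("positive", "negative")
        assert len(book) == 3 * len(corpus)

    def test_positive_labels_never_revert_without_resolution(self, small_corpus):
        corpus, _ = small_corpus
        for tl in build_timelines(corpus):
            for organ in (OrganSite.LUNGS, OrganSite.LIVER):
                seen_positive = False
                for report in tl.reports:
                    pos = report.labels[organ] == POSITIVE
                    if seen_positive:
                        assert pos
                    seen_positive = seen_positive or pos

    def test_information_asymmetry_at_full_stability(self):
        # q_stable=1: the only positive reports carrying a measurement are
        # the first-positive ones -- history is required for the rest.
        params = TrajectoryParams(
            onset_hazard={LUNG: 0.2},
            q_stable=1.0,
            benign_measurement_rate={},
        )
        corpus, book = generate_corpus(
            GeneratorConfig(n_patients=400, seed=9), params
        )
        measured_positives = first_positives = total_positives = 0
        for tl in build_timelines(corpus):
            prev = 0
            for idx, report in enumerate(tl.reports):
                pos = book[(tl.patient_id, idx, LUNG)] == POSITIVE
                if pos:
                    total_positives += 1
                    if contains_measurement(report.findings[LUNG]):
                        measured_positives += 1
                    if not prev:
                        first_positives += 1
                prev = pos
        assert total_positives > 0
        assert measured_positives == first_positives


class TestSolveOnsetHazard:
    def test_single_exam_hazard_equals_target(self):
        # capped at one exam per patient, prevalence equals the hazard
        h = solve_onset_hazard(
            0.166,
            exam_geometric_p=1.0,
            max_exams=1,
            rng=np.random.default_rng(0),
        )
        assert abs(h - 0.166) < 0.01

    @pytest.mark.parametrize("target", [0.305, 0.071])
    def test_self_consistency(self, target):
        rng = np.random.default_rng(11)
        h = solve_onset_hazard(target, rng=rng, n_patients=10_000)
        # independent re-simulation with fresh randomness
        check = np.random.default_rng(99)
        params = TrajectoryParams(onset_hazard={LUNG: h})
        pos = total = 0
        for _ in range(4000):
            n_exams = int(min(1 + check.geometric(0.5), 12))
            states = simulate_trajectory(params, n_exams, check)[LUNG]
            pos += int(states.sum())
            total += n_exams
        assert abs(pos / total - target) < 0.012

    def test_out_of_range_target(self):
        with pytest.raises(ValueError):
            solve_onset_hazard(1.2)

    def test_unattainable_target(self):
        # with near-certain resolution, established disease rarely persists,
        # so very high report-level prevalence cannot be reached
        with pytest.raises(ValueError, match="unattainable"):
            solve_onset_hazard(0.95, resolution_prob=0.9)
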