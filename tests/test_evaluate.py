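"""Metric identities, Wald half-widths, comparison tables, metastases maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metmap import (
    ConfusionCounts,
    OracleClassifier,
    OrganSite,
    build_metastases_map,
    build_timelines,
    comparison_table,
    compute_metrics,
    f1_score,
    format_comparison,
    prevalence,
    wald_halfwidth,
)
from metmap.reports import POSITIVE


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "precision, recall, expected_f1",
        [
            (1.00, 0.5000, 0.6667),
            (0.9080, 0.6860, 0.7815),
            (0.9526, 0.8960, 0.9234),
            (0.9792, 0.9792, 0.9792),
        ],
    )
    def test_published_precision_recall_pairs(self, precision, recall, expected_f1):
        assert round(f1_score(precision, recall), 4) == expected_f1

    @given(st.floats(min_value=0.01, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_equal_precision_recall_gives_that_f1(self, x):
        assert np.isclose(f1_score(x, x), x)

    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
    )
    @settings(max_examples=100, deadline=None)
    def test_metric_identities_on_random_counts(self, tp, fp, tn, fn):
        counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        if counts.n == 0:
            with pytest.raises(ValueError):
                compute_metrics(counts)
            return
        rep = compute_metrics(counts)
        assert np.isclose(rep.accuracy, (tp + tn) / counts.n)
        assert np.isclose(rep.f1, f1_score(rep.precision, rep.recall))
        assert 0 <= rep.precision <= 1 and 0 <= rep.recall <= 1

    def test_degenerate_denominators_flagged(self):
        rep = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert rep.precision == 0.0 and rep.recall == 0.0 and rep.degenerate


class TestWaldHalfwidth:
    @pytest.mark.parametrize(
        "p, n, cell",
        [
            (0.9233, 1160, 1.53),
            (0.925, 417, 2.53),
            (0.9969, 5413, 0.15),
            (0.938, 1160, 1.39),
        ],
    )
    def test_published_accuracy_cells(self, p, n, cell):
        assert round(100 * wald_halfwidth(p, n), 2) == cell

    def test_degenerate_proportions(self):
        assert wald_halfwidth(0.0, 100) == 0.0
        assert wald_halfwidth(1.0, 100) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wald_halfwidth(0.5, 0)
        with pytest.raises(ValueError):
            wald_halfwidth(1.5, 10)


class TestPrevalence:
    @pytest.mark.parametrize(
        "pos, total, pct",
        [(1287, 7733, 16.6), (848, 2777, 30.5), (291, 4107, 7.1)],
    )
    def test_published_count_pairs(self, pos, total, pct):
        labels = [1] * pos + [0] * (total - pos)
        assert prevalence(labels) == (pos, total, pct)

    def test_zero_positives(self):
        assert prevalence([0] * 50) == (0, 50, 0.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            prevalence([])


def counts_grid(tp_shift=0):
    cells = [("lungs", "validation"), ("lungs", "test"), ("liver", "validation")]
    return {
        cell: ConfusionCounts(tp=20 + tp_shift, fp=5, tn=70 - tp_shift, fn=5)
        for cell in cells
    }


class TestComparisonTable:
    def test_shape_and_self_consistency(self):
        table = comparison_table({"baseline": counts_grid(), "cnn": counts_grid(3)})
        assert table.shape == (8, 3)  # 2 models x 4 metrics, 3 cells
        rep = compute_metrics(counts_grid(3)[("lungs", "validation")])
        assert np.isclose(
            table.loc[("cnn", "f1"), ("lungs", "validation")], rep.f1
        )

    def test_best_flags_mark_maxima_and_ties(self):
        table = comparison_table({"a": counts_grid(), "b": counts_grid(5),
                                  "c": counts_grid(5)})
        best = table.attrs["best"]
        col = ("lungs", "validation")
        assert not best.loc[("a", "recall"), col]
        assert best.loc[("b", "recall"), col] and best.loc[("c", "recall"), col]

    def test_split_mismatch_rejected(self):
        mismatched = counts_grid()
        mismatched[("lungs", "validation")] = ConfusionCounts(20, 5, 60, 5)
        with pytest.raises(ValueError, match="split"):
            comparison_table({"a": counts_grid(), "b": mismatched})

    def test_formatting_styles(self):
        table = comparison_table({"baseline": counts_grid()})
        tsv = format_comparison(table, "tsv")
        md = format_comparison(table, "markdown")
        assert "% (±" in tsv and "**" in md


class TestMetastasesMap:
    def test_oracle_reproduces_simulated_trajectories(self, small_corpus):
        corpus, book = small_corpus
        oracle = OracleClassifier(book)
        mmap = build_metastases_map(
            corpus, {o: oracle for o in (OrganSite.LUNGS, OrganSite.LIVER)}
        )
        assert len(mmap.table) == 2 * len(corpus)
        index_of = {}
        for tl in build_timelines(corpus):
            for idx, rep in enumerate(tl.reports):
                index_of[rep.report_id] = idx
        for row in mmap.table.itertuples():
            truth = book[(row.patient_id, index_of[row.report_id],
                          OrganSite(row.organ))]
            assert row.label == int(truth == POSITIVE)

    def test_first_positive_dates_match_onsets(self, small_corpus):
        corpus, book = small_corpus
        oracle = OracleClassifier(book)
        mmap = build_metastases_map(corpus, {OrganSite.LUNGS: oracle})
        firsts = mmap.first_positive_dates().set_index("patient_id")
        for tl in build_timelines(corpus):
            onset_dates = [
                rep.exam_date.isoformat()
                for idx, rep in enumerate(tl.reports)
                if book[(tl.patient_id, idx, OrganSite.LUNGS)] == POSITIVE
            ]
            if onset_dates:
                assert (
                    firsts.loc[tl.patient_id, "first_positive_date"]
                    == onset_dates[0]
                )
            else:
                assert tl.patient_id not in firsts.index

    def test_exports_write_files(self, tiny_corpus, tmp_path):
        corpus, book = tiny_corpus
        mmap = build_metastases_map(corpus, {OrganSite.LUNGS: OracleClassifier(book)})
        mmap.to_tsv(tmp_path / "map.tsv")
        mmap.to_patient_json(tmp_path / "map.json")
        assert (tmp_path / "map.tsv").read_text().startswith("patient_id")
        assert (tmp_path / "map.json").stat().st_size > 0

    def test_requires_classifiers(self, tiny_corpus):
        corpus, _ = tiny_corpus
        with pytest.raises(ValueError):
            build_metastases_map(corpus, {})
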