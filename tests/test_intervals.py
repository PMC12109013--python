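"""Interval hierarchy, assignment, metric matrices and expectation checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ki67gan import intervals as iv
from ki67gan import synthdata as sd


def get_relation(a_label, b_label):
    a, b = iv._BY_LABEL[a_label], iv._BY_LABEL[b_label]
    return iv.relation(a, b)


class TestHierarchy:
    def test_six_intervals_plus_full_range(self):
        ivs, rels = iv.build_interval_hierarchy()
        assert len(ivs) == 7
        labels = {i.label for i in ivs}
        assert labels == {"<0.5,1>", "<0,0.5)", "<0.2,0.5)", "<0,0.2)",
                          "<0.1,0.2)", "<0,0.1)", "<0,1>"}
        assert len(rels) == 21  # all unordered pairs

    def test_nested_intervals_are_subsets(self):
        assert get_relation("<0,0.1)", "<0,0.2)") == "subset"
        assert get_relation("<0.2,0.5)", "<0,0.5)") == "subset"
        assert get_relation("<0,1>", "<0.5,1>") == "subset"

    def test_disjoint_intervals_are_complementary(self):
        assert get_relation("<0.1,0.2)", "<0,0.1)") == "complementary"
        assert get_relation("<0,0.5)", "<0.5,1>") == "complementary"
        assert get_relation("<0.5,1>", "<0,0.2)") == "complementary"

    def test_complementary_halves_cover_full_range(self):
        xs = np.linspace(0, 1, 1001)
        low = iv._BY_LABEL["<0,0.5)"].contains(xs)
        high = iv._BY_LABEL["<0.5,1>"].contains(xs)
        assert np.all(low ^ high)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            iv.Ki67Interval(0.5, 0.2, False, "bad")


class TestAssign:
    def test_boundary_conventions(self):
        assert 0 in iv.assign([0.1], iv._BY_LABEL["<0.1,0.2)"])
        assert len(iv.assign([0.1], iv._BY_LABEL["<0,0.1)"])) == 0
        assert 0 in iv.assign([1.0], iv._BY_LABEL["<0.5,1>"])

    def test_partition_conservation(self):
        rng = np.random.default_rng(2)
        labels = rng.uniform(0, 1, 5000)
        def count(lbl):
            return len(iv.assign(labels, iv._BY_LABEL[lbl]))
        assert count("<0,0.1)") + count("<0.1,0.2)") == count("<0,0.2)")
        assert count("<0,0.2)") + count("<0.2,0.5)") == count("<0,0.5)")
        assert count("<0,0.5)") + count("<0.5,1>") == len(labels)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            iv.assign([0.3, 1.2], iv.FULL_RANGE)


@pytest.fixture(scope="module")
def interval_sets():
    """Real per-interval image sets from rendered pairs (uniform labels)."""
    rng = np.random.default_rng(12)
    labels = rng.uniform(0, 1, 220)
    images = np.stack([sd.render_patch_pair(float(p), 64, rng).he_image
                       for p in labels])
    sets = {}
    for interval in iv.PAPER_INTERVALS:
        sets[interval.label] = images[iv.assign(labels, interval)]
    return sets


class TestMetricMatrix:
    def test_identical_sets_have_zero_diagonal(self, interval_sets):
        report = iv.metric_matrix(interval_sets, interval_sets)
        diag = [report.values[i][i] for i in range(6)]
        assert np.allclose(np.round(diag, 2), 0.0)

    def test_shared_sets_give_symmetric_matrix(self, interval_sets):
        report = iv.metric_matrix(interval_sets, interval_sets)
        np.testing.assert_allclose(report.values, report.values.T, atol=1e-9)

    def test_resampled_generator_diagonal_is_row_minimum(self, interval_sets):
        rng = np.random.default_rng(3)
        fake_sets = {lbl: imgs[rng.integers(0, len(imgs), len(imgs))]
                     for lbl, imgs in interval_sets.items()}
        report = iv.metric_matrix(interval_sets, fake_sets)
        for i in range(6):
            row = report.values[i]
            assert row[i] == pytest.approx(np.nanmin(row))

    def test_empty_interval_reported_missing(self, interval_sets):
        sparse = dict(interval_sets)
        sparse["<0.5,1>"] = sparse["<0.5,1>"][:0]
        report = iv.metric_matrix(sparse, interval_sets)
        assert np.isnan(report.values[0]).all()
        assert not np.isnan(report.values[1]).any()

    def test_expectation_flags_follow_relations(self, interval_sets):
        report = iv.metric_matrix(interval_sets, interval_sets)
        i = report.row_labels.index("<0.2,0.5)")
        j_sub = report.col_labels.index("<0,0.5)")
        j_comp = report.col_labels.index("<0,0.1)")
        assert report.flags[i][i] == "diagonal"
        assert report.flags[i][j_sub] == "expect-low"
        assert report.flags[i][j_comp] == "expect-high"

    def test_fhd_without_embedder_rejected(self, interval_sets):
        with pytest.raises(ValueError, match="histological"):
            iv.metric_matrix(interval_sets, interval_sets, metric="fhd")


class TestCheckRelations:
    def test_transcribed_fid_table_flags_reported_anomalies(self):
        report = iv.load_table_fixture("table1")
        comp = {(v["row"], v["col"]) for v in report.violations
                if v["kind"] == "complement-below-subset"}
        # the <0.2,0.5) dataset row sits closer to its complementary
        # intervals than to the diagonal
        for col in ("<0,0.2)", "<0.1,0.2)", "<0,0.1)"):
            assert ("<0.2,0.5)", col) in comp
        # the top interval row behaves as expected
        assert not any(v["row"] == "<0.5,1>" for v in report.violations)

    def test_transcribed_fhd_table_diagonal_recovers(self):
        report = iv.load_table_fixture("table2")
        # in the FHD table the <0.2,0.5) row regains its diagonal minimum
        assert not any(v["kind"] == "diagonal-not-row-min"
                       and v["row"] == "<0.2,0.5)"
                       for v in report.violations)

    def test_clean_matrix_has_no_violations(self):
        labels = [i.label for i in iv.PAPER_INTERVALS]
        values = np.full((6, 6), 50.0)
        np.fill_diagonal(values, 1.0)
        flags = np.array([[iv._expectation_flag(iv._BY_LABEL[r], iv._BY_LABEL[c])
                           for c in labels] for r in labels], dtype=object)
        # nested pairs mid-range, complementary high
        for i, r in enumerate(labels):
            for j, c in enumerate(labels):
                if flags[i][j] == "expect-low":
                    values[i][j] = 10.0
        report = iv.MetricMatrixReport(labels, labels, values, flags)
        assert iv.check_relations(report) == []

    def test_dataset_vs_dataset_fixture_diagonal_is_exact_zero(self):
        report = iv.load_table_fixture("table4")
        assert np.allclose(np.diag(report.values), 0.0)
        np.testing.assert_allclose(report.values, report.values.T)


class TestRelationProperties:
    """Algebraic properties of the bound-derived relation, over random
    half-open intervals."""

    @staticmethod
    def make_interval(lo, width, label):
        hi = min(1.0, lo + width)
        return iv.Ki67Interval(lo, hi, hi == 1.0, label)

    @given(st.tuples(st.floats(0, 0.8), st.floats(0.05, 1.0),
                     st.floats(0, 0.8), st.floats(0.05, 1.0)))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_relation_is_symmetric_and_exclusive(self, bounds):
        a = self.make_interval(bounds[0], bounds[1], "a")
        b = self.make_interval(bounds[2], bounds[3], "b")
        rel_ab, rel_ba = iv.relation(a, b), iv.relation(b, a)
        assert rel_ab == rel_ba
        assert rel_ab in ("identical", "subset", "complementary",
                          "overlapping")
        if rel_ab == "complementary":
            # disjoint: no point belongs to both
            xs = np.linspace(0, 1, 201)
            assert not np.any(a.contains(xs) & b.contains(xs))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_every_label_lands_in_one_interval_per_level(self, labels):
        labels = np.asarray(labels)
        for level in (("<0,0.5)", "<0.5,1>"),
                      ("<0,0.2)", "<0.2,0.5)", "<0.5,1>"),
                      ("<0,0.1)", "<0.1,0.2)", "<0.2,0.5)", "<0.5,1>")):
            counts = sum(len(iv.assign(labels, iv._BY_LABEL[lbl]))
                         for lbl in level)
            assert counts == len(labels)
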