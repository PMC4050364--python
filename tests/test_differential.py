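"""Fold-change, T score and gene-vs-outcome correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from surfscreen import (
    CohortDesign,
    PipelineError,
    fold_change,
    group_mean,
    pearson_outcome,
    score_all,
    t_score,
)
from surfscreen.simulate import SyntheticCohortSpec, generate_cohort

from conftest import make_matrix


class TestGroupMean:
    def test_single_sample_group_is_identity(self):
        m = make_matrix([[2.0, 9.0]], scale="linear")
        design = CohortDesign(
            groups={"d": ("s1",), "c": ("s2", "s2b")},
            disease_group="d", comparator_groups=(),
        )
        # add the extra sample to the matrix
        m = make_matrix([[2.0, 9.0, 9.0]], samples=["s1", "s2", "s2b"],
                        scale="linear")
        assert group_mean(m, design, "d").iloc[0] == 2.0

    def test_linear_arithmetic_mean(self):
        m = make_matrix([[2.0, 4.0, 6.0]], scale="linear")
        design = CohortDesign(groups={"g": ("s1", "s2", "s3")},
                              disease_group="g", comparator_groups=())
        assert group_mean(m, design, "g").iloc[0] == 4.0

    def test_log2_values_unlogged_before_averaging(self):
        m = make_matrix([[1.0, 3.0]])  # linear 2 and 8
        design = CohortDesign(groups={"g": ("s1", "s2")},
                              disease_group="g", comparator_groups=())
        assert group_mean(m, design, "g").iloc[0] == 5.0

    def test_unknown_group_errors(self, tiny_matrix, two_group_design):
        with pytest.raises(PipelineError):
            group_mean(tiny_matrix, two_group_design, "nope")


class TestFoldChange:
    def test_equal_means_give_one(self):
        assert fold_change(5.0, 5.0) == 1.0

    def test_simple_ratio(self):
        assert fold_change(50.0, 5.0) == 10.0

    def test_floor_bounds_ratio(self):
        assert fold_change(1.0, 0.0, floor=0.01) == 100.0

    @given(st.floats(1.1, 1e4), st.floats(1.1, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_property_above_floor(self, a, b):
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)


class TestTScore:
    def _design(self):
        return CohortDesign(
            groups={"g1": ("s1", "s2"), "g2": ("s3", "s4")},
            disease_group="g1", comparator_groups=("g2",),
        )

    def test_identical_groups_give_zero(self):
        m = make_matrix([[2.0, 4.0, 2.0, 4.0]])
        assert t_score(m, self._design(), "g1", "g2").iloc[0] == 0.0

    def test_hand_computed_welch(self):
        m = make_matrix([[4.0, 6.0, 1.0, 3.0]])
        t = t_score(m, self._design(), "g1", "g2", variant="welch")
        assert t.iloc[0] == pytest.approx(3 / np.sqrt(2))

    def test_swapping_groups_flips_sign(self):
        m = make_matrix([[4.0, 6.0, 1.0, 3.0]])
        d = self._design()
        assert t_score(m, d, "g1", "g2").iloc[0] == pytest.approx(
            -t_score(m, d, "g2", "g1").iloc[0]
        )

    def test_zero_variance_unequal_means_is_signed_infinity(self):
        m = make_matrix([[5.0, 5.0, 2.0, 2.0]])
        assert t_score(m, self._design(), "g1", "g2").iloc[0] == np.inf

    @pytest.mark.parametrize("variant", ["welch", "pooled"])
    def test_matches_scipy_on_random_matrices(self, variant):
        rng = np.random.default_rng(42)
        x = rng.normal(6, 1, size=(50, 11))
        m = make_matrix(x)
        d = CohortDesign(
            groups={"g1": tuple(m.sample_ids[:5]), "g2": tuple(m.sample_ids[5:])},
            disease_group="g1", comparator_groups=("g2",),
        )
        ours = t_score(m, d, "g1", "g2", variant=variant)
        ref = stats.ttest_ind(x[:, :5], x[:, 5:], axis=1,
                              equal_var=(variant == "pooled"))
        assert np.allclose(ours, ref.statistic, atol=1e-12)


class TestPearsonOutcome:
    def test_perfect_separation(self):
        m = make_matrix([[1.0, 1.0, 0.0, 0.0]])
        labels = {"s1": 1, "s2": 1, "s3": 0, "s4": 0}
        assert pearson_outcome(m, labels).iloc[0] == pytest.approx(1.0)

    def test_constant_probe_undefined(self):
        m = make_matrix([[3.0, 3.0, 3.0, 3.0]])
        labels = {"s1": 1, "s2": 1, "s3": 0, "s4": 0}
        assert np.isnan(pearson_outcome(m, labels).iloc[0])

    def test_closed_form_point_biserial(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0]])
        labels = {"s1": 0, "s2": 0, "s3": 1, "s4": 1}
        assert pearson_outcome(m, labels).iloc[0] == pytest.approx(2 / np.sqrt(5))

    def test_single_class_labels_error(self):
        m = make_matrix([[1.0, 2.0]])
        with pytest.raises(PipelineError):
            pearson_outcome(m, {"s1": 1, "s2": 1})

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(0, 1, size=(1, 6))
            y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
            m = make_matrix(x)
            labels = dict(zip(m.sample_ids, y))
            ours = pearson_outcome(m, labels).iloc[0]
            cov = np.mean((x[0] - x[0].mean()) * (y - y.mean()))
            ref = cov / (x[0].std() * y.std())
            assert ours == pytest.approx(ref, abs=1e-12)


class TestScoreAll:
    def test_row_count_and_null_probe_behaviour(self):
        spec = SyntheticCohortSpec(n_genes=300, n_lineage=0, n_tumor=0,
                                   n_stem=0, seed=11)
        m, design, ann, _ = generate_cohort(spec)
        table = score_all(m, design, "broad", ann)
        assert len(table) == 300
        assert table["fold_change"].mean() == pytest.approx(1.0, abs=0.25)
        assert table["t_score"].abs().median() < 2.0
        assert (table["n_disease"] == 15).all()
        assert (table["n_comparator"] == 15).all()

    def test_planted_shift_recovered_as_fold_change(self):
        spec = SyntheticCohortSpec(n_genes=400, n_lineage=0, n_tumor=8,
                                   n_stem=0, effect_size=5.0, seed=5)
        m, design, ann, truth = generate_cohort(spec)
        table = score_all(m, design, "broad", ann).set_index("probe_id")
        fc = table.loc[truth.genes_of("tumor"), "fold_change"]
        assert 16 < fc.mean() < 64  # 2**5 with log-normal sampling error

    def test_t_and_r_agree_in_sign(self):
        spec = SyntheticCohortSpec(n_genes=500, seed=2)
        m, design, ann, _ = generate_cohort(spec)
        table = score_all(m, design, "broad", ann)
        t, r = table["t_score"], table["pearson_r"]
        ok = np.isfinite(t) & np.isfinite(r) & (t != 0) & (r != 0)
        assert (np.sign(t[ok]) == np.sign(r[ok])).all()

    def test_unknown_comparator_errors(self, tiny_matrix, two_group_design,
                                       tiny_annotation):
        with pytest.raises(PipelineError):
            score_all(tiny_matrix, two_group_design, "nope", tiny_annotation)
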