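"""Confusion metrics, paired t-tests, mixed-split and sweep protocols."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from seiznet import (MetricsReport, ModelConfig, RunSet, evaluate,
                     mixed_split_generalization, paired_ttest,
                     sensitivity_sweep)
from seiznet.experiments import (benchmark_model_config, benchmark_sweep_grid,
                                 stratified_split, study_sweep_grid)


class TestEvaluate:
    def test_hand_arithmetic_case(self):
        # TP=9 FN=1 TN=8 FP=2
        pred = [1] * 9 + [0] * 1 + [0] * 8 + [1] * 2
        true = [1] * 10 + [0] * 10
        rep = evaluate(pred, true)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.sensitivity == pytest.approx(0.90)
        assert rep.specificity == pytest.approx(0.80)
        assert rep.f1 == pytest.approx(18 / 21)

    def test_perfect_predictions(self):
        rep = evaluate([0, 1, 1, 0], [0, 1, 1, 0])
        assert (rep.accuracy, rep.sensitivity, rep.specificity, rep.f1) == (1, 1, 1, 1)

    def test_all_positive_predictor_has_zero_specificity(self):
        rep = evaluate(np.ones(10), [1] * 6 + [0] * 4)
        assert rep.specificity == 0.0
        assert rep.sensitivity == 1.0

    def test_positive_class_convention_swaps_sens_spec(self):
        pred = [1, 1, 0, 0, 1]
        true = [1, 0, 0, 1, 1]
        a = evaluate(pred, true, positive_class=1)
        b = evaluate(pred, true, positive_class=0)
        assert a.sensitivity == b.specificity
        assert a.specificity == b.sensitivity

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate([], [])

    def test_agrees_with_sklearn_confusion_matrix(self, rng):
        from sklearn.metrics import confusion_matrix, f1_score
        pred = rng.integers(0, 2, 50)
        true = rng.integers(0, 2, 50)
        rep = evaluate(pred, true)
        tn, fp, fn, tp = confusion_matrix(true, pred).ravel()
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (tp, tn, fp, fn)
        assert rep.f1 == pytest.approx(f1_score(true, pred))

    @given(tp=st.integers(0, 50), tn=st.integers(0, 50),
           fp=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_count_identities(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        rep = MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn)
        assert rep.accuracy * rep.n_samples == pytest.approx(tp + tn)
        if tp + fp and tp + fn and tp:
            precision = tp / (tp + fp)
            recall = tp / (tp + fn)
            harmonic = 2 * precision * recall / (precision + recall)
            assert rep.f1 == pytest.approx(harmonic)


class TestPairedTTest:
    def test_identical_runs_null_case(self):
        r = paired_ttest([0.9, 0.8, 0.95], [0.9, 0.8, 0.95])
        assert r.t_statistic == 0.0 and r.p_value == 1.0 and not r.significant

    def test_closed_form_differences(self):
        # d = [1,2,3]: t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        r = paired_ttest([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == pytest.approx(2 * np.sqrt(3), rel=1e-9)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert paired_ttest(a, b).t_statistic == pytest.approx(
            -paired_ttest(b, a).t_statistic)

    def test_matches_scipy_reference(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=10), rng.normal(size=10)
            mine = paired_ttest(a, b)
            ref = stats.ttest_rel(a, b)
            assert abs(mine.t_statistic - ref.statistic) < 1e-8
            assert abs(mine.p_value - ref.pvalue) < 1e-8

    def test_constant_nonzero_difference_is_infinitely_significant(self):
        r = paired_ttest([1.0, 1.0, 1.0], [0.5, 0.5, 0.5])
        assert np.isinf(r.t_statistic) and r.p_value == 0.0 and r.significant

    def test_validation(self):
        with pytest.raises(ValueError, match="length"):
            paired_ttest([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="two"):
            paired_ttest([1.0], [2.0])

    def test_accepts_run_sets(self):
        a = RunSet(values=np.array([0.9, 0.92, 0.91]), seeds=[0, 1, 2])
        b = RunSet(values=np.array([0.8, 0.81, 0.79]), seeds=[0, 1, 2])
        assert paired_ttest(a, b).significant


class TestStratifiedSplit:
    def test_disjoint_covering_and_stratified(self, rng):
        y = np.array([0] * 90 + [1] * 10)
        tr, te = stratified_split(y, 0.8, rng)
        assert len(tr) == 80 and len(te) == 20
        assert sorted(np.concatenate([tr, te])) == list(range(100))
        assert y[tr].sum() == 8 and y[te].sum() == 2  # 10% in both folds

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ValueError, match="train_frac"):
            stratified_split(np.zeros(10), 1.5, rng)


def _majority_runner(train_x, train_y, test_x, test_y, seed):
    majority = int(np.bincount(train_y.astype(int)).argmax())
    return evaluate(np.full(len(test_y), majority), test_y)


class TestMixedSplit:
    def _datasets(self, rng):
        return [(rng.normal(size=(60, 16)), rng.integers(0, 2, 60)),
                (rng.normal(size=(40, 16)), rng.integers(0, 2, 40))]

    def test_partitions_are_disjoint_80_20(self, rng):
        out = mixed_split_generalization(self._datasets(rng), _majority_runner,
                                         n_repeats=20, seed=1, return_splits=True)
        assert len(out["per_repeat"]) == 20
        for tr, te in out["splits"]:
            assert len(tr) == 80 and len(te) == 20
            assert np.intersect1d(tr, te).size == 0
            assert sorted(np.concatenate([tr, te])) == list(range(100))

    def test_distinct_repeats_use_distinct_permutations(self, rng):
        out = mixed_split_generalization(self._datasets(rng), _majority_runner,
                                         n_repeats=5, seed=2, return_splits=True)
        trains = [tuple(tr) for tr, _ in out["splits"]]
        assert len(set(trains)) == 5

    def test_degenerate_aggregate(self, rng):
        def constant_runner(*args):
            return MetricsReport(tp=4, tn=4, fp=1, fn=1)
        out = mixed_split_generalization(self._datasets(rng), constant_runner,
                                         n_repeats=4, seed=0)
        assert out["summary"]["accuracy"]["mean"] == pytest.approx(0.8)
        assert out["summary"]["accuracy"]["sd"] == 0.0

    def test_validation(self, rng):
        with pytest.raises(ValueError, match="train_frac"):
            mixed_split_generalization(self._datasets(rng), _majority_runner,
                                       train_frac=0.0)
        with pytest.raises(ValueError, match="dataset"):
            mixed_split_generalization([], _majority_runner)


class TestSensitivitySweep:
    @staticmethod
    def _fake_runner(cfg: ModelConfig) -> dict:
        return {"accuracy": 0.9, "tau": cfg.dfs_temperature}

    def test_one_row_per_grid_point_with_constant_base(self):
        base = benchmark_model_config()
        grid = {"dfs_temperature": [0.1, 0.5, 1, 2]}
        table = sensitivity_sweep(base, grid, self._fake_runner)
        assert len(table) == 4
        assert (table["status"] == "ok").all()
        assert table["base_hash"].nunique() == 1

    def test_empty_grid_gives_empty_table(self):
        table = sensitivity_sweep(benchmark_model_config(), {}, self._fake_runner)
        assert len(table) == 0

    def test_non_divisible_scales_recorded_as_failed_rows(self):
        base = benchmark_model_config()
        table = sensitivity_sweep(base, {"scales": benchmark_sweep_grid()["scales"]},
                                  self._fake_runner)
        assert len(table) == 3
        fine = table.iloc[2]
        assert fine["status"] == "failed"
        assert "divide" in fine["error"] or "divisible" in fine["error"]
        assert (table.iloc[:2]["status"] == "ok").all()

    def test_interpolation_flag_makes_fine_scales_valid(self):
        base = benchmark_model_config(allow_interpolation=True)
        table = sensitivity_sweep(base, {"scales": benchmark_sweep_grid()["scales"]},
                                  self._fake_runner)
        assert (table["status"] == "ok").all()

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown config key"):
            sensitivity_sweep(benchmark_model_config(), {"bogus": [1]},
                              self._fake_runner)

    def test_study_grids_have_printed_shapes(self):
        grid = study_sweep_grid()
        assert grid["dfs_temperature"] == [0.1, 0.5, 1, 2]
        assert grid["n_heads"] == [2, 4, 8]
        assert grid["alpha_init"] == [0.3, 0.5, 0.7]
        assert [len(s) for s in grid["scales"]] == [2, 3, 5]
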