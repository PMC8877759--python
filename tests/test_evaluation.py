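import numpy as np
import pandas as pd
import pytest

from imufatigue.core import ValidationError
from imufatigue import evaluation as ev
from imufatigue.personalization import ModelConfig
from imufatigue.similarity import SimilarityParams


class TestConfusion:
    def test_all_correct(self):
        c = ev.confusion(["fatigue", "non_fatigue"], ["fatigue", "non_fatigue"])
        assert (c.fp, c.fn) == (0, 0)

    def test_enumeration(self):
        c = ev.confusion(["fatigue", "fatigue", "non_fatigue", "non_fatigue"],
                         ["fatigue", "non_fatigue", "fatigue", "non_fatigue"])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_swapping_swaps_fp_fn(self, rng):
        y1 = rng.choice(["fatigue", "non_fatigue"], 50)
        y2 = rng.choice(["fatigue", "non_fatigue"], 50)
        a = ev.confusion(y1, y2)
        b = ev.confusion(y2, y1)
        assert (a.fp, a.fn) == (b.fn, b.fp)
        assert (a.tp, a.tn) == (b.tp, b.tn)

    def test_total_is_input_length(self, rng):
        y1 = rng.choice(["fatigue", "non_fatigue"], 37)
        y2 = rng.choice(["fatigue", "non_fatigue"], 37)
        assert ev.confusion(y1, y2).total == 37

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            ev.confusion(["fatigue"], ["fatigue", "fatigue"])


class TestMetrics:
    def test_worked_example(self):
        m = ev.metrics(ev.ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
        assert m.accuracy == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)

    def test_degenerate_precision(self):
        m = ev.metrics(ev.ConfusionCounts(tp=0, fp=0, fn=2, tn=3))
        assert m.precision == 0.0
        assert m.f1 == 0.0

    def test_counting_oracle_random_vectors(self, rng):
        labels = np.array(["fatigue", "non_fatigue"])
        for _ in range(300):
            n = int(rng.integers(1, 40))
            yt = rng.choice(labels, n)
            yp = rng.choice(labels, n)
            c = ev.confusion(yt, yp)
            tp = sum(1 for a, b in zip(yt, yp) if a == b == "fatigue")
            tn = sum(1 for a, b in zip(yt, yp) if a == b == "non_fatigue")
            m = ev.metrics(c)
            assert m.accuracy == pytest.approx((tp + tn) / n)
            pred_pos = sum(1 for b in yp if b == "fatigue")
            true_pos = sum(1 for a in yt if a == "fatigue")
            assert m.precision == pytest.approx(tp / pred_pos if pred_pos else 0.0)
            assert m.recall == pytest.approx(tp / true_pos if true_pos else 0.0)

    def test_f1_from_reported_precision_recall(self):
        # percent-scale inputs give percent-scale F1
        assert ev.f1_from_precision_recall(60.57, 61.32) == pytest.approx(60.94, abs=0.005)


class TestAccuracyGainRatio:
    def test_reference_values(self):
        assert ev.accuracy_gain_ratio(5.44, 15) == pytest.approx(0.3627, abs=1e-4)
        assert ev.accuracy_gain_ratio(25.96, 8) == pytest.approx(3.245, abs=1e-4)

    def test_zero_delta(self):
        assert ev.accuracy_gain_ratio(0.0, 7) == 0.0

    def test_zero_reps_rejected(self):
        with pytest.raises(ValidationError):
            ev.accuracy_gain_ratio(1.0, 0)


class TestComparisonTable:
    def test_identical_models_zero(self):
        t = ev.comparison_table({"a": 70.0, "b": 70.0})
        assert (t.to_numpy() == 0).all()

    def test_reference_deltas(self):
        t = ev.comparison_table(
            {"cross": 60.08, "personalized": 76.08, "specific": 88.75})
        assert t.loc["personalized", "cross"] == pytest.approx(16.00, abs=1e-9)
        assert t.loc["specific", "cross"] == pytest.approx(28.67, abs=1e-9)
        assert t.loc["specific", "personalized"] == pytest.approx(12.67, abs=1e-9)

    def test_antisymmetry(self, rng):
        accs = {f"m{i}": float(rng.uniform(50, 99)) for i in range(4)}
        t = ev.comparison_table(accs)
        np.testing.assert_allclose(t.to_numpy(), -t.to_numpy().T, atol=1e-12)

    def test_mismatched_test_sets_rejected(self):
        with pytest.raises(ValidationError):
            ev.comparison_table({"a": 1.0, "b": 2.0},
                                test_ids={"a": [1, 2], "b": [1, 3]})


@pytest.fixture(scope="module")
def fast_cfg():
    return ev.PipelineConfig(
        params=SimilarityParams(),
        model=ModelConfig.tree(n_rounds=3, seed=0),
        sample_reps=5,
        budget_basis=25,
    )


class TestLoocv:
    def test_fold_count_equals_subjects(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        result = ev.loocv(table, traits, fast_cfg, mode="cross")
        assert len(result.folds) == 4
        assert sorted(f.subject_id for f in result.folds) == sorted(traits)

    def test_fold_outputs_independent_of_order(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        a = ev.loocv(table, traits, fast_cfg, mode="personalized")
        shuffled = table.sample(frac=1.0, random_state=7)
        b = ev.loocv(shuffled.sort_index(), traits, fast_cfg, mode="personalized")
        for fa, fb in zip(a.folds, b.folds):
            assert fa.subject_id == fb.subject_id
            assert fa.report.accuracy == pytest.approx(fb.report.accuracy)

    def test_too_few_subjects_rejected(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        one = table[table.subject_id == sorted(traits)[0]]
        with pytest.raises(ValidationError):
            ev.loocv(one, traits, fast_cfg)


class TestSweeps:
    def test_grid_must_include_zero(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        with pytest.raises(ValidationError):
            ev.sweep_gamma(table, traits, [1.0, 2.0], fast_cfg)

    def test_gamma_zero_reference_delta(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        result = ev.sweep_gamma(table, traits, [0.0], fast_cfg)
        for deltas in result.deltas.values():
            np.testing.assert_allclose(deltas, 0.0)

    def test_values_stable_across_grid_refinement(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        coarse = ev.sweep_gamma(table, traits, [0.0, 10.0], fast_cfg)
        fine = ev.sweep_gamma(table, traits, [0.0, 5.0, 10.0], fast_cfg)
        for variant in coarse.accuracies:
            assert coarse.accuracies[variant][0] == fine.accuracies[variant][0]
            assert coarse.accuracies[variant][-1] == fine.accuracies[variant][-1]

    def test_alpha_grid_step(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        result = ev.sweep_alpha_beta(table, traits, 0.5, fast_cfg)
        np.testing.assert_allclose(result.grid, [0.0, 0.5, 1.0])

    def test_alpha_default_step_grid_contains_reference_points(self):
        n = round(1 / 0.05)
        grid = np.round(np.linspace(0, 1, n + 1), 10)
        assert len(grid) == 21
        for point in (0.25, 0.4, 0.5):
            assert point in grid

    def test_bad_step_rejected(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        with pytest.raises(ValidationError):
            ev.sweep_alpha_beta(table, traits, 0.3, fast_cfg)
        with pytest.raises(ValidationError):
            ev.sweep_alpha_beta(table, traits, 0.0, fast_cfg)

    def test_alpha_endpoints_match_single_variant_runs(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        sweep = ev.sweep_alpha_beta(table, traits, 1.0, fast_cfg)
        signal_only = ev.loocv(
            table, traits,
            fast_cfg.with_params(SimilarityParams(0.0, 1.0, fast_cfg.params.gamma)),
            mode="personalized")
        physical_only = ev.loocv(
            table, traits,
            fast_cfg.with_params(SimilarityParams(1.0, 0.0, fast_cfg.params.gamma)),
            mode="personalized")
        assert sweep.accuracies["alpha"][0] == pytest.approx(signal_only.mean.accuracy)
        assert sweep.accuracies["alpha"][-1] == pytest.approx(physical_only.mean.accuracy)


class TestBudgetCurve:
    def test_seven_rows_per_family(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        curves = ev.budget_curve(table, traits, fast_cfg)
        assert set(curves) == {"subject_specific", "personalized"}
        for runs in curves.values():
            assert len(runs) == 7

    def test_first_row_has_no_delta(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        curves = ev.budget_curve(table, traits, fast_cfg, fractions=(0.0, 0.2))
        for runs in curves.values():
            assert runs[0].delta_accuracy is None
            assert runs[0].agr is None

    def test_agr_identity(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        curves = ev.budget_curve(table, traits, fast_cfg)
        for runs in curves.values():
            for run in runs:
                if run.agr is not None and run.n_reps > 0:
                    assert run.agr * run.n_reps == pytest.approx(
                        run.delta_accuracy, abs=1e-9)

    def test_personalized_fraction_zero_matches_loocv(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        curves = ev.budget_curve(table, traits, fast_cfg, fractions=(0.0,))
        direct = ev.loocv(table, traits, fast_cfg, mode="personalized", fraction=0.0)
        assert curves["personalized"][0].accuracy == pytest.approx(
            direct.mean.accuracy * 100)

    def test_unsorted_fractions_rejected(self, tiny_tables, fast_cfg):
        table, traits = tiny_tables
        with pytest.raises(ValidationError):
            ev.budget_curve(table, traits, fast_cfg, fractions=(0.2, 0.0))

    def test_leakage_guard_across_fractions(self, tiny_tables, fast_cfg):
        # disjointness asserted inside mix_budget; here: held-out rows shrink
        # by exactly the budget size as the fraction grows
        table, traits = tiny_tables
        sid = sorted(traits)[0]
        n_rows = (table.subject_id == sid).sum()
        for fraction in (0.0, 0.2, 0.4):
            fold = ev.run_fold(table, traits, sid, fast_cfg, "personalized", fraction)
            from imufatigue.personalization import budget_to_repetitions
            expected = n_rows - budget_to_repetitions(fraction, fast_cfg.budget_basis)
            assert fold.n_test == expected
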