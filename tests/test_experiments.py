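import numpy as np
import pandas as pd
import pytest

from valbias.exceptions import InvalidArgumentError
from valbias.experiments import (
    PRESETS,
    ExperimentConfig,
    experiment_preset,
    fit_trend,
    run_discriminable_sweep,
    run_feature_count_sweep,
    run_folds_sweep,
    run_grid_size_sweep,
    run_ratio_sweep,
    run_sample_size_sweep,
    run_sweep,
    summarize,
)
from valbias.model_tuning import make_grid
from valbias.validation_schemes import PipelineSpec

FAST_LOGREG = PipelineSpec(
    selector="ttest",
    classifier_kind="logistic",
    grid=make_grid("logistic", 2),
    inner_folds=5,
)


class TestSummarize:
    def test_constant_sample_degenerate(self):
        s = summarize([50.0, 50.0, 50.0])
        assert s["ci_width"] == 0.0
        assert s["degenerate"] is True

    def test_closed_form_interval(self):
        # mean 50, sd 2, half-width = t(.975, df=2) * 2 / sqrt(3)
        # t(.975, 2) = 4.302652729911275 -> half-width = 4.9682754235006605
        s = summarize([48.0, 50.0, 52.0])
        assert s["mean"] == pytest.approx(50.0)
        assert s["ci_lo"] == pytest.approx(50.0 - 4.9682754235006605, abs=1e-9)
        assert s["ci_hi"] == pytest.approx(50.0 + 4.9682754235006605, abs=1e-9)
        assert s["p"] == pytest.approx(1.0)  # mean exactly at chance

    def test_ci_contains_mean(self):
        rng = np.random.default_rng(4)
        x = 50 + rng.normal(0, 5, size=30)
        s = summarize(x)
        assert s["ci_lo"] <= s["mean"] <= s["ci_hi"]
        assert 0.0 < s["p"] <= 1.0

    def test_too_small_sample_rejected(self):
        with pytest.raises(InvalidArgumentError, match=">= 2"):
            summarize([50.0])


class TestFitTrend:
    def test_constant_input(self):
        x = np.arange(10.0)
        coefs = fit_trend(x, np.full(10, 3.0), order=5)
        assert coefs[0] == pytest.approx(3.0, abs=1e-8)
        assert np.allclose(coefs[1:], 0.0, atol=1e-8)

    def test_exact_interpolation(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([1.0, 3.0, 9.0])
        coefs = fit_trend(x, y, order=2)
        fitted = np.polynomial.polynomial.polyval(x, coefs)
        assert np.allclose(fitted, y, atol=1e-10)

    def test_nested_model_residuals(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 1, 25)
        y = np.sin(3 * x) + rng.normal(0, 0.1, 25)

        def rss(order):
            c = fit_trend(x, y, order=order)
            return np.sum((np.polynomial.polynomial.polyval(x, c) - y) ** 2)

        assert rss(5) <= rss(3) + 1e-12


def small_config(**kw):
    base = dict(
        variable="sample_size",
        values=(20,),
        schemes=("split", "kfold"),
        pipeline=FAST_LOGREG,
        runs_per_point=3,
        seed=11,
    )
    base.update(kw)
    return ExperimentConfig(**base)


class TestSweepEngine:
    def test_sample_size_smoke(self):
        res = run_sample_size_sweep(small_config(values=(20, 24)))
        assert set(res.raw.columns) >= {"scheme", "point", "run", "accuracy"}
        assert len(res.raw) == 2 * 2 * 3  # points x schemes x runs
        assert len(res.summary) == 4
        assert {"mean", "ci_lo", "ci_hi", "t", "p"} <= set(res.summary.columns)
        assert len(res.pairwise) == 2  # one pair per point
        assert {"t_unpaired", "p_unpaired", "t_paired", "p_paired"} <= set(
            res.pairwise.columns
        )

    def test_odd_sample_size_rejected(self):
        with pytest.raises(InvalidArgumentError, match="even"):
            run_sample_size_sweep(small_config(values=(21,)))

    def test_determinism(self):
        a = run_sample_size_sweep(small_config())
        b = run_sample_size_sweep(small_config())
        pd.testing.assert_frame_equal(a.raw, b.raw)

    def test_datasets_shared_across_schemes(self):
        # paired comparison: run column aligns scheme samples at one point
        res = run_sample_size_sweep(small_config())
        by_scheme = {
            s: g.sort_values("run")["run"].tolist()
            for s, g in res.raw.groupby("scheme")
        }
        assert by_scheme["split"] == by_scheme["kfold"]

    def test_feature_count_smoke(self):
        res = run_feature_count_sweep(
            small_config(variable="n_features", values=(10, 20), schemes=("kfold",),
                         n_samples=20)
        )
        assert res.raw["n_features"].nunique() == 2

    def test_grid_size_smoke(self):
        res = run_grid_size_sweep(
            small_config(variable="grid_size", values=(2,), schemes=("kfold",),
                         n_samples=20, pipeline="logreg")
        )
        assert len(res.raw) == 3

    def test_folds_smoke(self):
        res = run_folds_sweep(
            small_config(variable="n_folds", values=(2, 3), schemes=("kfold",),
                         n_samples=20)
        )
        assert res.raw["inner_folds"].nunique() == 2

    def test_ratio_smoke(self):
        res = run_ratio_sweep(
            small_config(
                variable="ratio",
                values=((1 / 3, 30), (2, 30)),
                schemes=("kfold",),
                n_folds=5,
            )
        )
        assert set(res.raw["n_features"]) == {10, 60}

    def test_discriminable_smoke(self):
        res = run_discriminable_sweep(
            small_config(
                variable="discriminable_sample_size",
                values=(16,),
                schemes=("kfold",),
                n_folds=4,
            )
        )
        assert "share_perfect" in res.summary.columns
        assert 0.0 <= res.summary["share_perfect"].iloc[0] <= 1.0

    def test_dispatch(self):
        res = run_sweep(small_config())
        assert res.config.variable == "sample_size"

    def test_invalid_runs_rejected(self):
        with pytest.raises(InvalidArgumentError, match="runs_per_point"):
            small_config(runs_per_point=1)


class TestPresets:
    def test_quick_preset_resolves(self):
        cfg = experiment_preset("fig3-quick", seed=3)
        assert cfg.values == (20, 60, 100)
        assert set(cfg.schemes) == {"split", "kfold", "nested", "fs_out", "tune_out"}

    def test_publication_presets_encode_protocol(self):
        fig3 = experiment_preset("fig3-svm")
        assert fig3.values[0] == 20 and fig3.values[-1] == 1000
        assert fig3.runs_per_point == 50
        fig6 = experiment_preset("fig6-svm")
        ratios = sorted({v[0] for v in fig6.values})
        assert ratios == sorted((1 / 3, 1 / 2, 1, 2, 3, 10, 20))
        ns = {v[1] for v in fig6.values}
        assert min(ns) == 14 and max(ns) == 446
        fig4b = experiment_preset("fig4b-svm")
        assert fig4b.values == tuple(range(2, 21))

    def test_unknown_preset_rejected(self):
        with pytest.raises(InvalidArgumentError, match="preset"):
            experiment_preset("fig99")

    def test_all_presets_construct(self):
        for name in PRESETS:
            experiment_preset(name, seed=1)


@pytest.mark.slow
class TestMonteCarloTrends:
    def test_bias_increases_with_feature_count(self):
        # kfold on noise at N=40: more features to select from -> more bias
        cfg = ExperimentConfig(
            variable="n_features",
            values=(10, 50, 150),
            schemes=("kfold",),
            pipeline="logreg",
            runs_per_point=12,
            n_samples=40,
            seed=5,
        )
        res = run_feature_count_sweep(cfg)
        means = res.summary.set_index("point")["mean"]
        assert means[150] > means[10]
        rho = np.corrcoef([10, 50, 150], means[[10, 50, 150]])[0, 1]
        assert rho > 0

    def test_bias_increases_with_ratio(self):
        cfg = ExperimentConfig(
            variable="ratio",
            values=((1 / 3, 42), (1, 42), (3, 42)),
            schemes=("kfold",),
            pipeline="logreg",
            runs_per_point=15,
            seed=6,
        )
        res = run_ratio_sweep(cfg)
        means = res.summary.sort_values("point")["mean"]
        by_ratio = res.summary.set_index("point")["mean"]
        assert by_ratio["r=3,N=42"] > by_ratio["r=0.333333,N=42"]

    @staticmethod
    def _paired_grid_size_diffs(kind, seed=9, runs=20, n_samples=40):
        # same dataset and fold seed for both grid sizes: a paired design
        # isolates the grid-size effect from sampling noise
        from dataclasses import replace

        from valbias.seeding import derive_seed
        from valbias.synthetic_data import generate_noise
        from valbias.validation_schemes import kfold_validate

        base = PipelineSpec(selector="ttest", classifier_kind=kind, inner_folds=5)
        small = replace(base, grid=make_grid(kind, 2))
        big = replace(base, grid=make_grid(kind, 20))
        diffs = []
        for run in range(runs):
            ds = generate_noise(n_samples, 50, derive_seed(seed, "gs-data", run))
            vseed = derive_seed(seed, "gs-val", run)
            a = kfold_validate(ds, small, seed=vseed).accuracy
            b = kfold_validate(ds, big, seed=vseed).accuracy
            diffs.append(b - a)
        return np.array(diffs)

    def test_grid_size_effect_present_for_rbf(self):
        diffs = self._paired_grid_size_diffs("rbf-svm")
        from scipy import stats

        t, p = stats.ttest_1samp(diffs, 0.0)
        assert diffs.mean() > 0
        assert t > 0 and p < 0.05

    def test_grid_size_effect_absent_for_logistic(self):
        diffs = self._paired_grid_size_diffs("logistic")
        assert abs(diffs.mean()) < 2.0
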