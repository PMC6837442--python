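import numpy as np
import pytest

from valbias.exceptions import InvalidArgumentError
from valbias.model_tuning import TuningGrid, make_grid
from valbias.seeding import derive_seed
from valbias.synthetic_data import generate_noise
from valbias.validation_schemes import (
    PipelineSpec,
    kfold_validate,
    nested_cv_validate,
    partial_nested_fs_out,
    partial_nested_tune_out,
    preset,
    train_test_split_validate,
    validate,
)

# small grids keep the unit tests fast; protocol logic is grid-agnostic
FAST_LOGREG = PipelineSpec(
    selector="ttest",
    classifier_kind="logistic",
    grid=make_grid("logistic", 2),
    inner_folds=5,
)


def all_dev_rows(record):
    return (
        set(record.selection_rows) | set(record.tuning_rows) | set(record.fit_rows)
    )


class TestSplit:
    def test_evaluation_never_in_development(self, noise_small):
        res = train_test_split_validate(noise_small, FAST_LOGREG, seed=1)
        rec = res.folds[0]
        assert set(rec.evaluation_rows) & all_dev_rows(rec) == set()
        assert len(rec.evaluation_rows) == 4  # 20% of 20
        assert res.scheme == "split"
        assert 0.0 <= res.accuracy <= 100.0

    def test_degenerate_split_rejected(self, noise_small):
        with pytest.raises(InvalidArgumentError, match="degenerate"):
            train_test_split_validate(noise_small, FAST_LOGREG, test_fraction=0.01)

    def test_split_is_stratified(self, noise_medium):
        res = train_test_split_validate(noise_medium, FAST_LOGREG, seed=3)
        eval_labels = noise_medium.labels[res.folds[0].evaluation_rows]
        assert np.bincount(eval_labels).tolist() == [6, 6]


class TestKFold:
    def test_fold_partition(self, noise_medium):
        res = kfold_validate(noise_medium, FAST_LOGREG, n_folds=10, seed=2)
        evals = [rec.evaluation_rows for rec in res.folds]
        flat = sorted(r for f in evals for r in f)
        assert flat == list(range(60))
        sizes = [len(f) for f in evals]
        assert max(sizes) - min(sizes) <= 1
        assert len(res.fold_accuracies) == 10
        assert res.accuracy == pytest.approx(np.mean(res.fold_accuracies))

    def test_development_sees_all_rows(self, noise_small):
        res = kfold_validate(noise_small, FAST_LOGREG, n_folds=5, seed=4)
        for rec in res.folds:
            assert rec.selection_rows == list(range(20))
            assert rec.tuning_rows == list(range(20))
            # the intended leak: evaluation rows were seen by development
            assert set(rec.evaluation_rows) <= set(rec.selection_rows)

    def test_frozen_model_across_folds(self, noise_small):
        res = kfold_validate(noise_small, FAST_LOGREG, n_folds=5, seed=5)
        first = res.folds[0]
        for rec in res.folds[1:]:
            assert rec.features == first.features
            assert rec.params == first.params

    def test_leave_one_out_accuracies_binary(self):
        ds = generate_noise(8, 4, seed=31)
        spec = PipelineSpec(
            selector="none",
            classifier_kind="logistic",
            grid=TuningGrid("logistic", ({"C": 1.0, "penalty": "l2"},)),
            inner_folds=2,
        )
        res = kfold_validate(ds, spec, n_folds=8, seed=6)
        assert set(res.fold_accuracies) <= {0.0, 100.0}

    def test_k_exceeding_n_rejected(self, noise_small):
        with pytest.raises(InvalidArgumentError, match="exceeds"):
            kfold_validate(noise_small, FAST_LOGREG, n_folds=21)


class TestNested:
    def test_leakage_free_per_fold(self, noise_small):
        res = nested_cv_validate(noise_small, FAST_LOGREG, n_folds=5, seed=7)
        for rec in res.folds:
            assert set(rec.evaluation_rows) & all_dev_rows(rec) == set()

    def test_models_differ_across_folds(self, noise_medium):
        res = nested_cv_validate(noise_medium, FAST_LOGREG, n_folds=5, seed=8)
        feature_sets = {tuple(rec.features) for rec in res.folds}
        assert len(feature_sets) > 1  # selection redone per fold on noise


class TestPartiallyNested:
    def test_fs_out_ledger(self, noise_small):
        res = partial_nested_fs_out(noise_small, FAST_LOGREG, n_folds=5, seed=9)
        for rec in res.folds:
            assert rec.selection_rows == list(range(20))  # pooled selection
            assert set(rec.evaluation_rows) & set(rec.tuning_rows) == set()
            assert set(rec.evaluation_rows) & set(rec.fit_rows) == set()

    def test_tune_out_ledger(self, noise_small):
        res = partial_nested_tune_out(noise_small, FAST_LOGREG, n_folds=5, seed=10)
        params = {tuple(sorted(rec.params.items())) for rec in res.folds}
        assert len(params) == 1  # hyperparameters frozen globally
        for rec in res.folds:
            assert rec.tuning_rows == list(range(20))  # pooled tuning
            assert set(rec.evaluation_rows) & set(rec.selection_rows) == set()
            assert set(rec.evaluation_rows) & set(rec.fit_rows) == set()

    def test_tune_out_alternate_feature_space(self, noise_small):
        spec_all = PipelineSpec(
            selector="ttest",
            classifier_kind="logistic",
            grid=make_grid("logistic", 2),
            inner_folds=5,
            tune_out_feature_space="all",
        )
        res = partial_nested_tune_out(noise_small, spec_all, n_folds=5, seed=11)
        assert 0.0 <= res.accuracy <= 100.0


class TestDeterminismAndDispatch:
    def test_identical_seed_identical_result(self, noise_small):
        a = nested_cv_validate(noise_small, FAST_LOGREG, n_folds=5, seed=12)
        b = nested_cv_validate(noise_small, FAST_LOGREG, n_folds=5, seed=12)
        assert a.to_json() == b.to_json()

    def test_dispatch_names(self, noise_small):
        for scheme in ("split", "kfold", "nested", "fs_out", "tune_out"):
            res = validate(scheme, noise_small, FAST_LOGREG, seed=13, n_folds=5)
            assert res.scheme == scheme

    def test_unknown_scheme_rejected(self, noise_small):
        with pytest.raises(InvalidArgumentError, match="scheme"):
            validate("bootstrap", noise_small, FAST_LOGREG)

    def test_presets(self):
        svm = preset("svm")
        assert svm.selector == "svm-rfe" and svm.classifier_kind == "rbf-svm"
        logreg = preset("logreg")
        assert logreg.selector == "ttest" and logreg.classifier_kind == "logistic"
        with pytest.raises(InvalidArgumentError):
            preset("boosting")


@pytest.mark.slow
class TestBiasOrdering:
    def test_bias_ordering_on_noise(self):
        # scaled-down Monte-Carlo: 15 runs at N=60 with the canonical logreg
        # pipeline; the biased schemes must rank kfold >= fs_out >> the
        # leakage-free ones, and kfold must exceed chance by > 3 SE
        spec = preset("logreg")
        runs = 15
        means = {}
        samples = {s: [] for s in ("kfold", "fs_out", "tune_out", "nested", "split")}
        for run in range(runs):
            ds = generate_noise(60, 50, seed=derive_seed(77, "bias-data", run))
            for scheme in samples:
                res = validate(
                    scheme, ds, spec, seed=derive_seed(77, scheme, run), n_folds=10
                )
                samples[scheme].append(res.accuracy)
        for scheme, vals in samples.items():
            means[scheme] = float(np.mean(vals))
        kfold_se = np.std(samples["kfold"], ddof=1) / np.sqrt(runs)
        assert means["kfold"] - 50.0 > 3 * kfold_se
        # for the logistic pipeline the tuning leak adds almost nothing, so
        # kfold ~ fs_out; allow sampling slack on their ordering
        assert means["kfold"] >= means["fs_out"] - 2.5
        assert means["kfold"] > 60.0 and means["fs_out"] > 60.0
        assert means["fs_out"] > means["tune_out"]
        assert means["fs_out"] > means["nested"]
        # leakage-free schemes sit near chance
        for scheme in ("tune_out", "nested", "split"):
            se = np.std(samples[scheme], ddof=1) / np.sqrt(runs)
            assert abs(means[scheme] - 50.0) <= 3 * se + 1.0
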