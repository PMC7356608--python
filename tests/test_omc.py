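import numpy as np
import pytest
from sklearn.base import clone

from omcboost import (
    CaseDataset,
    ComplexityProfile,
    OMCRegressor,
    Omics,
    SyntheticCaseSpec,
    evaluate_complexity,
    generate_case,
    make_cv_folds,
    run_case,
    select_omc,
)
from omcboost.omc import _fold_rankings
from tests.conftest import FAST, STRONG_SPEC


def _profile(k, fold_rs, flags=None):
    flags = flags or [False] * len(fold_rs)
    return ComplexityProfile.from_folds(k, fold_rs, flags)


class TestComplexityProfile:
    def test_passes_requires_strictly_exceeding_threshold(self):
        at_threshold = _profile(3, [0.25, 0.5, 0.5, 0.5, 0.5])
        assert not at_threshold.passes
        above = _profile(3, [0.2501, 0.5, 0.5, 0.5, 0.5])
        assert above.passes

    def test_constant_flag_fails_profile(self):
        p = _profile(3, [0.5, 0.5, 0.5, 0.5, 0.5], [False, True, False, False, False])
        assert not p.passes

    def test_undefined_fold_fails_profile(self):
        p = _profile(3, [0.5, float("nan"), 0.5, 0.5, 0.5])
        assert not p.passes

    def test_median_recorded(self):
        p = _profile(5, [0.4, 0.5, 0.3, 0.6, 0.45])
        assert p.median_rs == pytest.approx(0.45)


class TestSelectOmc:
    def test_unique_survivor(self):
        profiles = [_profile(2, [0.1, 0.5, 0.5, 0.5, 0.5]),
                    _profile(5, [0.4, 0.5, 0.3, 0.6, 0.45])]
        assert select_omc(profiles) == 5

    def test_none_when_nothing_passes(self):
        profiles = [_profile(k, [0.1, 0.2, 0.2, 0.1, 0.0]) for k in (2, 3, 4)]
        assert select_omc(profiles) is None

    def test_highest_median_wins(self):
        profiles = [_profile(2, [0.3, 0.4, 0.5, 0.4, 0.3]),
                    _profile(3, [0.3, 0.6, 0.7, 0.6, 0.3])]
        assert select_omc(profiles) == 3

    def test_median_tie_broken_toward_smaller_k(self):
        fold_rs = [0.3, 0.4, 0.5, 0.4, 0.3]
        assert select_omc([_profile(9, fold_rs), _profile(4, fold_rs)]) == 4

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_omc([])


class TestEvaluateComplexity:
    def test_out_of_range_k_rejected(self, strong_case):
        ds, _ = strong_case
        folds = make_cv_folds(ds.y, ds.cell_ids, seed=0)
        with pytest.raises(ValueError):
            evaluate_complexity(1, ds, folds, FAST)
        with pytest.raises(ValueError):
            evaluate_complexity(ds.m // 2 + 1, ds, folds, FAST)

    def test_strong_signal_passes_at_true_k(self, strong_case):
        ds, _ = strong_case
        folds = make_cv_folds(ds.y, ds.cell_ids, seed=1)
        profile = evaluate_complexity(5, ds, folds, FAST)
        assert len(profile.fold_rs) == 5
        assert profile.passes

    def test_constant_training_response_flags_fold(self):
        r = np.random.default_rng(0)
        X = r.standard_normal((20, 6))
        ds = CaseDataset(
            drug="d", cancer_type="t", omics=Omics.GEX,
            cell_ids=[f"c{i}" for i in range(20)],
            feature_names=[f"g{j}" for j in range(6)],
            X=X, y=np.zeros(20),
        )
        folds = make_cv_folds(ds.y, ds.cell_ids, seed=0)
        profile = evaluate_complexity(2, ds, folds, FAST)
        assert any(profile.constant_flagged)
        assert not profile.passes


class TestOMCRegressor:
    def test_sklearn_protocol(self):
        est = OMCRegressor(n_trees=40, random_state=3)
        assert clone(est).get_params() == est.get_params()

    def test_k_grid_covers_2_to_half_n(self, strong_case):
        ds, _ = strong_case
        est = OMCRegressor(n_trees=50, n_seeds=2, random_state=0)
        est.fit(ds.X[:35], ds.y[:35], feature_names=ds.feature_names)
        assert [p.k for p in est.profiles_] == list(range(2, 18))

    def test_fold_rankings_are_nested_for_all_k(self, strong_case):
        ds, _ = strong_case
        folds = make_cv_folds(ds.y, ds.cell_ids, seed=4)
        rankings = _fold_rankings(ds.X, ds.y, ds.cell_ids, folds, "continuous",
                                  ds.feature_names)
        for fold, rk in rankings.items():
            for k in range(2, ds.m // 2):
                assert set(rk.top_k(k)) < set(rk.top_k(k + 1))

    def test_selects_planted_features_on_strong_signal(self, strong_case):
        ds, truth = strong_case
        est = OMCRegressor(n_trees=50, n_seeds=3, random_state=11)
        est.fit(ds.X, ds.y, feature_names=ds.feature_names, cell_ids=ds.cell_ids)
        assert est.k_opt_ is not None
        assert len(est.selected_features_) == est.k_opt_
        assert len(set(est.selected_features_) & set(truth.informative_features)) >= 3
        pred = est.predict(ds.X)
        assert pred.shape == (ds.m,)

    def test_predict_without_passing_complexity_raises(self, null_case):
        ds, _ = null_case
        est = OMCRegressor(n_trees=50, n_seeds=2, random_state=1)
        est.fit(ds.X, ds.y, feature_names=ds.feature_names, cell_ids=ds.cell_ids)
        if est.k_opt_ is None:  # overwhelmingly likely on null data
            with pytest.raises(ValueError, match="not potentially predictive"):
                est.predict(ds.X)


class TestRunCase:
    def test_ineligible_dataset_rejected(self):
        spec = SyntheticCaseSpec(m=30, p=10, k_true=0, effect_sizes=(), seed=0)
        ds, _ = generate_case(spec)
        with pytest.raises(ValueError, match="ineligible"):
            run_case(ds, master_seed=0, config=FAST)

    def test_strong_case_end_to_end(self, strong_case):
        ds, truth = strong_case
        res = run_case(ds, master_seed=5, config=FAST)
        assert res.k_opt is not None
        assert res.classification in ("predictive", "potentially_predictive")
        assert len(res.test_cell_ids) == 10 and len(res.train_cell_ids) == 35
        assert set(res.fold_of.values()) == {1, 2, 3, 4, 5}
        assert res.omc_evaluation is not None
        assert res.all_features_evaluation is not None
        assert len(res.omc_evaluation.predictions) == 10
        # ranking covers every feature exactly once
        ranked = [row[0] for row in res.ranking]
        assert sorted(ranked) == sorted(ds.feature_names)

    def test_null_cases_not_predictive(self):
        for seed in (0, 1, 2):
            spec = SyntheticCaseSpec(m=45, p=40, k_true=0, effect_sizes=(),
                                     noise_sd=0.5, seed=seed)
            ds, _ = generate_case(spec)
            res = run_case(ds, master_seed=seed, config=FAST, include_all_features=False)
            assert res.classification != "predictive"

    def test_rerun_is_byte_identical(self, strong_case):
        ds, _ = strong_case
        a = run_case(ds, master_seed=17, config=FAST)
        b = run_case(ds, master_seed=17, config=FAST)
        assert a.to_json() == b.to_json()

    def test_test_rows_do_not_influence_training_artifacts(self, strong_case):
        """Replaying the search on the training rows alone reproduces the
        profiles and selection: the held-out rows touch nothing upstream."""
        from omcboost import make_test_split
        from omcboost._seeds import derive_seed

        ds, _ = strong_case
        res = run_case(ds, master_seed=23, config=FAST, include_all_features=False)
        split = make_test_split(ds.y, ds.cell_ids, seed=derive_seed(23, "split"))
        train_only = ds.subset(split.train_idx)
        est = OMCRegressor(kind="continuous", n_trees=FAST.n_trees, random_state=23)
        est.fit(train_only.X, train_only.y, feature_names=train_only.feature_names,
                cell_ids=train_only.cell_ids)
        assert est.k_opt_ == res.k_opt
        assert est.selected_features_ == res.selected_features
        for p_replay, p_run in zip(est.profiles_, res.profiles):
            np.testing.assert_allclose(p_replay.fold_rs, p_run.fold_rs)
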