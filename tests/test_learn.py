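"""Metrics, splits, capacity rule, ANN protocol, SVM, presence analysis."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import imperham as ip
from imperham.learn import (
    ProtocolResult,
    TrainingFailure,
    parameter_count,
    presence_analysis,
)


class TestMetrics:
    @pytest.mark.parametrize(
        "residuals, expected_mue, expected_rmse",
        [
            ([1.0, -1.0], 1.0, 1.0),
            ([0.0, 0.0, 0.0], 0.0, 0.0),
            ([3.0, 0.0, -5.0], 8.0 / 3.0, math.sqrt(34.0 / 3.0)),
        ],
    )
    def test_hand_values(self, residuals, expected_mue, expected_rmse):
        y = np.zeros(len(residuals))
        pred = -np.asarray(residuals)
        assert ip.mue(y, pred) == pytest.approx(expected_mue)
        assert ip.rmse(y, pred) == pytest.approx(expected_rmse)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    def test_rmse_dominates_mue(self, residuals):
        y = np.zeros(len(residuals))
        pred = np.asarray(residuals)
        assert ip.rmse(y, pred) >= ip.mue(y, pred) - 1e-9

    def test_errors(self):
        with pytest.raises(ValueError):
            ip.mue(np.zeros(2), np.zeros(3))
        with pytest.raises(ValueError):
            ip.rmse(np.zeros(0), np.zeros(0))

    def test_bayes_mue_closed_form(self):
        assert ip.bayes_mue(1.0) == pytest.approx(math.sqrt(2 / math.pi))


class TestMakeSplit:
    def test_singleton_groups_hit_exact_fractions(self):
        ids = [f"s{i}" for i in range(100)]
        split = ip.make_split(ids, groups={s: s for s in ids}, seed=4)
        assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (60, 15, 25)

    def test_no_group_leakage(self, delta_data):
        fm, _, groups, _ = delta_data
        for seed in range(10):
            split = ip.make_split(fm.sample_ids, groups=groups, seed=seed)
            for part in (split.train_ids, split.val_ids, split.test_ids):
                part = set(part)
                for other in (split.train_ids, split.val_ids, split.test_ids):
                    if set(other) is part:
                        continue
                gs = {groups[s] for s in part}
                rest = {groups[s] for s in set(fm.sample_ids) - part}
                # a group is either fully inside or fully outside the partition
                for g in gs:
                    members = [s for s in fm.sample_ids if groups[s] == g]
                    assert set(members) <= part or not (set(members) & part)

    def test_seed_changes_assignment_not_profile(self):
        ids = [f"s{i}" for i in range(200)]
        groups = {s: f"g{i // 5}" for i, s in enumerate(ids)}
        s1 = ip.make_split(ids, groups=groups, seed=1)
        s2 = ip.make_split(ids, groups=groups, seed=2)
        assert s1.train_ids != s2.train_ids
        assert len(s1.train_ids) == len(s2.train_ids)
        assert len(s1.val_ids) == len(s2.val_ids)

    def test_deterministic_for_fixed_seed(self):
        ids = [f"s{i}" for i in range(50)]
        assert ip.make_split(ids, seed=9).train_ids == ip.make_split(ids, seed=9).train_ids

    def test_oversized_group_warns_but_assigns(self):
        ids = [f"s{i}" for i in range(20)]
        groups = {s: "big" for s in ids[:18]} | {ids[18]: "a", ids[19]: "b"}
        with pytest.warns(UserWarning, match="exceeds"):
            split = ip.make_split(ids, groups=groups, seed=0)
        all_ids = set(split.train_ids) | set(split.val_ids) | set(split.test_ids)
        assert all_ids == set(ids)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            ip.make_split(["a"], fractions=(0.5, 0.2, 0.2))


class TestCapacityRule:
    def test_parameter_count_direct(self):
        assert parameter_count(38, 16) == 641  # (38+1)*16 + 17

    def test_boundary_h1(self):
        for d in (3, 10, 38):
            n = 10 * (d + 3)  # P(h=1) = d+3 exactly at the bound
            assert ip.max_hidden_units(n, d) == 1
            assert ip.max_hidden_units(n - 1, d) == 0

    def test_monotone_in_samples_per_param(self):
        assert ip.max_hidden_units(300, 8, 5) >= ip.max_hidden_units(300, 8, 10)

    def test_closed_form_inequality(self):
        for n in (50, 137, 1000):
            for d in (2, 7, 20):
                h = ip.max_hidden_units(n, d)
                if h >= 1:
                    assert parameter_count(d, h) <= n / 10
                assert parameter_count(d, h + 1) > n / 10

    def test_count_matches_stored_weights(self, delta_data):
        fm, target, groups, _ = delta_data
        split = ip.make_split(fm.sample_ids, groups=groups, seed=5)
        res = ip.train_ann(fm, target, ["water|8", "water|9"], hidden=3,
                           split=split, init_seed=0)
        assert res.model.weights_vector().size == parameter_count(2, 3)
        assert res.model.n_parameters == parameter_count(2, 3)


class TestTrainAnn:
    def test_noiseless_linear_target_recovered(self, conformer_dataset):
        ds0 = ip.gen_conformer_dataset(
            ip.SyntheticSpec(preset="conformers", n_groups=100,
                             noise_sigma=0.0, seed=11)
        )
        fm, _, tgt = ip.delta_correct(ds0.features, ds0.groups, "vacuum|1",
                                      target=ds0.target)
        groups = dict(zip(fm.sample_ids, fm.group_ids))
        split = ip.make_split(fm.sample_ids, groups=groups, seed=5)
        res = ip.train_ann(fm, tgt, ds0.spec.true_columns, hidden=4,
                           split=split, init_seed=2,
                           max_epochs=6000, patience=300)
        assert res.test_mue < 1e-2

    def test_constant_target_predicted(self, delta_data):
        fm, _, groups, _ = delta_data
        target = np.full(fm.n_samples, 3.75)
        split = ip.make_split(fm.sample_ids, groups=groups, seed=1)
        # constant target is learned through the output bias alone
        res = ip.train_ann(fm, target + 0.0, ["water|8"], hidden=1,
                           split=split, init_seed=0, max_epochs=200)
        assert res.test_mue == pytest.approx(0.0, abs=1e-4)

    def test_permuted_target_no_better_than_mean(self, delta_data):
        fm, target, groups, _ = delta_data
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(target)
        split = ip.make_split(fm.sample_ids, groups=groups, seed=2)
        res = ip.train_ann(fm, shuffled, ["water|8", "water|9"], hidden=2,
                           split=split, init_seed=1)
        _, _, te = split.indices(fm.sample_ids)
        baseline = ip.mue(shuffled[te], np.full(len(te), shuffled.mean()))
        assert res.test_mue > 0.5 * baseline

    def test_deterministic_given_seed_and_split(self, delta_data):
        fm, target, groups, _ = delta_data
        split = ip.make_split(fm.sample_ids, groups=groups, seed=3)
        r1 = ip.train_ann(fm, target, ["water|8", "water|9"], 2, split, init_seed=7)
        r2 = ip.train_ann(fm, target, ["water|8", "water|9"], 2, split, init_seed=7)
        assert np.array_equal(r1.model.weights_vector(), r2.model.weights_vector())
        assert r1.test_mue == r2.test_mue

    def test_capacity_guard(self, delta_data):
        fm, target, groups, _ = delta_data
        split = ip.make_split(fm.sample_ids, groups=groups, seed=3)
        with pytest.raises(ValueError, match="capacity"):
            ip.train_ann(fm, target, fm.columns[:30], hidden=10, split=split)
        with pytest.warns(UserWarning, match="OVER-CAPACITY"):
            ip.train_ann(fm, target, fm.columns[:30], hidden=10, split=split,
                         allow_over_capacity=True, max_epochs=10)

    def test_model_json_roundtrip(self, tmp_path, delta_data):
        fm, target, groups, _ = delta_data
        split = ip.make_split(fm.sample_ids, groups=groups, seed=3)
        res = ip.train_ann(fm, target, ["water|8", "acetone|9"], 2, split, init_seed=1)
        p = tmp_path / "model.json"
        res.model.to_json(p)
        back = ip.AnnModel.from_json(p)
        np.testing.assert_array_equal(back.weights_vector(),
                                      res.model.weights_vector())
        np.testing.assert_allclose(back.predict_fm(fm), res.model.predict_fm(fm))


class TestReplicaValidate:
    def test_single_nonsignificant_replica_accepts(self, delta_data):
        fm, target, groups, _ = delta_data
        split = ip.make_split(fm.sample_ids, groups=groups, seed=5)
        res = ip.train_ann(fm, target, ["water|8", "water|9"], 2, split, init_seed=2)
        rep = ip.replica_validate(res.model, fm, target, groups=groups,
                                  n_replicas=1, seed=0)
        if rep.p_values[0] >= rep.alpha:
            assert rep.fraction_nonsignificant == 1.0 and rep.accepted

    def test_acceptance_threshold_definition(self, delta_data):
        fm, target, groups, _ = delta_data
        split = ip.make_split(fm.sample_ids, groups=groups, seed=5)
        res = ip.train_ann(fm, target, ["water|8", "water|9"], 2, split, init_seed=2)
        rep = ip.replica_validate(res.model, fm, target, groups=groups,
                                  n_replicas=10, seed=1)
        assert rep.accepted == (rep.fraction_nonsignificant >= 0.80)
        assert len(rep.p_values) == 10


class TestProtocolSearch:
    def test_budget_one_equals_single_train(self, delta_data):
        fm, target, groups, _ = delta_data
        sel = ip.mrmr_select(fm, target, sizes=[4])
        result = ip.protocol_search(
            fm, target, sel.per_size_sets, groups=groups,
            n_divisions=1, n_inits=1, hidden_grid=[2], replica_budget=5, seed=0,
        )
        assert len(result.trial_log) == 1

    def test_trial_log_size_and_determinism(self, delta_data):
        fm, target, groups, _ = delta_data
        sel = ip.mrmr_select(fm, target, sizes=[4])
        kwargs = dict(groups=groups, n_divisions=2, n_inits=2,
                      hidden_grid=[1, 2], replica_budget=5, seed=3)
        r1 = ip.protocol_search(fm, target, sel.per_size_sets, **kwargs)
        r2 = ip.protocol_search(fm, target, sel.per_size_sets, **kwargs)
        assert len(r1.trial_log) == 2 * 2 * 2  # divisions x widths x inits
        assert [t["val_mue"] for t in r1.trial_log] == [t["val_mue"] for t in r2.trial_log]
        if r1.best_model is not None:
            assert np.array_equal(r1.best_model.weights_vector(),
                                  r2.best_model.weights_vector())

    def test_empty_grid_rejected(self, delta_data):
        fm, target, _, _ = delta_data
        with pytest.raises(ValueError, match="empty"):
            ip.protocol_search(fm, target, {})


class TestTrainSvm:
    @staticmethod
    def _blob_fm(n=60, sep=6.0, seed=0):
        rng = np.random.default_rng(seed)
        x = np.vstack([
            rng.normal(0.0, 1.0, size=(n // 2, 2)),
            rng.normal(sep, 1.0, size=(n // 2, 2)),
        ])
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        fm = ip.FeatureMatrix([f"s{i}" for i in range(n)], ["x", "y"], x)
        return fm, labels

    def test_separable_blobs_perfect_training_accuracy(self):
        fm, labels = self._blob_fm()
        ids = fm.sample_ids
        _, acc = ip.train_svm(fm, labels, train_ids=ids, test_ids=ids)
        assert acc["train_accuracy"] == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        n = 400
        fm = ip.FeatureMatrix(
            [f"s{i}" for i in range(n)], ["a", "b", "c"], rng.normal(size=(n, 3))
        )
        labels = np.array([0, 1] * (n // 2))
        labels = rng.permutation(labels)
        split = ip.make_split(fm.sample_ids, seed=2)
        _, acc = ip.train_svm(fm, labels, split=split)
        # binomial 95% band around 0.5 at n_test = 100
        assert 0.5 - 1.96 * 0.05 - 0.05 <= acc["test_accuracy"] <= 0.5 + 1.96 * 0.05 + 0.05

    def test_duplicated_training_samples_same_predictions(self):
        fm, labels = self._blob_fm(n=40, sep=3.0, seed=4)
        ids = fm.sample_ids
        clf1, _ = ip.train_svm(fm, labels, train_ids=ids, test_ids=ids)
        fm2 = ip.FeatureMatrix(
            ids + [f"d{i}" for i in range(len(ids))],
            fm.columns,
            np.vstack([fm.values, fm.values]),
        )
        labels2 = np.concatenate([labels, labels])
        clf2, _ = ip.train_svm(fm2, labels2,
                               train_ids=fm2.sample_ids, test_ids=ids)
        np.testing.assert_array_equal(
            clf1.predict(fm.values), clf2.predict(fm.values)
        )

    def test_single_class_training_rejected(self):
        fm, labels = self._blob_fm(n=20)
        with pytest.raises(ValueError, match="single class"):
            ip.train_svm(fm, np.zeros(20, dtype=int),
                         train_ids=fm.sample_ids, test_ids=fm.sample_ids)


class TestPresenceAnalysis:
    @staticmethod
    def _entry(metric, columns):
        return {"metric": metric, "columns": columns}

    def test_universal_medium_is_100_percent(self):
        log = [self._entry(0.1 * i, ["water|9", "vacuum|1"]) for i in range(10)]
        rep = presence_analysis(log, top_fraction=0.10)
        assert rep.medium_presence["water"] == 100.0

    def test_three_of_four_is_75_percent(self):
        log = [
            self._entry(0.1, ["water|9"]),
            self._entry(0.2, ["water|9", "hexane|2"]),
            self._entry(0.3, ["water|9"]),
            self._entry(0.4, ["hexane|2"]),
        ]
        rep = presence_analysis(log, top_fraction=1.0)
        assert rep.attribute_presence[9] == 75.0

    def test_ceil_rule(self):
        log = [self._entry(i, ["water|1"]) for i in range(50)]
        rep = presence_analysis(log, top_fraction=0.10)
        assert rep.n_models_considered == 5

    def test_higher_is_better_flips_ordering(self):
        log = [self._entry(0.9, ["water|1"]), self._entry(0.1, ["hexane|1"])]
        rep = presence_analysis(log, top_fraction=0.5, higher_is_better=True)
        assert rep.medium_presence == {"water": 100.0}

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            presence_analysis([])
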