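"""Splitting rules, fold grouping, schedules, epoch selection, training loop."""

import numpy as np
import pandas as pd
import pytest

from bdlseg.network import NetworkConfig
from bdlseg.training import (
    TrainConfig,
    learning_rate,
    make_folds,
    optimize_beta,
    select_final_model,
    split_cohort,
    train_model,
)

TOY_NET = NetworkConfig(base_filters=4, depth=3, input_size=16, seed=0)


def quick_cfg(**kw):
    kw.setdefault("initial_lr", 1e-3)
    kw.setdefault("max_epochs", 5)
    kw.setdefault("batch_size", 2)
    kw.setdefault("seed", 0)
    return TrainConfig(**kw)


class TestLearningRate:
    def test_published_schedule_values(self):
        cfg = TrainConfig(initial_lr=1e-4, lr_halving_period=30)
        assert learning_rate(cfg, 0) == pytest.approx(1e-4)
        assert learning_rate(cfg, 29) == pytest.approx(1e-4)
        assert learning_rate(cfg, 30) == pytest.approx(5e-5)
        assert learning_rate(cfg, 60) == pytest.approx(2.5e-5)

    def test_closed_form_at_every_epoch(self):
        cfg = TrainConfig(initial_lr=1e-4, lr_halving_period=30)
        for e in range(200):
            assert learning_rate(cfg, e) == 1e-4 * 0.5 ** (e // 30)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(initial_lr=0.0)
        with pytest.raises(ValueError):
            TrainConfig(lr_halving_period=0)
        with pytest.raises(ValueError):
            TrainConfig(loss_mode="focal")


class TestSplitCohort:
    def test_registry_shaped_split_counts(self, registry_manifest):
        train, test = split_cohort(registry_manifest, n_test=17, seed=0)
        assert len(test) == 17
        train_meningioma = train[train.has_lesion]
        assert len(train_meningioma) == 154
        assert train_meningioma.patient_id.nunique() == 74
        # normals always stay on the training side
        assert (~train.has_lesion).sum() == 10

    def test_test_set_only_non_followup_lesions(self, registry_manifest):
        _, test = split_cohort(registry_manifest, n_test=17, seed=1)
        assert (~test.followup).all()
        assert test.has_lesion.all()

    def test_patient_disjoint(self, registry_manifest):
        train, test = split_cohort(registry_manifest, n_test=17, seed=2)
        assert not set(train.patient_id) & set(test.patient_id)

    def test_zero_test_is_identity(self, registry_manifest):
        train, test = split_cohort(registry_manifest, n_test=0, seed=0)
        assert len(test) == 0
        assert len(train) == len(registry_manifest)

    def test_insufficient_cases_raise(self, registry_manifest):
        with pytest.raises(ValueError, match="non-follow-up"):
            split_cohort(registry_manifest, n_test=57, seed=0)


class TestMakeFolds:
    def test_folds_partition_patients(self, registry_manifest):
        train, _ = split_cohort(registry_manifest, n_test=17, seed=0)
        folds = make_folds(train, k=5, seed=0)
        lesion = train[train.has_lesion]
        val_scans = pd.concat([val for _, val in folds])
        assert sorted(val_scans.scan_id) == sorted(lesion.scan_id)
        val_pats = [set(val.patient_id) for _, val in folds]
        for i in range(5):
            for j in range(i + 1, 5):
                assert not val_pats[i] & val_pats[j]

    def test_patient_scans_share_a_fold(self, registry_manifest):
        train, _ = split_cohort(registry_manifest, n_test=17, seed=0)
        folds = make_folds(train, k=5, seed=3)
        multi = train[train.followup].patient_id.unique()
        for pid in multi[:5]:
            homes = [
                i for i, (_, val) in enumerate(folds)
                if pid in set(val.patient_id)
            ]
            assert len(homes) == 1

    def test_balanced_patient_counts(self, registry_manifest):
        # 74 lesion patients over 5 folds -> counts in {14, 15}
        train, _ = split_cohort(registry_manifest, n_test=17, seed=0)
        folds = make_folds(train, k=5, seed=1)
        counts = {val.patient_id.nunique() for _, val in folds}
        assert counts <= {14, 15}

    def test_normals_in_every_training_side_never_validation(
        self, registry_manifest
    ):
        train, _ = split_cohort(registry_manifest, n_test=17, seed=0)
        for tr, val in make_folds(train, k=5, seed=0):
            assert (~tr.has_lesion).sum() == 10
            assert val.has_lesion.all()

    def test_too_few_patients(self):
        man = pd.DataFrame(
            {
                "scan_id": ["a", "b"],
                "patient_id": ["p1", "p2"],
                "followup": [False, False],
                "has_lesion": [True, True],
                "path": ["a", "b"],
            }
        )
        with pytest.raises(ValueError, match="folds"):
            make_folds(man, k=5)


class TestTrainModel:
    def test_loss_decreases_when_overfitting_one_case(self, tiny_cases):
        (case, _), _ = tiny_cases[0][0], None
        vol, mask = tiny_cases[0][0]
        model, hist = train_model(
            [(vol, mask)], [], TOY_NET, quick_cfg(max_epochs=10, batch_size=1)
        )
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_lr_history_follows_schedule(self, tiny_cases):
        vol, mask = tiny_cases[0][0]
        cfg = quick_cfg(max_epochs=6, lr_halving_period=2)
        _, hist = train_model([(vol, mask)], [], TOY_NET, cfg)
        assert hist["lr"] == [learning_rate(cfg, e) for e in range(6)]

    def test_bdl_sees_normals(self, tiny_cases):
        lesions, normal = tiny_cases
        cfg = quick_cfg(max_epochs=1, loss_mode="bdl", beta=100.0, batch_size=4)
        _, h_with = train_model(lesions + [normal], [], TOY_NET, cfg)
        _, h_without = train_model(lesions, [], TOY_NET, cfg)
        assert h_with["train_loss"][0] != pytest.approx(h_without["train_loss"][0])

    def test_reproducible_given_seed(self, tiny_cases):
        lesions, _ = tiny_cases
        cfg = quick_cfg(max_epochs=2)
        m1, h1 = train_model(lesions, [], TOY_NET, cfg)
        m2, h2 = train_model(lesions, [], TOY_NET, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        s1, s2 = m1.state_dict(), m2.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            train_model([], [], TOY_NET, quick_cfg())

    def test_architecture_mismatch_on_init_weights(self, tiny_cases):
        from bdlseg.network import build_model

        lesions, _ = tiny_cases
        other = build_model(NetworkConfig(base_filters=8, depth=3, input_size=16))
        cfg = quick_cfg(max_epochs=1, init_weights=other.state_dict())
        with pytest.raises(ValueError):
            train_model(lesions, [], TOY_NET, cfg)

    def test_validation_history_recorded(self, tiny_cases):
        lesions, _ = tiny_cases
        cfg = quick_cfg(max_epochs=3, batch_size=1)
        _, hist = train_model(lesions[:1], lesions[1:], TOY_NET, cfg)
        assert len(hist["val_loss"]) == 3
        assert np.isfinite(hist["initial_val_loss"])


class TestOptimizeBeta:
    def test_grid_search_returns_member_and_scores(self, tiny_cases):
        lesions, normal = tiny_cases
        folds = [
            (lesions[:1] + [normal], lesions[1:]),
            (lesions[1:] + [normal], lesions[:1]),
        ]
        cfg = quick_cfg(max_epochs=2, batch_size=2)
        net = NetworkConfig(base_filters=4, depth=3, input_size=16, seed=0)
        best, scores = optimize_beta(folds, net, cfg, grid=(1.0, 100.0))
        assert best in (1.0, 100.0)
        assert set(scores) == {1.0, 100.0}
        assert all(np.isfinite(v) for v in scores.values())

    def test_empty_grid_rejected(self, tiny_cases):
        with pytest.raises(ValueError, match="grid"):
            optimize_beta([], TOY_NET, quick_cfg(), grid=())


class TestSelectFinalModel:
    def _histories(self, curves):
        return [{"val_loss": list(c)} for c in curves]

    def test_unanimous_minimum(self, tiny_cases):
        lesions, _ = tiny_cases
        curves = [[1.0, 0.9, 0.8, 0.7, 0.8, 0.9, 0.95, 0.2, 0.5]] * 3
        _, epoch = select_final_model(
            self._histories(curves), lesions, TOY_NET, quick_cfg(max_epochs=9)
        )
        assert epoch == 7

    def test_argmin_of_averaged_curve(self, tiny_cases):
        lesions, _ = tiny_cases
        curves = [[1.0, 0.4, 0.6], [1.0, 0.4, 0.6]]
        _, epoch = select_final_model(
            self._histories(curves), lesions, TOY_NET, quick_cfg(max_epochs=3)
        )
        assert epoch == 1

    def test_tie_breaks_earliest(self, tiny_cases):
        lesions, _ = tiny_cases
        curves = [[0.5, 0.4, 0.4]]
        _, epoch = select_final_model(
            self._histories(curves), lesions, TOY_NET, quick_cfg(max_epochs=3)
        )
        assert epoch == 1

    def test_matches_brute_force_argmin(self, tiny_cases):
        lesions, _ = tiny_cases
        rng = np.random.default_rng(0)
        curves = rng.uniform(0.2, 1.0, size=(5, 8))
        mean_curve = curves.mean(axis=0)
        brute = min(range(8), key=lambda e: mean_curve[e])
        _, epoch = select_final_model(
            self._histories(curves), lesions, TOY_NET, quick_cfg(max_epochs=8)
        )
        assert epoch == brute

    def test_unequal_lengths_rejected(self, tiny_cases):
        lesions, _ = tiny_cases
        with pytest.raises(ValueError, match="unequal"):
            select_final_model(
                self._histories([[1.0, 0.5], [1.0]]),
                lesions,
                TOY_NET,
                quick_cfg(),
            )
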