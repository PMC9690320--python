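"""Loss/schedule closed forms, fold splitting, metric oracles, paired
comparison tests, early stopping, transfer, and contribution analysis."""

import itertools

import numpy as np
import pytest

from ghtnet.datasets import LabeledDataset
from ghtnet.encoding import SkipgramConfig
from ghtnet.model import GHTNetConfig
from ghtnet.synthetic import (PlantedMotif, TrackModel, ctcf_like_pwm,
                              generate_planted_motif_dataset, generate_tracks)
from ghtnet.training import (TrainingConfig, cross_entropy, warmup_lr,
                             split_and_fold, train, evaluate, compare_models,
                             transfer_evaluate, contribution_analysis,
                             fit_embeddings, prepare_inputs, TrainedModel)


class TestCrossEntropy:
    def test_half_probability_is_ln2(self):
        assert cross_entropy([1], [0.5]) == pytest.approx(np.log(2),
                                                          abs=1e-9)

    def test_perfect_prediction_near_zero(self):
        assert cross_entropy([1, 0], [1.0, 0.0]) < 1e-5

    def test_hand_arithmetic_example(self):
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert cross_entropy([1, 0], [0.9, 0.2]) == pytest.approx(expected,
                                                                  abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy([1, 0], [0.5])


class TestWarmup:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 1e-4), (5, 3e-4), (10, 5e-4), (11, 5e-4), (100, 5e-4)])
    def test_linear_schedule(self, epoch, expected):
        assert warmup_lr(epoch) == pytest.approx(expected, abs=1e-12)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            warmup_lr(-1)


class TestSplitAndFold:
    def test_80_10_10_with_stratification(self):
        labels = np.array([1] * 500 + [0] * 500)
        folds = split_and_fold(labels, folds=5, seed=0)
        assert len(folds) == 5
        for tr, va, te in folds:
            assert (len(tr), len(va), len(te)) == (800, 100, 100)
            for part in (tr, va, te):
                assert labels[part].sum() == len(part) // 2  # 50/50
            assert not (set(tr) & set(va) or set(tr) & set(te)
                        or set(va) & set(te))

    def test_test_folds_pairwise_disjoint(self):
        labels = np.array([1] * 100 + [0] * 100)
        folds = split_and_fold(labels, folds=5, seed=1)
        for (_, _, a), (_, _, b) in itertools.combinations(folds, 2):
            assert not set(a) & set(b)

    def test_seed_determinism(self):
        labels = np.array([1, 0] * 50)
        f1 = split_and_fold(labels, seed=4)
        f2 = split_and_fold(labels, seed=4)
        for (a, b, c), (x, y, z) in zip(f1, f2):
            np.testing.assert_array_equal(a, x)
            np.testing.assert_array_equal(c, z)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            split_and_fold(np.ones(20))


class TestEvaluate:
    def test_perfect_ranking(self):
        rep = evaluate([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert rep.auroc == 1.0 and rep.auprc == 1.0 and rep.acc == 1.0

    def test_inverted_ranking(self):
        rep = evaluate([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1])
        assert rep.auroc == 0.0

    def test_auroc_equals_pairwise_concordance(self, rng):
        for trial in range(5):
            y = rng.integers(0, 2, size=30)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(30), 2)   # force some ties
            pos, neg = s[y == 1], s[y == 0]
            pairs = [(p, q) for p in pos for q in neg]
            conc = np.mean([1.0 if p > q else 0.5 if p == q else 0.0
                            for p, q in pairs])
            assert evaluate(y, s).auroc == pytest.approx(conc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1, 1], [0.5, 0.6])


class TestCompareModels:
    def test_identical_vectors_degenerate(self):
        out = compare_models([0.9, 0.8, 0.7], [0.9, 0.8, 0.7])
        assert out["degenerate"] and out["p_value"] == 1.0

    def test_constant_shift_equal_variance_selects_t_test(self, rng):
        a = rng.normal(0.8, 0.01, size=10)
        b = a + 0.05 + rng.normal(0.0, 0.001, size=10)
        out = compare_models(a, b)
        assert out["test"] == "paired_t"
        assert out["p_value"] < 0.01

    def test_unequal_variance_selects_wilcoxon(self, rng):
        a = rng.normal(0.0, 0.001, size=15)
        b = rng.normal(0.5, 1.0, size=15)
        out = compare_models(a, b)
        assert out["test"] == "wilcoxon"

    def test_p_value_matches_exact_permutation_oracle(self):
        a = np.array([0.896, 0.897, 0.882, 0.851, 0.877])
        b = np.array([0.899, 0.908, 0.873, 0.852, 0.883])
        out = compare_models(a, b)
        # exact paired permutation distribution of |mean difference|
        d = a - b
        obs = abs(d.mean())
        perms = [abs(np.mean(signs * d)) >= obs - 1e-12
                 for signs in itertools.product([1, -1], repeat=len(d))]
        p_exact = np.mean(perms)
        assert out["p_value"] == pytest.approx(p_exact, abs=0.02)


def _quick_setup(n=150, seed=0, motif=None, w2v_epochs=2):
    ds = generate_planted_motif_dataset(n, n, motif=motif, seed=seed)
    emb = fit_embeddings(ds, k=3,
                         config=SkipgramConfig(d=8, max_epochs=w2v_epochs),
                         seed=seed)
    X, _ = prepare_inputs(ds, emb, None)
    return ds, emb, X


class TestTrainLoop:
    def test_history_follows_warmup_schedule(self, tiny_config):
        ds, _, X = _quick_setup(n=60, seed=1)
        folds = split_and_fold(ds.labels, seed=1)
        tc = TrainingConfig(max_epochs=4, patience=10)
        _, hist = train(tiny_config, X, None, ds.labels, folds[0], tc, seed=1)
        assert hist["lr"] == [warmup_lr(e) for e in range(4)]

    def test_validation_loss_improves_on_separable_data(self, tiny_config):
        ds, _, X = _quick_setup(n=150, seed=2)
        folds = split_and_fold(ds.labels, seed=2)
        tc = TrainingConfig(max_epochs=10, patience=10,
                            lr_start=5e-4, lr_peak=1e-3, warmup_epochs=2)
        _, hist = train(tiny_config, X, None, ds.labels, folds[0], tc, seed=2)
        assert min(hist["val_loss"]) < hist["val_loss"][0]

    def test_early_stop_after_patience_and_best_restored(self, tiny_config):
        ds, _, X = _quick_setup(n=60, seed=3)
        folds = split_and_fold(ds.labels, seed=3)
        # freeze learning: zero learning rate -> no improvement possible
        tc = TrainingConfig(max_epochs=50, patience=5,
                            lr_start=0.0, lr_peak=0.0, warmup_epochs=1)
        _, hist = train(tiny_config, X, None, ds.labels, folds[0], tc, seed=3)
        assert len(hist["val_loss"]) == 1 + 5     # best epoch + patience
        assert hist["best_val_loss"] == min(hist["val_loss"])

    def test_single_class_training_split_rejected(self, tiny_config):
        X = np.zeros((10, 21, 8), dtype=np.float32)
        labels = np.ones(10)
        split = (np.arange(8), np.array([8]), np.array([9]))
        with pytest.raises(ValueError):
            train(tiny_config, X, None, labels, split)


@pytest.fixture(scope="module")
def trained(tiny_config):
    ds, emb, X = _quick_setup(n=250, seed=4)
    folds = split_and_fold(ds.labels, seed=4)
    tc = TrainingConfig(max_epochs=10, patience=10, lr_start=5e-4,
                        lr_peak=1e-3, warmup_epochs=2)
    model, _ = train(tiny_config, X, None, ds.labels, folds[0], tc, seed=4)
    return ds, emb, X, folds[0], model


class TestTransfer:
    def _bundle(self, model, emb, cfg):
        return TrainedModel(model=model, config=cfg, embeddings=emb,
                            normalizer=None, channel_names=[], history={},
                            seed=4)

    def test_b_equals_test_split_gives_identical_metrics(self, trained,
                                                         tiny_config):
        ds, emb, X, split, model = trained
        te = split[2]
        bundle = self._bundle(model, emb, tiny_config)
        out = transfer_evaluate(bundle, (X[te], None, ds.labels[te]),
                                ds.subset(te))
        assert out["transferred"].auroc == pytest.approx(
            out["in_domain"].auroc, abs=1e-12)

    def test_same_distribution_transfer_small_auroc_drop(self, trained,
                                                         tiny_config):
        ds, emb, X, split, model = trained
        te = split[2]
        ds_b = generate_planted_motif_dataset(250, 250, seed=104)
        bundle = self._bundle(model, emb, tiny_config)
        out = transfer_evaluate(bundle, (X[te], None, ds.labels[te]), ds_b)
        assert out["in_domain"].auroc - out["transferred"].auroc <= 0.05

    def test_shuffled_labels_transfer_near_chance(self, trained, tiny_config):
        ds, emb, X, split, model = trained
        te = split[2]
        ds_b = generate_planted_motif_dataset(250, 250, seed=105)
        rng = np.random.default_rng(0)
        ds_b.labels = rng.permutation(ds_b.labels)
        bundle = self._bundle(model, emb, tiny_config)
        out = transfer_evaluate(bundle, (X[te], None, ds.labels[te]), ds_b)
        assert abs(out["transferred"].auroc - 0.5) < 0.15

    def test_missing_channels_listed(self, trained, tiny_config):
        ds, emb, X, split, model = trained
        bundle = TrainedModel(model=model, config=tiny_config,
                              embeddings=emb, normalizer=None,
                              channel_names=["dnase"], history={}, seed=4)
        with pytest.raises(KeyError, match="dnase"):
            transfer_evaluate(bundle, (X[split[2]], None,
                                       ds.labels[split[2]]), ds)


@pytest.fixture(scope="module")
def tracked():
    ds = generate_planted_motif_dataset(120, 120, seed=6)
    generate_tracks(ds, {
        "informative": TrackModel(kind="peak_bump", amplitude=1.0,
                                  noise_sd=0.3, label_effect=3.0),
        "noise": TrackModel(kind="noise", noise_sd=1.0),
    }, seed=6)
    return ds


class TestContribution:
    def test_informative_group_dominates_and_sums_to_100(self, tracked,
                                                         tiny_config):
        from dataclasses import replace
        cfg = replace(tiny_config, use_sequence=False, n_feature_channels=1)
        out = contribution_analysis(
            tracked, {"informative": ["informative"], "noise": ["noise"]},
            model_config=cfg,
            training_config=TrainingConfig(max_epochs=6, patience=6,
                                           lr_start=5e-4, lr_peak=1e-3,
                                           warmup_epochs=2),
            strategy="separate_input", seed=6)
        pct = out["contribution_pct"]
        assert pct["informative"] > 50.0 > pct["noise"]
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.1)

    def test_fewer_than_two_groups_rejected(self, tracked):
        with pytest.raises(ValueError):
            contribution_analysis(tracked, {"only": ["informative"]})

    def test_empty_group_rejected(self, tracked):
        with pytest.raises(ValueError, match="empty"):
            contribution_analysis(tracked, {"a": ["informative"], "b": []})
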