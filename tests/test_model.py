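"""CNN architecture arithmetic, soft targets, training and ensemble behavior."""

import numpy as np
import pytest

import wristmotor.model as mo
from wristmotor.augment import LeakageError, augment_training_set, random_rotation, rotate_window
from wristmotor.evaluate import ConfusionMatrix3, clinimetrics
from wristmotor.preprocess import WindowedDataset
from conftest import make_band_dataset

TINY = dict(fc_hidden=32, epochs=5, batch_size=32, early_stopping=False,
            n_members=1)


def balanced_accuracy(windows, preds):
    cm = ConfusionMatrix3.from_labels([int(w.label) for w in windows],
                                      [p.argmax for p in preds])
    return clinimetrics(cm)["balanced_accuracy"]


class TestArchitecture:
    def test_default_block_lengths(self):
        # oracle: L_out = floor((L_in - k)/s) + 1 applied step by step
        cfg = mo.CNNConfig()
        lengths, l = [], 3600
        for k, s in cfg.temporal:
            l = (l - k) // s + 1
            lengths.append(l)
        assert lengths == [899, 223, 73, 35, 16, 14, 13]
        assert mo.block_lengths(cfg) == lengths

    def test_caption_flatten_is_832(self):
        assert mo.flatten_length(mo.CNNConfig.named("caption")) == 13 * 64 == 832

    def test_paper_text_flatten_is_13x1024(self):
        assert mo.flatten_length(mo.CNNConfig.named("paper-text")) == 13 * 1024

    def test_output_is_three_logits(self):
        cfg = mo.CNNConfig.named("reduced", fc_hidden=16)
        net = mo.build_cnn(cfg, np.random.default_rng(0))
        y = net.forward(np.zeros((2, 3, 3600), np.float32))
        assert y.shape == (2, 3)

    def test_bad_schedule_reports_lengths(self):
        cfg = mo.CNNConfig(temporal=((8, 4), (8, 4), (8, 4), (4, 2), (4, 2),
                                     (3, 1), (2, 1)))
        with pytest.raises(mo.ShapeError, match=r"\["):
            mo.build_cnn(cfg)

    def test_parameter_count_closed_form_matches_network(self):
        for name in ("caption", "reduced"):
            cfg = mo.CNNConfig.named(name, fc_hidden=64)
            net = mo.build_cnn(cfg, np.random.default_rng(0))
            assert net.n_parameters() == mo.parameter_count(cfg)

    def test_channel_scaling_changes_count_predictably(self):
        base = mo.CNNConfig(channels=(8, 16, 16, 32, 32, 64, 64), fc_hidden=64)
        half = mo.CNNConfig(channels=(4, 8, 8, 16, 16, 32, 32), fc_hidden=64)

        def conv_params(cfg):
            n, c_in = 0, 3
            for c, (k, _) in zip(cfg.channels, cfg.temporal):
                n += c_in * k * c + 2 * c
                c_in = c
            return n
        # closed form: conv weight terms scale ~1/4 except the input block (~1/2)
        assert mo.parameter_count(base) - mo.parameter_count(half) == \
            (conv_params(base) - conv_params(half)) \
            + (mo.flatten_length(base) - mo.flatten_length(half)) * 64

    def test_image_layout_is_same_computation(self):
        a = mo.CNNConfig.named("reduced", input_layout="channels")
        b = mo.CNNConfig.named("reduced", input_layout="image")
        na = mo.build_cnn(a, np.random.default_rng(3))
        nb = mo.build_cnn(b, np.random.default_rng(3))
        x = np.random.default_rng(0).normal(size=(2, 3, 3600)).astype(np.float32)
        assert np.array_equal(na.forward(x), nb.forward(x))


class TestSoftTarget:
    @pytest.mark.parametrize("label,expected", [
        (1.0, (0, 1, 0)),
        (1.3, (0, 0.7, 0.3)),
        (0.5, (0.5, 0.5, 0)),
        (0.0, (1, 0, 0)),
        (2.0, (0, 0, 1)),
    ])
    def test_examples(self, label, expected):
        assert mo.soft_target(label) == pytest.approx(expected, abs=1e-12)

    def test_mass_sums_to_one_and_out_of_range_rejected(self):
        for l in np.linspace(0, 2, 21):
            assert mo.soft_target(l).sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            mo.soft_target(2.1)


class TestTraining:
    def test_zero_epochs_predicts_near_uniform_on_average(self, band_windows):
        cfg = mo.CNNConfig.named("reduced", **{**TINY, "epochs": 0})
        m = mo.train_member(band_windows, ["S0", "S1"], cfg,
                            np.random.default_rng(0))
        preds = mo.predict(mo.EnsembleModel([m], cfg), band_windows[:30])
        mean_p = np.mean([p.p for p in preds], axis=0)
        assert np.all(np.abs(mean_p - 1 / 3) < 0.25)

    def test_loss_decreases_on_separable_fixture(self, band_windows):
        cfg = mo.CNNConfig.named("reduced", **TINY)
        m = mo.train_member(band_windows, ["S0", "S1", "S2", "S3"], cfg,
                            np.random.default_rng(1))
        assert m.history[-1] < m.history[0]

    def test_band_power_oracle_then_cnn_beat_090(self, band_windows):
        """Verify the fixture is separable with a band-power logistic oracle
        before asking the CNN to solve it."""
        from sklearn.linear_model import LogisticRegression
        train = [w for w in band_windows if w.subject_id not in ("S4", "S5")]
        test = [w for w in band_windows if w.subject_id in ("S4", "S5")]

        def band_features(w):
            x = w.values - w.values.mean(axis=0)
            spec = np.abs(np.fft.rfft(x, axis=0)) ** 2
            f = np.fft.rfftfreq(3600, d=1 / 60.0)
            bands = [(0.5, 3), (1, 4), (4, 6)]
            return [np.log(spec[(f >= a) & (f < b)].sum() + 1e-12) for a, b in bands]
        Xtr = np.array([band_features(w) for w in train])
        Xte = np.array([band_features(w) for w in test])
        ytr = np.array([int(w.label) for w in train])
        yte = np.array([int(w.label) for w in test])
        oracle = LogisticRegression(max_iter=2000).fit(Xtr, ytr)
        assert oracle.score(Xte, yte) > 0.9  # fixture is separable

        cfg = mo.CNNConfig.named("reduced", **TINY)
        m = mo.train_member(train, ["S0", "S1", "S2", "S3"], cfg,
                            np.random.default_rng(1))
        preds = mo.predict(mo.EnsembleModel([m], cfg), train)
        acc = np.mean([p.argmax == int(w.label) for p, w in zip(preds, train)])
        assert acc > 0.9

    def test_same_seed_identical_weights(self, band_windows):
        cfg = mo.CNNConfig.named("reduced", **{**TINY, "epochs": 2})
        runs = []
        for _ in range(2):
            m = mo.train_member(band_windows, ["S0", "S1"], cfg,
                                np.random.default_rng(9))
            runs.append(np.concatenate([p.ravel() for p, _ in
                                        m.network.parameters()]))
        assert np.array_equal(runs[0], runs[1])

    def test_leakage_raises(self, band_windows):
        cfg = mo.CNNConfig.named("reduced", **TINY)
        with pytest.raises(LeakageError):
            mo.train_member(band_windows, ["S0", "S5"], cfg,
                            np.random.default_rng(0), test_subjects=("S5",))

    def test_subset_size_is_capped_at_available_subjects(self, band_windows):
        cfg = mo.CNNConfig.named("reduced", **{**TINY, "epochs": 1})
        ens = mo.train_ensemble(WindowedDataset(list(band_windows)),
                                [f"S{i}" for i in range(6)], cfg,
                                np.random.default_rng(0))
        assert all(len(m.subject_subset) == min(15, 6) for m in ens.members)


class TestPredict:
    def _trained(self, band_windows, seed=1):
        cfg = mo.CNNConfig.named("reduced", **TINY)
        return mo.train_member(band_windows, ["S0", "S1"], cfg,
                               np.random.default_rng(seed)), cfg

    def test_softmax_normalized(self, band_windows):
        m, cfg = self._trained(band_windows)
        preds = mo.predict(mo.EnsembleModel([m], cfg), band_windows[:10])
        for p in preds:
            assert sum(p.p) == pytest.approx(1.0, abs=1e-6)

    def test_identical_members_idempotent(self, band_windows):
        m, cfg = self._trained(band_windows)
        one = mo.predict(mo.EnsembleModel([m], cfg), band_windows[:5])
        three = mo.predict(mo.EnsembleModel([m, m, m], cfg), band_windows[:5])
        for a, b in zip(one, three):
            assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_mean_of_two_members(self):
        a = mo.SoftmaxPrediction((1.0, 0.0, 0.0), "S", 0.0)
        b = mo.SoftmaxPrediction((0.0, 1.0, 0.0), "S", 0.0)
        mean = np.mean([a.p, b.p], axis=0)
        assert tuple(mean) == (0.5, 0.5, 0.0)

    def test_checkpoint_round_trip(self, band_windows, tmp_path):
        m, cfg = self._trained(band_windows)
        ens = mo.EnsembleModel([m], cfg)
        mo.save_ensemble(ens, tmp_path)
        back = mo.load_ensemble(tmp_path)
        pa = mo.predict(ens, band_windows[:5])
        pb = mo.predict(back, band_windows[:5])
        for a, b in zip(pa, pb):
            assert a.p == pytest.approx(b.p, abs=1e-7)


def test_rotational_augmentation_confers_rotation_robustness(band_windows):
    """Train with vs without rotation augmentation on axis-confined signals;
    score both on randomly rotated held-out windows.  The augmented model's
    drop must stay < 0.1 and be smaller than the non-augmented model's."""
    train = WindowedDataset([w for w in band_windows
                             if w.subject_id not in ("S4", "S5")])
    test = [w for w in band_windows if w.subject_id in ("S4", "S5")]
    rot_rng = np.random.default_rng(77)
    test_rot = [rotate_window(w, random_rotation(rot_rng)) for w in test]
    cfg = mo.CNNConfig.named("reduced", **TINY)
    scores = {}
    for use_rot in (True, False):
        aug = augment_training_set(train, np.random.default_rng(21),
                                   rotate=use_rot)
        m = mo.train_member(aug.windows, ["S0", "S1", "S2", "S3"], cfg,
                            np.random.default_rng(2))
        ens = mo.EnsembleModel([m], cfg)
        plain = balanced_accuracy(test, mo.predict(ens, test))
        rotated = balanced_accuracy(test_rot, mo.predict(ens, test_rot))
        scores[use_rot] = (plain, rotated)
    drop_aug = scores[True][0] - scores[True][1]
    drop_plain = scores[False][0] - scores[False][1]
    assert drop_aug < 0.1
    assert drop_plain > drop_aug
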