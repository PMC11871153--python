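import numpy as np
import pytest

from leadgraph import (
    AttackConfig,
    DipoleCohortSpec,
    TrainConfig,
    adversarial_sweep,
    generate_cohort,
    macro_f1,
    make_augmenter,
    make_separable_task,
    split_cohort,
    train_classifier,
)
from leadgraph.evaluate import macro_f1_from_predictions

from conftest import macro_f1_brute, random_cohort


def easy_cohort(n=240, T=128, seed=0, effect=1.5, noise=0.05):
    spec = make_separable_task(
        DipoleCohortSpec(n_records=n, T=T, noise_sd=noise, seed=seed),
        effect_size=effect,
    )
    return split_cohort(generate_cohort(spec), (0.7, 0.15, 0.15), seed=seed)


class TestMacroF1:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        assert macro_f1_from_predictions(y, y, "multi-class") == 1.0

    def test_all_one_class_on_balanced_pair(self):
        """Predicting only class 0 on a balanced 2-class set: (2/3 + 0)/2 = 1/3."""
        y_true = np.array([0] * 5 + [1] * 5)
        y_pred = np.zeros(10, dtype=int)
        assert macro_f1_from_predictions(y_true, y_pred, "multi-class") == pytest.approx(1 / 3)

    def test_closed_form_confusion_table(self):
        """TP=3, FP=1, FN=1, TN=5 per class -> F1 = 6/8 = 0.75 each, macro 0.75."""
        col_true = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        col_pred = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        y_true = np.stack([col_true, col_true], axis=1)
        y_pred = np.stack([col_pred, col_pred], axis=1)
        assert macro_f1_from_predictions(y_true, y_pred, "multi-label") == pytest.approx(0.75)

    def test_absent_class_contributes_zero(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 0, 1, 1])
        # class 2 never appears in truth or prediction but is in the universe
        got = macro_f1_from_predictions(y_true, np.array([0, 0, 1, 2]), "multi-class")
        assert got == pytest.approx((1.0 + 2 / 3 + 0.0) / 3)
        assert macro_f1_from_predictions(y_true, y_pred, "multi-class") == 1.0

    @pytest.mark.parametrize("multilabel", [False, True])
    def test_agrees_with_confusion_matrix_oracle(self, multilabel):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            if multilabel:
                K = int(rng.integers(2, 6))
                yt = rng.integers(0, 2, size=(n, K))
                yp = rng.integers(0, 2, size=(n, K))
                ours = macro_f1_from_predictions(yt, yp, "multi-label")
                oracle = macro_f1_brute(yt, yp, multilabel=True)
            else:
                K = int(rng.integers(2, 6))
                yt = rng.integers(0, K, size=n)
                yp = rng.integers(0, K, size=n)
                ours = macro_f1_from_predictions(yt, yp, "multi-class")
                oracle = macro_f1_brute(yt, yp, n_classes=K)
            assert abs(ours - oracle) < 1e-12


class TestTraining:
    def test_easy_task_reaches_high_f1(self):
        cohort = easy_cohort()
        model = train_classifier(cohort.subset("train"), None, None,
                                 TrainConfig(epochs=8, seed=0))
        assert macro_f1(model, cohort.subset("test")) > 0.95

    def test_untrained_model_is_chance_level(self):
        cohort = easy_cohort(seed=1)
        model = train_classifier(cohort.subset("train"), None, None,
                                 TrainConfig(epochs=0, seed=0))
        assert macro_f1(model, cohort.subset("test")) < 0.8

    def test_identity_augmenter_equals_no_augmenter(self):
        cohort = easy_cohort(n=96, seed=2)
        tr = cohort.subset("train")
        m_none = train_classifier(tr, None, None, TrainConfig(epochs=3, seed=5))
        m_ident = train_classifier(tr, None, make_augmenter(), TrainConfig(epochs=3, seed=5))
        assert [h.get("train_loss") for h in m_none.history] == \
               [h.get("train_loss") for h in m_ident.history]
        x = tr.signals()[:8]
        np.testing.assert_array_equal(m_none.predict_proba(x), m_ident.predict_proba(x))

    def test_effect_size_separates_learnability(self):
        """No effect -> near-chance; strong effect -> well above chance."""
        f1 = {}
        for eff in (0.0, 1.5):
            cohort = easy_cohort(n=240, seed=3, effect=eff, noise=0.1)
            model = train_classifier(cohort.subset("train"), None, None,
                                     TrainConfig(epochs=6, seed=1))
            f1[eff] = macro_f1(model, cohort.subset("test"))
        assert f1[1.5] > f1[0.0] + 0.2
        assert f1[0.0] < 0.75

    def test_deterministic_given_seed(self):
        cohort = easy_cohort(n=96, seed=4)
        tr = cohort.subset("train")
        a = train_classifier(tr, None, None, TrainConfig(epochs=2, seed=9))
        b = train_classifier(tr, None, None, TrainConfig(epochs=2, seed=9))
        x = tr.signals()[:4]
        np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))

    def test_missing_labels_rejected(self):
        cohort = random_cohort(n_records=6, labels=False)
        with pytest.raises(ValueError, match="labels"):
            train_classifier(cohort, None, None, TrainConfig(epochs=1))

    def test_ragged_lengths_rejected(self, rng):
        from leadgraph import Cohort, WaveformRecord

        recs = [
            WaveformRecord(rng.normal(size=(2, T)), ("a", "b"), 1.0, f"r{T}", labels=0)
            for T in (30, 40)
        ]
        with pytest.raises(ValueError, match="ragged"):
            train_classifier(Cohort(records=recs), None, None, TrainConfig(epochs=1))


@pytest.fixture(scope="module")
def fitted():
    cohort = easy_cohort(n=300, seed=6, effect=0.8, noise=0.3)
    model = train_classifier(cohort.subset("train"), None, None,
                             TrainConfig(epochs=8, seed=0))
    return model, cohort.subset("test")


class TestAdversarialSweep:

    def test_eps_zero_equals_clean_bit_exact(self, fitted):
        model, test = fitted
        sweep = adversarial_sweep(model, test, AttackConfig(epsilons=(0.0, 0.05)))
        assert sweep.loc[0, "macro_f1"] == macro_f1(model, test)

    def test_attack_degrades_f1(self, fitted):
        model, test = fitted
        sweep = adversarial_sweep(model, test, AttackConfig(epsilons=(0.0, 0.1)))
        assert sweep.loc[1, "macro_f1"] < sweep.loc[0, "macro_f1"]

    def test_adversarial_beats_random_perturbation(self, fitted):
        """Gradient-sign damage at eps must be at least random-sign damage."""
        model, test = fitted
        eps = 0.1
        x, y = test.signals(), test.labels_array()
        fgsm = adversarial_sweep(model, test, AttackConfig(epsilons=(0.0, eps)))
        f1_adv = fgsm.loc[1, "macro_f1"]
        rng = np.random.default_rng(0)
        f1_rand = []
        for _ in range(5):
            noise = rng.choice([-1.0, 1.0], size=x.shape)
            x_r = x + eps * model.lead_std[None, :, None] * noise
            pred = model.predict_proba(x_r).argmax(axis=1)
            f1_rand.append(macro_f1_from_predictions(y, pred, "multi-class"))
        assert f1_adv <= np.mean(f1_rand) + 0.02

    def test_pgd_at_least_as_strong_as_fgsm(self, fitted):
        model, test = fitted
        eps = 0.05
        fgsm = adversarial_sweep(model, test, AttackConfig(epsilons=(eps,)))
        pgd = adversarial_sweep(
            model, test,
            AttackConfig(epsilons=(eps,), attack="projected-gradient",
                         pgd_steps=5, pgd_step_size=0.02),
        )
        assert pgd.loc[0, "macro_f1"] <= fgsm.loc[0, "macro_f1"] + 0.02

    def test_sweep_never_mutates_test_signals(self, fitted):
        model, test = fitted
        before = test.signals().copy()
        adversarial_sweep(model, test, AttackConfig(epsilons=(0.0, 0.2)))
        np.testing.assert_array_equal(test.signals(), before)


def test_attack_config_validation():
    with pytest.raises(ValueError, match="ascending"):
        AttackConfig(epsilons=(0.1, 0.05))
    with pytest.raises(ValueError, match="unknown attack"):
        AttackConfig(attack="rubber-hose")
    with pytest.raises(ValueError, match="dropout"):
        TrainConfig(dropout_p=1.5)
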