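"""Mitigation transforms and the pre/post re-audit loop, verified with
direct probe-accuracy simulation oracles."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from shortcut_audit import (
    EmbeddingDataset,
    SyntheticConfig,
    ValidationError,
    adversarial_debias,
    contrastive_debias,
    erase_bias_direction,
    generate_synthetic,
    last_layer_retrain,
    mask_dimensions,
    mitigate_and_reaudit,
)


def probe_accuracy(ds, attr="group", seed=0):
    """Oracle measurement: 5-fold CV balanced accuracy of A ~ E."""
    X = ds.embeddings
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    clf = LogisticRegression(max_iter=200)
    cv = StratifiedKFold(5, shuffle=True, random_state=seed)
    return cross_val_score(
        clf, X, ds.attribute(attr), cv=cv, scoring="balanced_accuracy"
    ).mean()


@pytest.fixture(scope="module")
def strong_shortcut():
    return generate_synthetic(SyntheticConfig(n=800, d=32, delta=2.0, k=5, seed=2))


class TestMaskDimensions:
    def test_masking_true_dims_removes_attribute_signal(self, strong_shortcut):
        ds = strong_shortcut.dataset
        assert probe_accuracy(ds) > 0.9
        masked = mask_dimensions(ds, strong_shortcut.true_dims)
        assert probe_accuracy(masked) <= 0.55

    def test_empty_mask_is_identity(self, strong_shortcut):
        ds = strong_shortcut.dataset
        out = mask_dimensions(ds, set())
        np.testing.assert_array_equal(out.embeddings, ds.embeddings)

    def test_full_mask_gives_constant_matrix(self, strong_shortcut):
        ds = strong_shortcut.dataset
        out = mask_dimensions(ds, range(ds.d))
        assert np.allclose(out.embeddings.std(axis=0), 0.0)

    def test_out_of_range_rejected(self, strong_shortcut):
        with pytest.raises(ValidationError):
            mask_dimensions(strong_shortcut.dataset, {999})


class TestEraseBiasDirection:
    def test_rank_one_shortcut_cleared_in_one_round(self, strong_shortcut):
        ds = strong_shortcut.dataset
        erased = erase_bias_direction(ds, "group", rounds=1)
        assert probe_accuracy(erased) <= 0.55

    def test_repeat_erasure_changes_little(self, strong_shortcut):
        ds = strong_shortcut.dataset
        once = erase_bias_direction(ds, "group", rounds=3)
        again = erase_bias_direction(once, "group", rounds=1)
        rel = np.linalg.norm(again.embeddings - once.embeddings) / np.linalg.norm(
            once.embeddings
        )
        assert rel < np.sqrt(3.0 / ds.d)  # one more noise direction at most

    def test_null_input_barely_changes(self):
        syn = generate_synthetic(SyntheticConfig(n=800, d=64, delta=0.0, seed=3))
        ds = syn.dataset
        erased = erase_bias_direction(ds, "group", rounds=1)
        removed = 1.0 - erased.embeddings.var() / ds.embeddings.var()
        assert removed < 3.0 / ds.d  # projection removes ~1/d of the variance


class TestAdversarialDebias:
    def test_reduces_attribute_predictability(self, strong_shortcut):
        ds = strong_shortcut.dataset
        pre = probe_accuracy(ds)
        post = probe_accuracy(adversarial_debias(ds, "group", seed=0))
        assert pre - post >= 0.2

    def test_lambda_zero_preserves_attribute_signal(self, strong_shortcut):
        ds = strong_shortcut.dataset
        pre = probe_accuracy(ds)
        post = probe_accuracy(adversarial_debias(ds, "group", lam=0.0, seed=0))
        assert abs(pre - post) <= 0.05

    def test_seed_deterministic(self, strong_shortcut):
        ds = strong_shortcut.dataset
        e1 = adversarial_debias(ds, "group", seed=4).embeddings
        e2 = adversarial_debias(ds, "group", seed=4).embeddings
        np.testing.assert_array_equal(e1, e2)


class TestLastLayerRetrain:
    @staticmethod
    def _spurious_dataset(n=1200, seed=0):
        """Classic spurious-correlation setup: Y mostly equals A, the
        shortcut dims encode A strongly, the core dim encodes Y weakly."""
        rng = np.random.default_rng(seed)
        a = (rng.random(n) < 0.5).astype(int)
        y = np.where(rng.random(n) < 0.9, a, 1 - a)
        E = rng.standard_normal((n, 10))
        for j in (0, 1, 2):
            E[:, j] += np.where(a == 1, 2.0, -2.0)
        E[:, 5] += np.where(y == 1, 0.8, -0.8)
        return EmbeddingDataset(E, y, {"g": a})

    @staticmethod
    def _worst_group_accuracy(model, ds):
        y, a = ds.task_labels, ds.attribute("g")
        accs = []
        for yv in (0, 1):
            for av in (0, 1):
                m = (y == yv) & (a == av)
                if m.sum():
                    accs.append((model.predictions[m] == y[m]).mean())
        return min(accs)

    def test_balanced_retraining_helps_worst_group(self):
        from shortcut_audit.detectors.fairness import fit_downstream

        ds = self._spurious_dataset()
        erm = fit_downstream(ds, seed=0)
        retrained = last_layer_retrain(ds, "g", seed=0)
        assert retrained is not None
        worst_erm = self._worst_group_accuracy(erm, ds)
        worst_llr = self._worst_group_accuracy(retrained, ds)
        assert worst_llr - worst_erm >= 0.05

    def test_missing_cell_not_applicable(self):
        rng = np.random.default_rng(1)
        n = 200
        a = (rng.random(n) < 0.5).astype(int)
        y = a.copy()  # (Y=1, A=0) and (Y=0, A=1) empty
        ds = EmbeddingDataset(rng.standard_normal((n, 6)), y, {"g": a})
        assert last_layer_retrain(ds, "g", seed=0) is None


class TestContrastiveDebias:
    @staticmethod
    def _disjoint_subspaces(n=800, seed=0):
        """Y and A encoded in disjoint dimensions."""
        rng = np.random.default_rng(seed)
        a = (rng.random(n) < 0.5).astype(int)
        y = (rng.random(n) < 0.5).astype(int)
        E = rng.standard_normal((n, 16))
        for j in (0, 1, 2):
            E[:, j] += np.where(a == 1, 1.5, -1.5)
        for j in (8, 9, 10):
            E[:, j] += np.where(y == 1, 1.5, -1.5)
        return EmbeddingDataset(E, y, {"g": a})

    def test_removes_attribute_keeps_task(self):
        ds = self._disjoint_subspaces()
        out = contrastive_debias(ds, "g", seed=0)

        def acc(dataset, target):
            X = dataset.embeddings
            sd = X.std(axis=0)
            X = (X - X.mean(0)) / np.where(sd > 0, sd, 1.0)
            cv = StratifiedKFold(5, shuffle=True, random_state=0)
            return cross_val_score(
                LogisticRegression(max_iter=200), X, target, cv=cv,
                scoring="balanced_accuracy",
            ).mean()

        drop_a = acc(ds, ds.attribute("g")) - acc(out, out.attribute("g"))
        drop_y = acc(ds, ds.task_labels) - acc(out, out.task_labels)
        assert drop_a >= 0.15
        assert drop_y <= 0.05

    def test_constant_attribute_rejected(self):
        rng = np.random.default_rng(2)
        n = 100
        ds = EmbeddingDataset(
            rng.standard_normal((n, 6)),
            (rng.random(n) < 0.5).astype(int),
            {"g": np.zeros(n, int)},
        )
        with pytest.raises(Exception):
            contrastive_debias(ds, "g")


class TestReauditLoop:
    def test_identity_masking_pre_equals_post(self):
        syn = generate_synthetic(SyntheticConfig(n=500, d=24, delta=1.0, k=4, seed=7))
        res = mitigate_and_reaudit(
            syn.dataset, "group", "dimension_masking",
            methods=["statistical", "geometric", "bias_direction", "frequency"],
            seed=0, mask_dims=[],
        )
        assert res.pre_report.to_dict() == res.post_report.to_dict()

    def test_erasure_reduces_agreement_on_strong_shortcut(self):
        syn = generate_synthetic(SyntheticConfig(n=600, d=24, delta=2.0, k=4, seed=8))
        res = mitigate_and_reaudit(
            syn.dataset, "group", "bias_direction_erasure",
            methods=["statistical", "geometric", "frequency", "hbac", "sis",
                     "demographic_parity"],
            seed=0,
        )
        assert res.pre_report.agreement > res.post_report.agreement
        assert res.transformed.n == syn.dataset.n
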