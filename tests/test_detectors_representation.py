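"""Embedding-native detectors: oracle equivalence, calibration, and
contract invariants."""

import numpy as np
import pytest
from scipy import stats

from shortcut_audit import EmbeddingDataset, SyntheticConfig, generate_synthetic
from shortcut_audit.detectors.representation import (
    ClusterAudit,
    ProbeSettings,
    detect_bias_direction,
    detect_frequency,
    detect_geometric,
    detect_hbac,
    detect_probe,
    detect_sis,
    detect_statistical,
)

from conftest import make_dataset


def welch_oracle(x1, x0):
    """Textbook Welch t-test, computed from first principles."""
    n1, n0 = len(x1), len(x0)
    v1, v0 = x1.var(ddof=1), x0.var(ddof=1)
    t = (x1.mean() - x0.mean()) / np.sqrt(v1 / n1 + v0 / n0)
    df = (v1 / n1 + v0 / n0) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
    )
    return 2.0 * stats.t.sf(abs(t), df)


class TestStatistical:
    def test_matches_welch_oracle_on_small_instances(self):
        """Per-dimension p-values equal a first-principles Welch computation."""
        rng = np.random.default_rng(0)
        for trial in range(5):
            n, d = 24, 4
            a = np.array([0] * 12 + [1] * 12)
            E = rng.standard_normal((n, d)) * (1 + trial * 0.3)
            E[a == 1, 0] += 0.8
            ds = EmbeddingDataset(E, np.zeros(n, int), {"g": a})
            res = detect_statistical(ds, "g", alpha=0.05)
            raw_oracle = np.array(
                [welch_oracle(E[a == 1, j], E[a == 0, j]) for j in range(d)]
            )
            min_adj_oracle = min(1.0, raw_oracle.min() * d)
            assert res.score == pytest.approx(1.0 - min_adj_oracle, abs=1e-10)

    def test_zero_variance_dim_gets_p_one(self):
        n = 30
        a = np.array([0, 1] * 15)
        E = np.random.default_rng(1).standard_normal((n, 3))
        E[:, 2] = 5.0  # constant dim
        ds = EmbeddingDataset(E, np.zeros(n, int), {"g": a})
        res = detect_statistical(ds, "g")
        assert res.details["n_degenerate_dims"] == 1
        assert 2 not in res.localized_dims

    def test_familywise_error_under_global_null(self):
        """Flag rate under a permuted-attribute global null stays near alpha."""
        flags = 0
        runs = 60
        for s in range(runs):
            ds = make_dataset(n=120, d=12, seed=1000 + s)
            flags += detect_statistical(ds, "group", alpha=0.05).flag
        assert flags / runs <= 0.12


class TestProbe:
    def test_constant_embeddings_no_signal(self):
        n = 100
        a = np.array([0, 1] * 50)
        ds = EmbeddingDataset(np.ones((n, 4)), np.zeros(n, int), {"g": a})
        res = detect_probe(ds, "g", ProbeSettings(permutations=100), seed=0)
        assert not res.flag
        assert res.details["balanced_accuracy"] == pytest.approx(0.5, abs=0.05)

    def test_strong_shortcut_flagged_and_localized(self):
        ds = make_dataset(n=400, d=12, seed=2, attr_shift=2.5, shift_dims=(3, 7))
        res = detect_probe(ds, "group", seed=0)
        assert res.flag
        assert {3, 7} <= set(res.localized_dims)

    def test_single_class_attribute_not_applicable(self):
        n = 80
        ds = EmbeddingDataset(
            np.random.default_rng(0).standard_normal((n, 4)),
            np.zeros(n, int),
            {"g": np.zeros(n, int)},
        )
        res = detect_probe(ds, "g")
        assert not res.applicable and not res.flag and res.score is None


class TestGeometric:
    def test_permutation_size_calibrated(self):
        """Empirical size <= 0.07 at nominal alpha 0.05 over 200 null runs."""
        flags = 0
        for s in range(200):
            ds = make_dataset(n=80, d=6, seed=5000 + s)
            flags += detect_geometric(ds, "group", permutations=200, seed=s).flag
        assert flags / 200 <= 0.07

    def test_identical_groups_distance_zero(self):
        half = np.random.default_rng(0).standard_normal((40, 5))
        E = np.vstack([half, half])
        a = np.array([0] * 40 + [1] * 40)
        ds = EmbeddingDataset(E, np.zeros(80, int), {"g": a})
        res = detect_geometric(ds, "g", permutations=200, seed=0)
        assert res.details["centroid_distance"] == pytest.approx(0.0, abs=1e-12)
        assert res.details["p_value"] == 1.0 and not res.flag

    def test_too_few_permutations_rejected(self):
        ds = make_dataset(n=50, d=4)
        with pytest.raises(Exception):
            detect_geometric(ds, "group", permutations=50)


class TestBiasDirection:
    def test_strong_shift_localizes_true_dims(self):
        ds = make_dataset(n=600, d=24, seed=3, attr_shift=2.0, shift_dims=(1, 5, 9))
        res = detect_bias_direction(ds, "group")
        assert res.flag
        assert set(res.localized_dims) == {1, 5, 9}

    def test_coincident_centroids_not_applicable(self):
        E = np.tile(np.arange(6.0), (8, 1))
        a = np.array([0, 1] * 4)
        ds = EmbeddingDataset(E, np.zeros(8, int), {"g": a})
        res = detect_bias_direction(ds, "g")
        assert not res.applicable

    def test_flags_on_audit_scale_null(self):
        """The documented uncalibrated behavior: in-sample AUC along the
        estimated direction clears 0.60 on pure noise at n=1000, d=128."""
        syn = generate_synthetic(SyntheticConfig(n=1000, d=128, delta=0.0, seed=11))
        res = detect_bias_direction(syn.dataset, "group")
        assert res.flag
        assert res.details["auc"] > 0.6


class TestFrequency:
    def test_identical_group_distributions_no_flag(self):
        half = np.random.default_rng(2).standard_normal((60, 6))
        E = np.vstack([half, half])
        a = np.array([0] * 60 + [1] * 60)
        ds = EmbeddingDataset(E, np.zeros(120, int), {"g": a})
        res = detect_frequency(ds, "g")
        assert not res.flag and res.localized_dims == frozenset()

    def test_strong_shift_detected_in_tails(self):
        ds = make_dataset(n=800, d=10, seed=4, attr_shift=1.5, shift_dims=(2,))
        res = detect_frequency(ds, "group")
        assert res.flag and 2 in res.localized_dims

    def test_small_groups_not_applicable(self):
        ds = make_dataset(n=14, d=4, seed=0)
        res = detect_frequency(ds, "group")
        assert not res.applicable


class TestSIS:
    def test_perfect_single_dim_sufficiency(self):
        a = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        E = np.column_stack([a.astype(float), np.zeros(8), np.zeros(8)])
        E[:, 1:] = np.random.default_rng(0).standard_normal((8, 2)) * 0.01
        ds = EmbeddingDataset(E, np.zeros(8, int), {"g": a})
        res = detect_sis(ds, "g")
        assert res.flag
        assert res.localized_dims == frozenset({0})
        assert res.details["final_accuracy"] == 1.0

    def test_flags_on_audit_scale_null(self):
        """Documented uncalibrated behavior: greedy in-sample selection
        reaches the target even on pure noise at n=1000, d=128."""
        syn = generate_synthetic(SyntheticConfig(n=1000, d=128, delta=0.0, seed=21))
        assert detect_sis(syn.dataset, "group").flag


class TestHBAC:
    def test_two_separated_blobs_aligned_with_attribute(self):
        rng = np.random.default_rng(6)
        n = 300
        a = np.array([0] * 150 + [1] * 150)
        E = rng.standard_normal((n, 6))
        E[a == 1] += 4.0
        ds = EmbeddingDataset(E, np.zeros(n, int), {"g": a})
        res = detect_hbac(ds, "g", ClusterAudit(min_cluster=30), seed=0)
        assert res.flag
        assert res.details["max_significant_gap"] > 0.4

    def test_small_sample_not_applicable(self):
        ds = make_dataset(n=60, d=4)
        res = detect_hbac(ds, "group", ClusterAudit(min_cluster=50))
        assert not res.applicable


ALL_DETECTORS = [
    ("probe", lambda ds, s: detect_probe(ds, "group", ProbeSettings(permutations=100), seed=s)),
    ("statistical", lambda ds, s: detect_statistical(ds, "group")),
    ("geometric", lambda ds, s: detect_geometric(ds, "group", permutations=200, seed=s)),
    ("bias_direction", lambda ds, s: detect_bias_direction(ds, "group")),
    ("frequency", lambda ds, s: detect_frequency(ds, "group")),
    ("sis", lambda ds, s: detect_sis(ds, "group", seed=s)),
    ("hbac", lambda ds, s: detect_hbac(ds, "group", ClusterAudit(min_cluster=30), seed=s)),
]


class TestContracts:
    @pytest.mark.parametrize("name,call", ALL_DETECTORS)
    def test_score_threshold_flag_invariant(self, name, call, small_shortcut_dataset):
        res = call(small_shortcut_dataset, 0)
        assert res.method_name == name
        if res.applicable:
            assert 0.0 <= res.score <= 1.0
            assert res.flag == (res.score > res.threshold)
            if res.localized_dims is not None:
                d = small_shortcut_dataset.d
                assert all(0 <= i < d for i in res.localized_dims)

    @pytest.mark.parametrize("name,call", ALL_DETECTORS)
    def test_row_permutation_invariance(self, name, call, small_shortcut_dataset):
        """Shuffling sample order (E, Y, A in lockstep) with fixed seeds
        leaves score and flag unchanged."""
        ds = small_shortcut_dataset
        rng = np.random.default_rng(99)
        perm = rng.permutation(ds.n)
        shuffled = ds.subset(perm)
        r1, r2 = call(ds, 0), call(shuffled, 0)
        assert r1.flag == r2.flag
        assert r1.score == pytest.approx(r2.score, abs=5e-2)
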