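import numpy as np
import pytest

from sailnet.errors import ShapeError, ValidationError
from sailnet.plasticity import (
    BatchStats,
    LearningConfig,
    local_nonlocal_discrepancy,
    update_feedforward_local,
    update_feedforward_nonlocal,
    update_inhibitory,
    update_thresholds,
)


def _loop_local_update(Q, counts, X, beta):
    """Element-wise arithmetic oracle for the Oja rule."""
    n, k = Q.shape
    b = counts.shape[0]
    out = Q.copy()
    for i in range(n):
        for j in range(k):
            acc = 0.0
            for im in range(b):
                acc += counts[im, i] * (X[im, j] - counts[im, i] * Q[i, j])
            out[i, j] += beta * acc / b
    return out


def _loop_nonlocal_update(Q, counts, X, beta):
    """Element-wise arithmetic oracle for the gradient rule."""
    n, k = Q.shape
    b = counts.shape[0]
    out = Q.copy()
    for i in range(n):
        for j in range(k):
            acc = 0.0
            for im in range(b):
                model = sum(Q[m, j] * counts[im, m] for m in range(n))
                acc += counts[im, i] * (X[im, j] - model)
            out[i, j] += beta * acc / b
    return out


@pytest.fixture
def cfg():
    return LearningConfig(p=0.5, alpha=0.1, beta=0.01, gamma=0.2, batch_size=4)


@pytest.fixture
def toy_batch():
    # 3 units, 4 images, hand-listed counts.
    counts = np.array(
        [[1, 0, 2], [0, 1, 0], [2, 1, 1], [0, 0, 0]], dtype=float
    )
    rng = np.random.default_rng(5)
    X = rng.normal(0, 1, (4, 6))
    return BatchStats(counts, X)


class TestInhibitory:
    def test_hand_computed_update(self, cfg, toy_batch):
        w = np.zeros((3, 3))
        new = update_inhibitory(w, toy_batch, cfg)
        # mean(n_i n_m) computed by hand from the counts above.
        co = toy_batch.counts.T @ toy_batch.counts / 4
        expected = np.maximum(0.1 * (co - 0.25), 0.0)
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(new, expected)
        # spot value: pair (0, 2): mean(n_0 n_2) = (2 + 0 + 2 + 0)/4 = 1
        assert new[0, 2] == pytest.approx(0.1 * (1.0 - 0.25))

    def test_silent_batch_clips_at_zero(self, cfg):
        batch = BatchStats(np.zeros((4, 3)), np.zeros((4, 6)))
        new = update_inhibitory(np.zeros((3, 3)), batch, cfg)
        assert np.all(new == 0.0)

    def test_fixed_point_when_coactivation_equals_target(self):
        # With every image giving n_i n_m = p^2 exactly, W is unchanged.
        cfg = LearningConfig(p=1.0, alpha=0.1, beta=0.001, gamma=0.1, batch_size=2)
        counts = np.ones((2, 3))
        batch = BatchStats(counts, np.zeros((2, 4)))
        w = np.array([[0.0, 0.3, 0.1], [0.3, 0.0, 0.2], [0.1, 0.2, 0.0]])
        assert np.allclose(update_inhibitory(w, batch, cfg), w)

    def test_projection_invariants_and_symmetry(self, cfg):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.7, (4, 5)).astype(float)
        batch = BatchStats(counts, rng.normal(0, 1, (4, 6)))
        w = np.abs(rng.normal(0, 0.05, (5, 5)))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        new = update_inhibitory(w, batch, cfg)
        assert new.min() >= 0.0
        assert np.all(np.diag(new) == 0.0)
        assert np.allclose(new, new.T)

    def test_sign_free_variant_skips_clipping(self, toy_batch):
        cfg = LearningConfig(p=2.0, alpha=1.0, beta=0.01, gamma=0.5,
                             batch_size=4, clip_negative_w=False)
        new = update_inhibitory(np.zeros((3, 3)), toy_batch, cfg)
        assert new.min() < 0.0
        assert np.all(np.diag(new) == 0.0)


class TestThresholds:
    def test_hand_computed_update(self, cfg, toy_batch):
        theta = np.array([1.0, -0.5, 0.0])
        new = update_thresholds(theta, toy_batch, cfg)
        means = toy_batch.counts.mean(axis=0)  # [0.75, 0.5, 0.75]
        assert np.allclose(new, theta + 0.2 * (means - 0.5))

    def test_fixed_point_at_target_rate(self, cfg):
        counts = np.full((4, 3), 0.5)
        batch = BatchStats(counts, np.zeros((4, 6)))
        theta = np.array([0.3, 1.2, -0.1])
        assert np.array_equal(update_thresholds(theta, batch, cfg), theta)

    def test_silent_batch_lowers_all_thresholds(self, cfg):
        batch = BatchStats(np.zeros((4, 3)), np.zeros((4, 6)))
        theta = np.zeros(3)
        new = update_thresholds(theta, batch, cfg)
        assert np.allclose(new, -cfg.gamma * cfg.p)


class TestFeedforward:
    def test_local_matches_loop_oracle(self, cfg, toy_batch):
        rng = np.random.default_rng(1)
        Q = rng.normal(0, 0.5, (3, 6))
        new = update_feedforward_local(Q, toy_batch, cfg)
        expected = _loop_local_update(Q, toy_batch.counts, toy_batch.stimuli, cfg.beta)
        assert np.allclose(new, expected)

    def test_nonlocal_matches_loop_oracle(self, cfg, toy_batch):
        rng = np.random.default_rng(2)
        Q = rng.normal(0, 0.5, (3, 6))
        new = update_feedforward_nonlocal(Q, toy_batch, cfg)
        expected = _loop_nonlocal_update(Q, toy_batch.counts, toy_batch.stimuli, cfg.beta)
        assert np.allclose(new, expected)

    def test_silent_unit_row_unchanged(self, cfg):
        counts = np.array([[0, 2.0], [0, 1.0]])
        rng = np.random.default_rng(3)
        batch = BatchStats(counts, rng.normal(0, 1, (2, 6)))
        Q = rng.normal(0, 0.5, (2, 6))
        new = update_feedforward_local(Q, batch, cfg)
        assert np.array_equal(new[0], Q[0])
        assert not np.array_equal(new[1], Q[1])

    def test_oja_fixed_point_is_the_stimulus(self, cfg):
        x = np.array([[0.5, -1.0, 2.0, 0.0]])
        counts = np.ones((1, 1))
        batch = BatchStats(counts, x)
        Q = x.copy()
        assert np.allclose(update_feedforward_local(Q, batch, cfg), Q)

    def test_locality_metamorphic(self, cfg, toy_batch):
        """Row i's update ignores other rows of Q and other units' counts."""
        rng = np.random.default_rng(4)
        Q = rng.normal(0, 0.5, (3, 6))
        base = update_feedforward_local(Q, toy_batch, cfg)

        q_mut = Q.copy()
        q_mut[1] += 10.0  # perturb another unit's weights
        counts_mut = toy_batch.counts.copy()
        counts_mut[:, 2] += 5.0  # and a third unit's activity
        mutated = update_feedforward_local(
            q_mut, BatchStats(counts_mut, toy_batch.stimuli), cfg
        )
        assert np.array_equal(base[0], mutated[0])

    def test_nonlocal_is_not_local(self, cfg, toy_batch):
        rng = np.random.default_rng(4)
        Q = rng.normal(0, 0.5, (3, 6))
        base = update_feedforward_nonlocal(Q, toy_batch, cfg)
        q_mut = Q.copy()
        q_mut[1] += 10.0
        mutated = update_feedforward_nonlocal(q_mut, toy_batch, cfg)
        assert not np.array_equal(base[0], mutated[0])

    def test_single_active_unit_rules_coincide(self, cfg):
        # With at most one unit active per image (n_j = 0 for j != i), the
        # non-local residual reduces to the local Oja decay term.
        rng = np.random.default_rng(6)
        counts = np.zeros((6, 3))
        for im in range(6):
            counts[im, im % 3] = 1.0
        batch = BatchStats(counts, rng.normal(0, 1, (6, 5)))
        Q = rng.normal(0, 0.5, (3, 5))
        local = update_feedforward_local(Q, batch, cfg)
        nonlocal_ = update_feedforward_nonlocal(Q, batch, cfg)
        assert np.allclose(local, nonlocal_)

    def test_all_silent_batch_leaves_q(self, cfg):
        batch = BatchStats(np.zeros((3, 2)), np.ones((3, 4)))
        Q = np.arange(8.0).reshape(2, 4)
        assert np.array_equal(update_feedforward_nonlocal(Q, batch, cfg), Q)
        assert np.array_equal(update_feedforward_local(Q, batch, cfg), Q)


def _independent_batches(p, n_units, n_pixels, n_samples, seed, batch=100):
    """Synthetic batches with independent Poisson(p) counts per unit."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_samples // batch):
        counts = rng.poisson(p, (batch, n_units)).astype(float)
        X = rng.normal(0, 1, (batch, n_pixels))
        out.append(BatchStats(counts, X))
    return out


class TestDiscrepancy:
    def test_zero_for_single_active_unit(self, cfg):
        counts = np.zeros((8, 4))
        rng = np.random.default_rng(9)
        for im in range(8):
            counts[im, im % 4] = 1.0
        batches = [BatchStats(counts, rng.normal(0, 1, (8, 5)))]
        Q = rng.normal(0, 0.5, (4, 5))
        assert local_nonlocal_discrepancy(Q, batches, cfg) == pytest.approx(0.0)

    def test_shrinks_with_sparseness(self):
        rng = np.random.default_rng(12)
        Q = rng.normal(0, 0.2, (8, 16))
        cfg = LearningConfig(p=0.05, alpha=0.1, beta=0.01, gamma=0.1)
        low = local_nonlocal_discrepancy(
            Q, _independent_batches(0.05, 8, 16, 4000, seed=1), cfg
        )
        high = local_nonlocal_discrepancy(
            Q, _independent_batches(1.0, 8, 16, 4000, seed=1), cfg
        )
        assert low < high

    def test_grows_with_count_correlation(self):
        rng = np.random.default_rng(13)
        Q = rng.normal(0, 0.2, (8, 16))
        cfg = LearningConfig(p=0.2, alpha=0.1, beta=0.01, gamma=0.1)
        ind = _independent_batches(0.2, 8, 16, 4000, seed=2)
        # Perfectly correlated counts: all units share one Poisson draw.
        corr = []
        rng2 = np.random.default_rng(2)
        for _ in range(40):
            shared = rng2.poisson(0.2, (100, 1)).astype(float)
            corr.append(
                BatchStats(np.repeat(shared, 8, axis=1), rng2.normal(0, 1, (100, 16)))
            )
        assert local_nonlocal_discrepancy(Q, corr, cfg) > local_nonlocal_discrepancy(
            Q, ind, cfg
        )

    def test_empty_batch_list_rejected(self, cfg):
        with pytest.raises(ValidationError):
            local_nonlocal_discrepancy(np.zeros((2, 2)), [], cfg)


class TestConfigValidation:
    def test_beta_ratio_warns(self):
        with pytest.warns(UserWarning, match="much smaller"):
            LearningConfig(p=0.05, alpha=0.01, beta=0.009, gamma=0.1)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValidationError):
            LearningConfig(p=0.0)
        with pytest.raises(ValidationError):
            LearningConfig(alpha=-0.1)
        with pytest.raises(ValidationError):
            LearningConfig(batch_size=0)

    def test_zero_rates_allowed_for_probing(self):
        cfg = LearningConfig(p=0.05, alpha=0.0, beta=0.0, gamma=0.0)
        assert cfg.scaled(0.5).alpha == 0.0

    def test_shape_mismatch_raises(self, cfg, toy_batch):
        with pytest.raises(ShapeError):
            update_inhibitory(np.zeros((4, 4)), toy_batch, cfg)
        with pytest.raises(ShapeError):
            update_thresholds(np.zeros(2), toy_batch, cfg)
        with pytest.raises(ShapeError):
            update_feedforward_local(np.zeros((3, 7)), toy_batch, cfg)
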