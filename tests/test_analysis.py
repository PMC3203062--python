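import numpy as np
import pytest

from sailnet.analysis import (
    firing_rate_distribution,
    fit_decoder_gain,
    fit_rate_distribution,
    linear_decode,
    overlap_vs_inhibition,
    pairwise_correlations,
    reconstruct_image,
    spike_triggered_average,
    weight_distribution,
    ReceptiveField,
)
from sailnet.dynamics import NetworkParams, run_inference
from sailnet.errors import ShapeError, ValidationError


def _cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestSTA:
    def test_single_spike_sta_is_the_patch(self):
        counts = np.array([[0.0], [1.0], [0.0]])  # 3 images, 1 unit
        X = np.array([[1.0, 2.0], [3.0, -4.0], [5.0, 6.0]])
        [rf] = spike_triggered_average(counts, X)
        assert rf.defined and rf.n_spikes_used == 1
        assert np.array_equal(rf.map, X[1])

    def test_silent_unit_is_undefined_not_zero(self):
        counts = np.array([[1.0, 0.0], [2.0, 0.0]])
        X = np.ones((2, 4))
        rf_active, rf_silent = spike_triggered_average(counts, X)
        assert rf_active.defined
        assert not rf_silent.defined and rf_silent.map is None

    def test_all_silent_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="silent"):
            out = spike_triggered_average(np.zeros((3, 2)), np.ones((3, 4)))
        assert out == []

    def test_sta_tracks_feedforward_weights_and_permutation_breaks_it(self):
        """For Gaussian stimuli the STA points along the unit's feed-forward
        row; shuffling responses against stimuli destroys the alignment."""
        rng = np.random.default_rng(0)
        n, k, b = 6, 64, 4000
        q = rng.normal(0, 1 / np.sqrt(k), (n, k))
        params = NetworkParams(q, np.zeros((n, n)), np.full(n, 1.0))
        X = rng.normal(0, 1, (b, k))
        counts = np.stack([run_inference(params, x).counts for x in X])
        rfs = spike_triggered_average(counts, X)
        cos = [
            _cosine(rf.map, q[i]) for i, rf in enumerate(rfs) if rf.n_spikes_used >= 30
        ]
        assert len(cos) >= 3
        assert min(cos) > 0.8
        perm = rng.permutation(b)
        rfs_perm = spike_triggered_average(counts[perm], X)
        cos_perm = [
            _cosine(rf.map, q[i])
            for i, rf in enumerate(rfs_perm)
            if rf.n_spikes_used >= 30
        ]
        assert np.mean(np.abs(cos_perm)) < 0.3

    def test_misalignment_rejected(self):
        with pytest.raises(ShapeError):
            spike_triggered_average(np.zeros((3, 2)), np.ones((4, 4)))


class TestCorrelations:
    def test_duplicated_unit_has_unit_correlation(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(1.0, 200).astype(float)
        counts = np.stack([a, a, rng.poisson(1.0, 200).astype(float)], axis=1)
        r = pairwise_correlations(counts)
        assert r[0] == pytest.approx(1.0)  # pair (0, 1)

    def test_independent_counts_near_zero(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(0.5, (2000, 10)).astype(float)
        r = pairwise_correlations(counts)
        assert np.nanmean(np.abs(r)) < 3 / np.sqrt(2000)

    def test_never_coactive_floor_matches_closed_form(self):
        """Two equal-rate units that never fire together sit exactly at the
        analytic lower bound r = -q / (1 - q)."""
        b, m = 200, 30
        counts = np.zeros((b, 2))
        counts[:m, 0] = 1.0
        counts[m : 2 * m, 1] = 1.0
        q = m / b
        [r] = pairwise_correlations(counts)
        assert r == pytest.approx(-q / (1 - q))

    def test_zero_variance_pair_is_nan(self):
        counts = np.column_stack([np.ones(10), np.arange(10.0)])
        [r] = pairwise_correlations(counts)
        assert np.isnan(r)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ShapeError):
            pairwise_correlations(np.zeros((5, 1)))
        with pytest.raises(ShapeError):
            pairwise_correlations(np.zeros((1, 5)))


class TestRateDistribution:
    def test_model_selection_self_consistency(self):
        rng = np.random.default_rng(3)
        lognormal_rates = rng.lognormal(mean=np.log(0.05), sigma=0.6, size=1536)
        ln, ex, degenerate = fit_rate_distribution(lognormal_rates)
        assert not degenerate
        assert ln.variance_explained > ex.variance_explained

        exp_rates = rng.exponential(scale=0.05, size=1536)
        ln2, ex2, _ = fit_rate_distribution(exp_rates)
        assert ex2.variance_explained > ln2.variance_explained

    def test_degenerate_single_bin_flagged(self):
        _, _, degenerate = fit_rate_distribution(np.full(100, 0.25))
        assert degenerate

    def test_probe_is_deterministic(self):
        rng = np.random.default_rng(4)
        n, k = 4, 16
        params = NetworkParams(
            rng.normal(0, 0.25, (n, k)), np.zeros((n, n)), np.full(n, 0.8)
        )
        probe = [rng.normal(0, 1, k) for _ in range(50)]
        a = firing_rate_distribution(params, probe)
        b = firing_rate_distribution(params, probe)
        assert np.array_equal(a.rates, b.rates)
        assert a.split_half_variance_ratio is not None

    def test_empty_probe_rejected(self):
        params = NetworkParams(np.zeros((2, 4)), np.zeros((2, 2)), np.ones(2))
        with pytest.raises(ValidationError):
            firing_rate_distribution(params, [])


class TestWeightDistribution:
    def test_lognormal_weights_well_fit(self):
        rng = np.random.default_rng(5)
        w = rng.lognormal(mean=-2.0, sigma=0.8, size=(100, 100))
        np.fill_diagonal(w, 0.0)
        fit = weight_distribution(w)
        assert fit.family == "gaussian-on-log"
        assert fit.variance_explained > 0.9
        assert fit.params["mu"] == pytest.approx(-2.0, abs=0.15)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        w = rng.lognormal(-1.0, 0.5, size=(60, 60))
        np.fill_diagonal(w, 0.0)
        base = weight_distribution(w)
        scaled = weight_distribution(10.0 * w)
        assert scaled.params["mu"] == pytest.approx(
            base.params["mu"] + np.log(10.0), abs=1e-6
        )
        assert scaled.params["sigma"] == pytest.approx(base.params["sigma"], abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            weight_distribution(np.zeros((20, 20)))


class TestOverlapInhibition:
    def test_zero_w_flagged_undefined(self):
        rng = np.random.default_rng(7)
        params = NetworkParams(
            rng.normal(0, 1, (10, 16)), np.zeros((10, 10)), np.ones(10)
        )
        out = overlap_vs_inhibition(params, n_pairs=20, seed=0)
        assert not out.defined and np.isnan(out.rank_correlation)

    def test_positive_when_inhibition_tracks_overlap(self):
        rng = np.random.default_rng(8)
        q = rng.normal(0, 1, (30, 25))
        overlap = q @ q.T
        w = np.maximum(overlap + rng.normal(0, 0.5, overlap.shape), 0.0)
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        params = NetworkParams(q, w, np.ones(30))
        out = overlap_vs_inhibition(params, n_pairs=300, seed=1)
        assert out.defined and out.rank_correlation > 0.3

    def test_random_w_orthogonal_rows_near_zero(self):
        rng = np.random.default_rng(9)
        q, _ = np.linalg.qr(rng.normal(0, 1, (40, 40)))
        w = np.abs(rng.normal(0, 0.1, (40, 40)))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        params = NetworkParams(q, w, np.ones(40))
        out = overlap_vs_inhibition(params, n_pairs=5000, seed=2)
        assert abs(out.rank_correlation) < 0.1


class TestDecoding:
    def test_silent_response_decodes_to_zero(self):
        rfs = np.ones((3, 4))
        assert np.all(linear_decode(rfs, np.zeros((5, 3))) == 0.0)

    def test_one_unit_identity(self):
        x = np.array([[0.3, -1.0, 2.0, 0.1]])
        out = linear_decode(x, np.ones((1, 1)))
        assert np.array_equal(out, x)

    def test_linearity_in_counts(self):
        rng = np.random.default_rng(10)
        rfs = rng.normal(0, 1, (6, 16))
        n1 = rng.poisson(1.0, (7, 6)).astype(float)
        n2 = rng.poisson(1.0, (7, 6)).astype(float)
        lhs = linear_decode(rfs, 2.0 * n1 + 3.0 * n2)
        rhs = 2.0 * linear_decode(rfs, n1) + 3.0 * linear_decode(rfs, n2)
        assert np.allclose(lhs, rhs)

    def test_undefined_rf_for_spiking_unit_rejected(self):
        rfs = [ReceptiveField(np.ones(4), 5), ReceptiveField(None, 0)]
        counts = np.array([[1.0, 2.0]])
        with pytest.raises(ValidationError):
            linear_decode(rfs, counts)

    def test_lsq_gain_rescales_optimally(self):
        rng = np.random.default_rng(11)
        rfs = rng.normal(0, 1, (4, 9))
        counts = rng.poisson(1.0, (50, 4)).astype(float)
        X = 2.5 * linear_decode(rfs, counts)
        gain = fit_decoder_gain(rfs, counts, X)
        assert gain == pytest.approx(2.5)


class TestReconstructImage:
    def test_identity_codec_round_trip(self):
        rng = np.random.default_rng(12)
        image = rng.normal(0, 2.0, (24, 24)) + 1.5
        out = reconstruct_image(image, None, 8, codec=lambda z: z)
        assert np.allclose(out, image, atol=1e-12)

    def test_silent_network_reconstructs_patch_means(self):
        rng = np.random.default_rng(13)
        image = rng.normal(0, 1, (16, 16)) + 3.0
        n = 4
        params = NetworkParams(
            np.zeros((n, 64)), np.zeros((n, n)), np.full(n, 10.0)
        )
        out = reconstruct_image(image, params, 8)
        for r in (0, 8):
            for c in (0, 8):
                tile = image[r : r + 8, c : c + 8]
                assert np.allclose(out[r : r + 8, c : c + 8], tile.mean())

    def test_crop_warns(self):
        image = np.random.default_rng(14).normal(0, 1, (19, 21))
        with pytest.warns(UserWarning, match="cropping"):
            out = reconstruct_image(image, None, 8, codec=lambda z: z)
        assert out.shape == (16, 16)

    def test_too_small_image_rejected(self):
        with pytest.raises(ShapeError):
            reconstruct_image(np.zeros((4, 4)), None, 8, codec=lambda z: z)
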