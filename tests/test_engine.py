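"""Tests for segmentation and forward/backward posterior decoding."""

import numpy as np
import pytest

from gammasmc.core_model import GammaState, Observation
from gammasmc.engine import (
    TERM_CAP,
    TERM_END,
    TERM_HET,
    TERM_TARGET,
    backward_pass,
    decode_pair,
    forward_pass,
    segment_observations,
)
from gammasmc.synthetic_data import simulate_smc_pair

THETA = 0.00075
RHO = 0.0006

HOM, HET, MISS = (int(Observation.HOM), int(Observation.HET), int(Observation.MISSING))


class TestSegmentation:
    def test_basic_het_cut(self):
        obs = np.array([HOM, HOM, HET, HOM, HOM], dtype=np.uint8)
        segs = segment_observations(obs, [], max_len=10)
        assert list(segs.ends) == [3, 5]
        assert list(segs.terminal_kind) == [TERM_HET, TERM_END]
        assert list(segs.n_hom) == [2, 1]
        assert list(segs.n_missing) == [0, 0]

    def test_length_cap_splits_long_hom_run(self):
        obs = np.zeros(25_000, dtype=np.uint8)
        segs = segment_observations(obs, [], max_len=10_000)
        assert list(segs.ends) == [10_000, 20_000, 25_000]
        assert list(segs.terminal_kind) == [TERM_CAP, TERM_CAP, TERM_END]

    def test_mask_gap_counts(self):
        obs = np.zeros(100, dtype=np.uint8)
        obs[10:30] = MISS
        segs = segment_observations(obs, [], max_len=1000)
        assert segs.n_missing[0] == 20
        assert segs.n_hom[0] == 100 - 20 - 1  # terminal bp excluded from runs

    def test_targets_cut_and_are_indexed(self):
        obs = np.zeros(50, dtype=np.uint8)
        obs[30] = HET
        segs = segment_observations(obs, [10, 30, 45], max_len=1000)
        assert list(segs.ends) == [11, 31, 46, 50]
        # a het that is also a target keeps target identity
        assert segs.terminal_kind[1] == TERM_TARGET
        assert list(segs.target_index[:3]) == [0, 1, 2]

    def test_segments_tile_without_gaps(self):
        rng = np.random.default_rng(3)
        obs = rng.choice([HOM, HET, MISS], size=5000, p=[0.97, 0.02, 0.01]).astype(np.uint8)
        segs = segment_observations(obs, [100, 2500, 4999], max_len=700)
        assert segs.starts[0] == 0
        assert segs.ends[-1] == 5000
        assert np.array_equal(segs.starts[1:], segs.ends[:-1])
        assert np.all(segs.ends - segs.starts <= 700)
        assert np.all(segs.n_missing + segs.n_hom == segs.ends - segs.starts - 1)

    def test_unsorted_targets_raise(self):
        with pytest.raises(ValueError):
            segment_observations(np.zeros(10, dtype=np.uint8), [5, 2])


class TestForwardPass:
    def test_all_missing_returns_prior(self, grid, cache):
        # stays at the stationary prior up to time-grid discretization bias
        obs = np.full(400, MISS, dtype=np.uint8)
        segs = segment_observations(obs, [100, 399], max_len=2000)
        states = forward_pass(segs, cache, grid, THETA)
        for s in states:
            assert s.mean == pytest.approx(1.0, abs=5e-3)
            assert s.cv == pytest.approx(1.0, abs=5e-3)

    def test_conjugate_closed_form_at_zero_rho(self, grid0, cache0):
        rng = np.random.default_rng(5)
        obs = (rng.random(1200) < 0.02).astype(np.uint8)
        k = int(obs.sum())
        segs = segment_observations(obs, [1199], max_len=500)
        state = forward_pass(segs, cache0, grid0, THETA)[0]
        assert state.alpha == pytest.approx(1 + k, abs=1e-6)
        assert state.beta == pytest.approx(1 + 1200 * THETA, abs=1e-6)

    def test_cache_mismatch_raises(self, grid, cache):
        segs = segment_observations(np.zeros(10, dtype=np.uint8), [5], max_len=100)
        with pytest.raises(ValueError):
            forward_pass(segs, cache, grid, THETA * 3)


class TestBackwardPass:
    def test_all_missing_returns_prior(self, grid, cache):
        obs = np.full(300, MISS, dtype=np.uint8)
        segs = segment_observations(obs, [0, 150, 299], max_len=2000)
        for s in backward_pass(segs, cache, grid, THETA):
            assert s.mean == pytest.approx(1.0, abs=5e-3)

    def test_conjugacy_on_downstream_observations(self, grid0, cache0):
        rng = np.random.default_rng(11)
        obs = (rng.random(1000) < 0.02).astype(np.uint8)
        p = 400
        k_after = int(obs[p + 1:].sum())
        n_after = len(obs) - p - 1
        segs = segment_observations(obs, [p], max_len=500)
        state = backward_pass(segs, cache0, grid0, THETA)[0]
        assert state.alpha == pytest.approx(1 + k_after, abs=1e-6)
        assert state.beta == pytest.approx(1 + n_after * THETA, abs=1e-6)

    def test_palindrome_symmetry(self, grid, cache):
        half = np.zeros(250, dtype=np.uint8)
        half[[20, 90, 200]] = HET
        obs = np.concatenate([half, half[::-1]])
        L = len(obs)
        center = L // 2 - 1  # forward at center covers obs[:250]
        segs = segment_observations(obs, [center], max_len=2000)
        fwd = forward_pass(segs, cache, grid, THETA)[0]
        # backward at position 249 conditions on obs[250:] = reverse of
        # obs[:250]; it equals the forward state pushed through one extra
        # transition
        bwd = backward_pass(segs, cache, grid, THETA)[0]
        from gammasmc.flow_field import apply_flow
        expect = apply_flow(grid, fwd)
        assert bwd.l_mu == pytest.approx(expect.l_mu, abs=1e-9)
        assert bwd.l_cv == pytest.approx(expect.l_cv, abs=1e-9)


class TestDecodePair:
    def test_single_het_raises_posterior_mean(self, grid, cache, params):
        obs = np.full(41, MISS, dtype=np.uint8)
        obs[20] = HET
        track = decode_pair(obs, [20], params, cache, grid)
        assert track.mean_coal[0] > 1.0

    def test_long_hom_run_lowers_posterior_mean(self, grid, cache, params):
        obs = np.zeros(1500, dtype=np.uint8)
        track = decode_pair(obs, [750], params, cache, grid, max_len=2000)
        assert track.mean_coal[0] < 1.0

    def test_zero_rho_decoder_reproduces_conjugate_posterior(self, grid0, cache0, params0):
        rng = np.random.default_rng(2)
        obs = (rng.random(900) < 0.02).astype(np.uint8)
        k, n = int(obs.sum()), len(obs)
        track = decode_pair(obs, [450], params0, cache0, grid0, max_len=500)
        assert track.alpha[0] == pytest.approx(1 + k, abs=1e-6)
        assert track.beta[0] == pytest.approx(1 + n * THETA, abs=1e-6)

    def test_determinism(self, grid, cache, params):
        sim = simulate_smc_pair(100_000, THETA, RHO, seed=4)
        targets = np.arange(500, 100_000, 5_000)
        a = decode_pair(sim.obs, targets, params, cache, grid, max_len=2000)
        b = decode_pair(sim.obs, targets, params, cache, grid, max_len=2000)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.mean_generations, b.mean_generations)

    def test_combined_equals_sum_rule_when_proper(self, grid, cache, params):
        sim = simulate_smc_pair(200_000, THETA, RHO, seed=9)
        targets = np.arange(500, 200_000, 10_000)
        tr = decode_pair(sim.obs, targets, params, cache, grid, max_len=2000)
        proper = (tr.fwd_alpha + tr.bwd_alpha - 1.0) >= 0.01
        assert proper.any()
        assert np.allclose(tr.alpha[proper],
                           (tr.fwd_alpha + tr.bwd_alpha - 1)[proper])
        assert np.allclose(tr.beta[proper],
                           (tr.fwd_beta + tr.bwd_beta - 1)[proper])

    def test_posterior_tracks_truth_on_simulated_pair(self, grid, cache, params):
        # decoder recovery on this package's own SMC-kernel simulator; the
        # discretized exact-posterior ceiling on such data is r^2 ~ 0.54
        sim = simulate_smc_pair(4_000_000, THETA, RHO, seed=12)
        targets = np.arange(500, 4_000_000, 1_000)
        tr = decode_pair(sim.obs, targets, params, cache, grid, max_len=2000)
        truth = sim.tmrca_at(targets)
        r2 = np.corrcoef(truth, tr.mean_coal)[0, 1] ** 2
        assert r2 > 0.4

    def test_calibration_of_central_interval(self, grid, cache, params):
        # ~50% of true TMRCAs should fall in the central 50% credible interval
        from scipy import stats

        sim = simulate_smc_pair(4_000_000, THETA, RHO, seed=21)
        targets = np.arange(500, 4_000_000, 1_000)
        tr = decode_pair(sim.obs, targets, params, cache, grid, max_len=2000)
        truth = sim.tmrca_at(targets)
        lo = stats.gamma.ppf(0.25, tr.alpha, scale=1 / tr.beta)
        hi = stats.gamma.ppf(0.75, tr.alpha, scale=1 / tr.beta)
        cover = ((truth >= lo) & (truth <= hi)).mean()
        assert 0.35 < cover < 0.65

    def test_scale_robustness_rank_correlation(self, grid, cache, params):
        # data simulated with 100x smaller TMRCAs, decoded with unchanged
        # parameters: estimates must still rank-correlate with truth
        from scipy import stats

        sim = simulate_smc_pair(4_000_000, THETA, RHO, scale=0.01, seed=3)
        targets = np.arange(500, 4_000_000, 1_000)
        tr = decode_pair(sim.obs, targets, params, cache, grid, max_len=2000)
        truth = sim.tmrca_at(targets)
        rho_s = stats.spearmanr(truth, tr.mean_coal).statistic
        assert rho_s > 0
        # and the inferred scale is small (well below the prior mean)
        assert np.median(tr.mean_coal) < 0.1
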