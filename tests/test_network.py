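"""LIF dynamics, network construction, and trace-STDP correctness."""

import numpy as np
import pytest
from scipy import stats

from stdpmem import (
    LIFParams,
    LIFState,
    Profile,
    STDPConfig,
    SpikeTrains,
    build_network,
    make_pattern,
    run,
    step,
    tile_pattern,
)
from stdpmem.protocols import train

from conftest import quiet_params


class TestBuildNetwork:
    def test_connection_count_within_binomial_interval(self):
        net = build_network(50, 50, 0.2, seed=11)
        lo, hi = stats.binom.interval(0.999, 2500, 0.2)
        assert lo <= net.n_connections <= hi

    def test_degenerate_build_is_fully_connected_uniform(self):
        net = build_network(10, 10, 1.0, w_mean=0.5, w_sd=0.0, seed=1)
        assert net.mask.all()
        assert (net.W == 0.5).all()

    def test_same_seed_same_network(self):
        a = build_network(30, 30, 0.2, seed=4)
        b = build_network(30, 30, 0.2, seed=4)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.W, b.W)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            build_network(0, 10)
        with pytest.raises(ValueError):
            build_network(10, 10, p_connect=0.0)
        with pytest.raises(ValueError):
            build_network(10, 10, w_sd=-1.0)

    def test_weights_clipped_into_bounds(self):
        net = build_network(40, 40, 1.0, w_mean=0.95, w_sd=0.5, seed=2)
        on = net.W[net.mask]
        assert on.min() >= 0.0 and on.max() <= 1.0


class TestStep:
    def test_resting_state_is_fixed_point(self, tiny_network):
        p = tiny_network.params
        s = LIFState.resting(3, p)
        for _ in range(50):
            s, spk = step(s, p, np.zeros(4), tiny_network)
            assert spk.sum() == 0
        np.testing.assert_allclose(s.V, p.E_L)

    def test_conductance_decay_one_step(self, tiny_network):
        p = tiny_network.params
        s = LIFState(V=np.full(3, p.E_L), g=np.full(3, 0.12))
        s2, _ = step(s, p, np.zeros(4), tiny_network)
        np.testing.assert_allclose(s2.g, 0.12 * (1 - 1 / 3), atol=1e-12)

    def test_voltage_step_uses_previous_conductance(self, tiny_network):
        # dV = g_L*0 + g*(E_syn - E_L) = 0.12 * 60 with the pre-step g
        p = tiny_network.params
        s = LIFState(V=np.full(3, p.E_L), g=np.full(3, 0.12))
        s2, _ = step(s, p, np.zeros(4), tiny_network)
        np.testing.assert_allclose(s2.V, -57.8, atol=1e-12)

    def test_threshold_crossing_spikes_and_resets(self, tiny_network):
        p = tiny_network.params
        # far enough above threshold that one step of leak cannot rescue it
        s = LIFState(V=np.full(3, p.E_threshold + 15.0), g=np.zeros(3))
        s2, spk = step(s, p, np.zeros(4), tiny_network)
        assert spk.tolist() == [1, 1, 1]
        np.testing.assert_allclose(s2.V, p.E_L)

    def test_nan_state_is_fatal(self, tiny_network):
        s = LIFState(V=np.array([np.nan, -65.0, -65.0]), g=np.zeros(3))
        with pytest.raises(FloatingPointError):
            step(s, tiny_network.params, np.zeros(4), tiny_network)

    def test_epsp_amplitude_linear_in_weight(self):
        """First-felt voltage deflection scales exactly with the weight;
        the full EPSP peak stays proportional to good accuracy."""
        deflect, peaks = {}, {}
        for w in (0.25, 0.5):
            net = build_network(
                1, 1, 1.0, w_mean=w, w_sd=0.0, seed=1, params=quiet_params()
            )
            p = net.params
            s = LIFState.resting(1, p)
            s, _ = step(s, p, np.ones(1), net)  # spike arrives: g loads
            s, _ = step(s, p, np.zeros(1), net)  # first voltage response
            deflect[w] = s.V[0] - p.E_L
            vmax = s.V[0]
            for _ in range(20):
                s, _ = step(s, p, np.zeros(1), net)
                vmax = max(vmax, s.V[0])
            peaks[w] = vmax - p.E_L
        assert deflect[0.5] / deflect[0.25] == pytest.approx(2.0, abs=1e-9)
        assert peaks[0.5] / peaks[0.25] == pytest.approx(2.0, rel=0.1)


class TestRun:
    def test_frozen_run_never_touches_weights(self):
        net = build_network(20, 20, 0.3, seed=5)
        pat = make_pattern(20, 100, seed=6)
        w_before = net.W.copy()
        _, after, _ = run(net, tile_pattern(pat, 20), plastic=False, seed=7)
        np.testing.assert_array_equal(net.W, w_before)
        np.testing.assert_array_equal(after.W, w_before)

    def test_silent_noiseless_run_is_silent(self):
        net = build_network(10, 10, 0.5, seed=1, params=quiet_params())
        silent = SpikeTrains(raster=np.zeros((10, 500), dtype=np.uint8))
        out, after, _ = run(net, silent, plastic=True, seed=2)
        assert out.spike_count() == 0
        np.testing.assert_array_equal(after.W, net.W)

    def test_run_is_deterministic_under_seed(self):
        net = build_network(30, 30, 0.2, seed=9)
        pat = make_pattern(30, 100, seed=10)
        tiled = tile_pattern(pat, 30)
        out1, net1, _ = run(net, tiled, plastic=True, seed=42)
        out2, net2, _ = run(net, tiled, plastic=True, seed=42)
        np.testing.assert_array_equal(out1.raster, out2.raster)
        np.testing.assert_array_equal(net1.W, net2.W)

    def test_weight_bounds_and_mask_preserved_by_plastic_run(self):
        net = build_network(30, 30, 0.2, seed=13)
        pat = make_pattern(30, 100, seed=14)
        _, after, _ = run(net, tile_pattern(pat, 100), plastic=True, seed=15)
        on = after.W[after.mask]
        assert on.min() >= 0.0 and on.max() <= 1.0
        assert (after.W[~after.mask] == 0.0).all()

    def test_matches_stepwise_integration_without_noise(self):
        """The compiled loop and the reference step() agree exactly."""
        net = build_network(8, 6, 0.6, seed=3, params=quiet_params())
        rng = np.random.default_rng(4)
        raster = (rng.random((8, 300)) < 0.05).astype(np.uint8)
        out, _, _ = run(net, SpikeTrains(raster=raster), plastic=False, seed=5)
        s = LIFState.resting(6, net.params)
        expected = np.zeros((6, 300), dtype=np.uint8)
        for t in range(300):
            s, spk = step(s, net.params, raster[:, t], net)
            expected[:, t] = spk
        np.testing.assert_array_equal(out.raster, expected)

    def test_snapshots_cover_requested_times(self):
        net = build_network(10, 10, 0.5, seed=1)
        pat = make_pattern(10, 100, seed=2)
        _, _, snaps = run(
            net, tile_pattern(pat, 10), plastic=True, seed=3,
            snapshot_every_ms=250.0,
        )
        assert sorted(snaps) == [250.0, 500.0, 750.0, 1000.0]

    def test_mismatched_raster_rejected(self):
        net = build_network(10, 10, 0.5, seed=1)
        bad = SpikeTrains(raster=np.zeros((9, 100), dtype=np.uint8))
        with pytest.raises(ValueError):
            run(net, bad)


def all_pairs_oracle(net, pre_raster, post_raster):
    """Direct double loop over spike pairs, applied in event order.

    At each postsynaptic spike the LTP contributions of all strictly
    earlier presynaptic spikes are summed and applied with the current
    weight; at each presynaptic spike the LTD contributions of all
    post spikes at the same step or earlier are applied.  Clipping
    after every event.  This is the all-to-all pairing the trace
    mechanism implements.
    """
    s = net.stdp
    W = net.W.copy()
    n_in, T = pre_raster.shape
    pre_times = [np.flatnonzero(pre_raster[i]) for i in range(n_in)]
    post_times = [np.flatnonzero(post_raster[j]) for j in range(net.n_out)]

    def eps(w, ltp):
        a = s.effective_alpha
        ar = (1.0 - w) if ltp else w
        return a * 2.0 * min(1.0 - w, w) + (1 - a) * ar

    for t in range(T):
        for j in range(net.n_out):  # LTP at post spikes
            if post_raster[j, t]:
                for i in range(n_in):
                    if not net.mask[i, j]:
                        continue
                    lags = t - pre_times[i][pre_times[i] < t]
                    if lags.size:
                        k = np.exp(-lags / s.tau_plus).sum()
                        W[i, j] = np.clip(
                            W[i, j] + eps(W[i, j], True) * s.k_plus * k, 0, 1
                        )
        for i in range(n_in):  # LTD at pre spikes (coincidence included)
            if pre_raster[i, t]:
                for j in range(net.n_out):
                    if not net.mask[i, j]:
                        continue
                    lags = t - post_times[j][post_times[j] <= t]
                    if lags.size:
                        k = np.exp(-lags / s.tau_minus).sum()
                        W[i, j] = np.clip(
                            W[i, j] + eps(W[i, j], False) * s.k_minus * k, 0, 1
                        )
    return W


class TestTraceEqualsAllPairs:
    @pytest.mark.parametrize("profile", [Profile.AR, Profile.SR, Profile.HYBRID])
    def test_sparse_raster_matches_oracle(self, profile):
        # threshold just below E_syn: voltage can never cross, so the
        # postsynaptic spikes are exactly the imposed ones
        params = quiet_params(E_threshold=-6.0)
        stdp = STDPConfig(profile=profile, alpha=0.37)
        net = build_network(
            3, 2, 1.0, w_mean=0.5, w_sd=0.0, seed=1, params=params, stdp=stdp
        )
        rng = np.random.default_rng(8)
        T = 120
        pre = (rng.random((3, T)) < 0.03).astype(np.uint8)
        post = (rng.random((2, T)) < 0.03).astype(np.uint8)
        assert pre.sum() + post.sum() <= 20
        _, after, _ = run(
            net,
            SpikeTrains(raster=pre),
            plastic=True,
            seed=2,
            forced_output=SpikeTrains(raster=post),
        )
        expected = all_pairs_oracle(net, pre, post)
        np.testing.assert_allclose(after.W, expected, atol=1e-12)

    def test_dense_raster_matches_oracle(self):
        params = quiet_params(E_threshold=-6.0)
        net = build_network(
            4, 3, 1.0, w_mean=0.5, w_sd=0.0, seed=3,
            params=params, stdp=STDPConfig(profile=Profile.SR),
        )
        rng = np.random.default_rng(12)
        T = 400
        pre = (rng.random((4, T)) < 0.05).astype(np.uint8)
        post = (rng.random((3, T)) < 0.05).astype(np.uint8)
        _, after, _ = run(
            net, SpikeTrains(raster=pre), plastic=True, seed=4,
            forced_output=SpikeTrains(raster=post),
        )
        np.testing.assert_allclose(
            after.W, all_pairs_oracle(net, pre, post), atol=1e-10
        )


class TestTrainingEffect:
    def test_repeated_pattern_drives_weights_bimodal(self):
        """Pattern training saturates part of the weights at the bounds."""
        for profile in (Profile.AR, Profile.SR):
            net = build_network(50, 50, 0.2, seed=21, stdp=STDPConfig(profile=profile))
            pat = make_pattern(50, 100, seed=22)
            before = net.W[net.mask]
            frac_before = ((before < 0.1) | (before > 0.9)).mean()
            trained = train(net, pat, 100.0, seed=23)
            w = trained.W[trained.mask]
            frac_after = ((w < 0.1) | (w > 0.9)).mean()
            assert frac_after > frac_before + 0.3
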