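"""Circular–linear correlation, Hilbert phase, surrogate null, FDR and
preferred-phase estimation, each against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deltaseg.phase import (
    circ_lin_corr,
    estimate_preferred_phase,
    fdr_bh,
    fisher_z,
    group_phase_amplitude_test,
    hilbert_phase,
    surrogate_null,
    PhaseMap,
)

from conftest import make_epochs


def grid_oracle_r(theta, x, n_grid=10_000):
    """max over a phase grid of |corr(x, cos(theta - phi))| — the defining
    variational property of the circular-linear correlation."""
    phis = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    c = np.cos(theta[None, :] - phis[:, None])
    c = c - c.mean(axis=1, keepdims=True)
    xc = x - x.mean()
    num = c @ xc
    den = np.sqrt((c**2).sum(axis=1) * (xc**2).sum())
    return np.abs(num / den).max()


class TestCircLinCorr:
    def test_perfect_cosine_coupling_gives_r_one(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 64)
        for phi in (0.0, 1.3, -2.4):
            assert circ_lin_corr(theta, np.cos(theta - phi)) == pytest.approx(
                1.0, abs=1e-10)

    def test_independent_data_gives_small_r(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 10_000)
        x = rng.standard_normal(10_000)
        assert circ_lin_corr(theta, x) < 0.05

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(-np.pi, np.pi, 50)
        x = rng.standard_normal(50)
        r = circ_lin_corr(theta, x)
        assert r == pytest.approx(grid_oracle_r(theta, x), abs=1e-4)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-3, 3),
           st.floats(0.1, 10), st.floats(-5, 5))
    def test_rotation_and_affine_invariance(self, seed, rot, a, b):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(-np.pi, np.pi, 40)
        x = rng.standard_normal(40) + 0.5 * np.cos(theta)
        r0 = circ_lin_corr(theta, x)
        r_rot = circ_lin_corr(theta + rot, x)
        r_aff = circ_lin_corr(theta, a * x + b)
        assert r_rot == pytest.approx(r0, abs=1e-9)
        assert r_aff == pytest.approx(r0, abs=1e-9)

    def test_constant_x_degenerate(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 20)
        with pytest.warns(RuntimeWarning):
            assert np.isnan(circ_lin_corr(theta, np.full(20, 2.0)))

    def test_degenerate_phases(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(circ_lin_corr(np.zeros(10), np.arange(10.0)))


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493061443, abs=1e-9)

    def test_monotone(self, rng):
        r = np.sort(rng.uniform(0, 0.99, 50))
        z = fisher_z(r)
        assert (np.diff(z) > 0).all()

    def test_r_one_flagged_infinite(self):
        with pytest.warns(RuntimeWarning):
            assert np.isinf(fisher_z(1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(-0.1)
        with pytest.raises(ValueError):
            fisher_z(1.2)


class TestHilbertPhase:
    def test_unwrapped_phase_slope_of_one_hz_cosine(self):
        rate = 100.0
        t = np.arange(600) / rate
        ep = make_epochs(np.cos(2 * np.pi * t)[None, None, :].copy(), rate,
                         tmin=0.0)
        pm = hilbert_phase(ep)
        interior = slice(50, 550)
        slope = np.polyfit(t[interior],
                           np.unwrap(pm.data[0, 0])[interior], 1)[0]
        assert slope == pytest.approx(2 * np.pi, abs=0.01)

    def test_sine_lags_cosine_by_half_pi(self):
        rate = 100.0
        t = np.arange(600) / rate
        f = 1.0
        data = np.stack([np.cos(2 * np.pi * f * t),
                         np.sin(2 * np.pi * f * t)])[:, None, :]
        pm = hilbert_phase(make_epochs(data, rate, tmin=0.0))
        mid = slice(100, 500)
        diff = np.angle(np.exp(1j * (pm.data[0, 0, mid] - pm.data[1, 0, mid])))
        assert np.allclose(diff, np.pi / 2, atol=0.02)

    def test_slow_oscillation_phase_offset_recovered_at_origin(self):
        # 0.37 Hz cosine, +-3 s epoch: phase at t=0 must match the offset
        rate = 100.0
        t = np.arange(600) / rate - 3.0
        for psi in np.linspace(-3, 3, 7):
            data = np.cos(2 * np.pi * 0.37 * t + psi)[None, None, :]
            pm = hilbert_phase(make_epochs(data.copy(), rate, tmin=-3.0))
            i0 = pm.data.shape[2] // 2
            err = np.angle(np.exp(1j * (pm.data[0, 0, i0] - psi)))
            assert abs(err) < 0.05

    def test_nan_rejected(self):
        data = np.full((1, 1, 600), np.nan)
        with pytest.raises(ValueError):
            hilbert_phase(make_epochs(data, 100.0))

    def test_rate_mismatch_warns(self):
        ep = make_epochs(np.random.default_rng(0).standard_normal((1, 1, 600)),
                         250.0)
        with pytest.warns(RuntimeWarning, match="expected 100"):
            hilbert_phase(ep)


class TestSurrogateNull:
    def test_identity_convention_reproduces_observed(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 50)
        x = np.cos(theta - 0.4) + rng.standard_normal(50)
        null = surrogate_null(theta, x, n_perm=20, seed=0,
                              include_identity=True)
        observed = fisher_z(circ_lin_corr(theta, x))
        assert null[0] == pytest.approx(observed, abs=1e-12)

    def test_constant_amplitude_degenerate(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 20)
        with pytest.warns(RuntimeWarning):
            null = surrogate_null(theta, np.ones(20), n_perm=10, seed=0)
        assert np.isnan(null).all()

    def test_strong_coupling_beats_entire_null(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            theta = rng.uniform(-np.pi, np.pi, 200)
            x = 4.0 * np.cos(theta - 1.0) + rng.standard_normal(200)
            null = surrogate_null(theta, x, n_perm=1000, seed=seed)
            observed = fisher_z(circ_lin_corr(theta, x))
            hits += observed > null.max()
        assert hits >= 19

    def test_same_shuffle_shared_across_cells(self, rng):
        theta = rng.uniform(-np.pi, np.pi, (30, 4))
        x = rng.standard_normal(30)
        # a duplicated cell must produce an identical null column
        theta[:, 3] = theta[:, 0]
        null = surrogate_null(theta, x, n_perm=50, seed=1)
        assert np.allclose(null[:, 0], null[:, 3])

    def test_null_p_uniform_under_no_coupling(self):
        # KS test over 200 seeded datasets at a single cell, alpha = 0.01
        from scipy.stats import kstest

        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            theta = rng.uniform(-np.pi, np.pi, 50)
            x = rng.standard_normal(50)
            null = surrogate_null(theta, x, n_perm=200, seed=seed)
            obs = fisher_z(circ_lin_corr(theta, x))
            pvals.append((1 + (null >= obs).sum()) / (1 + len(null)))
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestFdrBH:
    def test_step_up_worked_example(self):
        # hand-computed: with m=15 and q=0.05 the largest k satisfying
        # p_(k) <= k q / m is k=1 (0.001 <= 0.0033; 0.008 > 0.0067), so only
        # the smallest p is rejected; at q=0.25 the largest such k is 7
        # (0.074 <= 7*0.25/15 = 0.1167) and the first seven are rejected
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205,
                      0.212, 0.216, 0.222, 0.251, 0.269, 0.275, 0.34])
        mask, cutoff = fdr_bh(p, q=0.05)
        assert mask.sum() == 1 and mask[0]
        assert cutoff == pytest.approx(0.001)
        mask25, cutoff25 = fdr_bh(p, q=0.25)
        assert mask25.sum() == 7 and mask25[:7].all()
        assert cutoff25 == pytest.approx(0.074)

    def test_all_ones_empty_mask(self):
        mask, cutoff = fdr_bh(np.ones(10), 0.05)
        assert not mask.any() and cutoff == 0.0

    def test_all_zeros_all_rejected(self):
        mask, _ = fdr_bh(np.zeros(10), 0.05)
        assert mask.all()

    def test_empty_input(self):
        mask, cutoff = fdr_bh(np.array([]), 0.05)
        assert mask.size == 0 and cutoff == 0.0


class TestPreferredPhase:
    def test_exact_cosine_recovers_phi(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 100)
        assert estimate_preferred_phase(theta, np.cos(theta - 1.0)) == \
            pytest.approx(1.0, abs=1e-8)

    def test_noisy_recovery_snr_one(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            theta = rng.uniform(-np.pi, np.pi, 500)
            x = np.cos(theta - 0.7) + np.sqrt(0.5) * rng.standard_normal(500)
            est = estimate_preferred_phase(theta, x)
            hits += abs(np.angle(np.exp(1j * (est - 0.7)))) < 0.2
        assert hits >= 19

    @pytest.mark.parametrize("seed", range(10))
    def test_closed_form_matches_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(-np.pi, np.pi, 60)
        x = rng.standard_normal(60) + np.cos(theta - 0.3)
        phis = np.linspace(-np.pi, np.pi, 10_000, endpoint=False)
        c = np.cos(theta[None, :] - phis[:, None])
        c = c - c.mean(axis=1, keepdims=True)
        xc = x - x.mean()
        corr = (c @ xc) / np.sqrt((c**2).sum(axis=1) * (xc**2).sum())
        assert estimate_preferred_phase(theta, x) == pytest.approx(
            phis[np.argmax(corr)], abs=2 * np.pi / 10_000 + 1e-9)


class TestGroupTest:
    def _phase_maps(self, rng, n_part=4, n_trials=60, n_ch=2, n_t=5,
                    coupled=True):
        maps, amps = [], []
        for _ in range(n_part):
            theta = rng.uniform(-np.pi, np.pi, (n_trials, n_ch, n_t))
            amp = rng.standard_normal(n_trials)
            if coupled:
                theta[:, 0, 2] = np.arccos(
                    np.clip(amp / np.abs(amp).max(), -1, 1))
            maps.append(PhaseMap(data=theta, rate=10.0, tmin=-0.2,
                                 ch_names=tuple(f"E{i:02d}" for i in range(n_ch))))
            amps.append(amp)
        return maps, amps

    def test_plus_one_floor_on_strong_coupling(self, rng):
        maps, amps = self._phase_maps(rng)
        res = group_phase_amplitude_test(maps, amps, window=(-0.2, 0.2),
                                         n_perm=50, q=0.05, seed=0)
        assert res.p.min() == pytest.approx(1 / 51)

    def test_few_trial_participants_dropped(self, rng):
        maps, amps = self._phase_maps(rng, n_part=3)
        maps[1].data = maps[1].data[:3]
        amps[1] = amps[1][:3]
        with pytest.warns(RuntimeWarning, match="dropped"):
            res = group_phase_amplitude_test(maps, amps, window=(-0.2, 0.2),
                                             n_perm=20, seed=0)
        assert res.n_participants == 2

    def test_all_dropped_raises(self, rng):
        maps, amps = self._phase_maps(rng, n_part=1)
        maps[0].data = maps[0].data[:2]
        amps[0] = amps[0][:2]
        with pytest.raises(ValueError):
            with pytest.warns(RuntimeWarning):
                group_phase_amplitude_test(maps, amps, window=(-0.2, 0.2),
                                           n_perm=20, seed=0)
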