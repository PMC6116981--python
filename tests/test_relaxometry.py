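"""T1 two-point fit, field mapping, TE_max rule and T2* fit tests."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

import mriwater as mw
from mriwater.relaxometry import ProtocolError, FieldGradientMap


def make_trains(t1, b1plus=1.0, m0=70.0, t2star=50.0, delta_f=None, noise=0.0, seed=0,
                grid=(1, 1, 1)):
    """Simulate matched low/high echo trains for given truth values."""
    ones = np.ones(grid)
    spec = mw.PhantomSpec(
        voxel_size=(1, 1, 1),
        h2o_true=ones * m0,
        t1_true=ones * t1,
        t2star_true=ones * t2star,
        b1plus_true=ones * b1plus,
        b1minus_true=ones,
        delta_f_true=None if delta_f is None else ones * delta_f,
        noise_sigma=noise,
        seed=seed,
    )
    low = mw.simulate_megre(spec, mw.MEGRE_LOW, seed=seed)
    high = mw.simulate_megre(spec, mw.MEGRE_HIGH, seed=seed + 1)
    return spec, low, high


class TestFitT1TwoPoint:
    def test_noiseless_recovery_is_exact(self):
        spec, low, high = make_trains(t1=1000.0)
        t1map = mw.fit_t1_two_point(low, high, spec.b1plus_true)
        assert t1map.t1.flat[0] == pytest.approx(1000.0, abs=0.1)

    @pytest.mark.parametrize("t1,b1", [(200.0, 0.7), (988.0, 1.0), (2500.0, 1.3), (5500.0, 0.9)])
    def test_exact_over_parameter_range(self, t1, b1):
        spec, low, high = make_trains(t1=t1, b1plus=b1)
        t1map = mw.fit_t1_two_point(low, high, spec.b1plus_true)
        assert t1map.t1.flat[0] == pytest.approx(t1, abs=0.1)

    def test_random_draws_property(self, rng):
        t1s = rng.uniform(200, 5500, 15)
        b1s = rng.uniform(0.7, 1.3, 15)
        for t1, b1 in zip(t1s, b1s):
            spec, low, high = make_trains(t1=t1, b1plus=b1)
            t1map = mw.fit_t1_two_point(low, high, spec.b1plus_true)
            assert t1map.t1.flat[0] == pytest.approx(t1, abs=0.1)

    def test_estimate_increases_with_true_t1(self):
        estimates = []
        for t1 in (500.0, 1000.0, 2000.0, 4000.0):
            spec, low, high = make_trains(t1=t1)
            estimates.append(mw.fit_t1_two_point(low, high, spec.b1plus_true).t1.flat[0])
        assert np.all(np.diff(estimates) > 0)

    def test_long_t1_clipped_to_six_seconds(self):
        spec, low, high = make_trains(t1=8000.0)
        t1map = mw.fit_t1_two_point(low, high, spec.b1plus_true)
        assert t1map.t1.flat[0] == 6000.0
        assert t1map.clipped_mask.flat[0]

    def test_mismatched_te_lists_raise(self):
        spec, low, _ = make_trains(t1=1000.0)
        other = mw.AcquisitionProtocol(
            tr=50.0, flip_nominal=40.0, te_list=mw.default_te_list(18, te1=3.0)
        )
        high = mw.EchoTrainVolume(magnitude=low.magnitude.copy(), protocol=other)
        with pytest.raises(ProtocolError):
            mw.fit_t1_two_point(low, high, spec.b1plus_true)

    def test_zero_signal_voxel_invalid(self):
        spec, low, high = make_trains(t1=1000.0, grid=(1, 1, 2))
        low.magnitude[0, 0, 1] = 0.0
        high.magnitude[0, 0, 1] = 0.0
        t1map = mw.fit_t1_two_point(low, high, spec.b1plus_true)
        assert t1map.valid_mask[0, 0, 0]
        assert not t1map.valid_mask[0, 0, 1]
        assert np.isnan(t1map.t1[0, 0, 1])

    def test_matches_grid_search_oracle_on_noisy_voxels(self, rng):
        # brute-force 0.1 ms grid search over [1, 6000] ms as the oracle
        n = 200
        t1s = rng.uniform(300, 4000, n)
        spec, low, high = make_trains(t1=1000.0, grid=(1, 1, n), noise=0.02, seed=9)
        # overwrite truth with per-voxel T1 and regenerate
        spec.t1_true[0, 0, :] = t1s
        low = mw.simulate_megre(spec, mw.MEGRE_LOW, seed=9)
        high = mw.simulate_megre(spec, mw.MEGRE_HIGH, seed=10)
        t1map = mw.fit_t1_two_point(low, high, spec.b1plus_true)

        te = low.protocol.te_list[:3]
        s1 = low.magnitude[0, 0, :, :3]
        s2 = high.magnitude[0, 0, :, :3]
        ss11 = (s1 * s1).sum(-1)
        ss12 = (s1 * s2).sum(-1)
        ss22 = (s2 * s2).sum(-1)
        candidates = np.arange(1.0, 6000.0 + 0.05, 0.1)
        best = np.full(n, np.inf)
        best_t1 = np.zeros(n)
        for chunk in np.array_split(candidates, 60):
            e = np.exp(-50.0 / chunk)
            c1 = np.sin(np.deg2rad(7.0)) * (1 - e) / (1 - e * np.cos(np.deg2rad(7.0)))
            c2 = np.sin(np.deg2rad(40.0)) * (1 - e) / (1 - e * np.cos(np.deg2rad(40.0)))
            obj = (
                ss11[:, None] / c1[None, :] ** 2
                - 2 * ss12[:, None] / (c1 * c2)[None, :]
                + ss22[:, None] / c2[None, :] ** 2
            )
            idx = np.argmin(obj, axis=1)
            vals = obj[np.arange(n), idx]
            better = vals < best
            best = np.where(better, vals, best)
            best_t1 = np.where(better, chunk[idx], best_t1)
        np.testing.assert_allclose(t1map.t1[0, 0, :], best_t1, atol=0.1)


class TestFieldMap:
    def make_phase_train(self, delta_f, grid=(2, 2, 2)):
        spec, low, _ = make_trains(t1=1000.0, delta_f=delta_f, grid=grid)
        return low

    def test_zero_phase_gives_zero_field(self):
        low = self.make_phase_train(0.0)
        fm = mw.fieldmap_from_phase(low)
        np.testing.assert_allclose(fm.delta_f, 0.0, atol=1e-10)

    def test_recovers_uniform_field(self):
        fm = mw.fieldmap_from_phase(self.make_phase_train(30.0))
        np.testing.assert_allclose(fm.delta_f, 30.0, atol=1e-8)

    def test_unwraps_beyond_two_echo_nyquist(self):
        # 1/(2 dTE) = 196 Hz at dTE = 2.55 ms; 250 Hz aliases in the echo pair
        fm = mw.fieldmap_from_phase(self.make_phase_train(250.0))
        np.testing.assert_allclose(fm.delta_f, 250.0, atol=1e-6)

    def test_missing_phase_raises_with_guidance(self):
        spec, low, _ = make_trains(t1=1000.0)
        low.phase = None
        with pytest.raises(ValueError, match="field map"):
            mw.fieldmap_from_phase(low)


class TestTeMax:
    def test_zero_gradient_gives_infinite_bound(self):
        fm = FieldGradientMap(delta_f=np.zeros((6, 6, 6)))
        out = mw.compute_te_max(fm, (1, 1, 1))
        assert np.all(np.isinf(out.te_max))
        spec, low, _ = make_trains(t1=1000.0, grid=(6, 6, 6))
        t2map = mw.fit_t2star(low, te_max=out)
        assert np.all(t2map.n_echoes_used == 18)

    def test_bound_restricts_echoes_to_first_seven(self):
        # linear ramp along x: gradient G with 2 q / (G d) = 20 ms
        # -> only echoes with TE < 20 ms (echoes 1..7 of the default train)
        shape = (8, 4, 4)
        d = 1.0  # mm
        g = 2 * 0.5 / (0.020 * d)  # Hz/mm, so te_max = 20 ms
        x = np.arange(shape[0])[:, None, None] * d
        fm = mw.compute_te_max(
            FieldGradientMap(delta_f=np.broadcast_to(g * x, shape).copy()), (d, d, d)
        )
        inner = fm.te_max[1:-1]  # central differences are exact away from borders
        np.testing.assert_allclose(inner, 20.0, rtol=1e-9)
        te = mw.MEGRE_LOW.te_list
        assert int(np.sum(te < 20.0)) == 7

    def test_extreme_gradient_floors_at_minimum_echoes(self):
        shape = (6, 4, 4)
        x = np.arange(shape[0])[:, None, None] * 1.0
        fm = mw.compute_te_max(
            FieldGradientMap(delta_f=np.broadcast_to(500.0 * x, shape).copy()), (1, 1, 1)
        )
        spec, low, _ = make_trains(t1=1000.0, grid=shape)
        t2map = mw.fit_t2star(low, te_max=fm)
        assert np.all(t2map.n_echoes_used[1:-1] == 3)
        assert t2map.floored_mask[1:-1].all()


class TestFitT2Star:
    def test_exact_on_noiseless_decay(self):
        te = mw.MEGRE_LOW.te_list
        mag = (100.0 * np.exp(-te / 50.0))[None, None, None, :]
        vol = mw.EchoTrainVolume(magnitude=mag, protocol=mw.MEGRE_LOW)
        t2map = mw.fit_t2star(vol)
        assert t2map.t2star.flat[0] == pytest.approx(50.0, rel=1e-12)
        assert t2map.s0.flat[0] == pytest.approx(100.0, rel=1e-12)

    def test_constant_signal_clipped_at_limit(self):
        mag = np.full((1, 1, 1, 18), 42.0)
        vol = mw.EchoTrainVolume(magnitude=mag, protocol=mw.MEGRE_LOW)
        t2map = mw.fit_t2star(vol)
        assert t2map.t2star.flat[0] == 1500.0
        assert t2map.clipped_mask.flat[0]

    def test_all_zero_voxel_invalid(self):
        mag = np.zeros((1, 1, 1, 18))
        vol = mw.EchoTrainVolume(magnitude=mag, protocol=mw.MEGRE_LOW)
        t2map = mw.fit_t2star(vol)
        assert not t2map.valid_mask.flat[0]
        assert np.isnan(t2map.t2star.flat[0])

    def test_matches_nonlinear_least_squares_on_noiseless(self, rng):
        te = mw.MEGRE_LOW.te_list
        for _ in range(20):
            s0, t2 = rng.uniform(20, 200), rng.uniform(20, 400)
            mag = (s0 * np.exp(-te / t2))[None, None, None, :]
            vol = mw.EchoTrainVolume(magnitude=mag, protocol=mw.MEGRE_LOW)
            fit = mw.fit_t2star(vol)
            popt, _ = curve_fit(
                lambda t, a, b: a * np.exp(-t / b), te, mag[0, 0, 0], p0=(s0 * 1.3, t2 * 0.7)
            )
            assert fit.s0.flat[0] == pytest.approx(popt[0], rel=1e-6)
            assert fit.t2star.flat[0] == pytest.approx(popt[1], rel=1e-6)

    def test_weighting_reduces_variance_vs_unweighted(self, rng):
        # heteroscedastic (Rician-like) noise: weighted fit beats plain log fit
        te = mw.MEGRE_LOW.te_list
        n = 1000
        s0, t2 = 100.0, 40.0
        clean = s0 * np.exp(-te / t2)
        noisy = np.abs(
            clean[None, :] + 2.0 * rng.standard_normal((n, te.size))
            + 1j * 2.0 * rng.standard_normal((n, te.size))
        )
        vol = mw.EchoTrainVolume(magnitude=noisy[None, None], protocol=mw.MEGRE_LOW)
        t2_w = mw.fit_t2star(vol).t2star[0, 0]
        t2_u = np.empty(n)
        for i in range(n):  # unweighted log-linear oracle
            slope, _ = np.polyfit(te, np.log(noisy[i]), 1)
            t2_u[i] = -1.0 / slope
        assert np.var(t2_w) <= np.var(t2_u)

    def test_cutoff_reduces_dephasing_bias(self):
        # strong through-voxel gradient: late echoes are sinc-attenuated;
        # restricting to TE < TE_max must shrink the T2* bias
        shape = (8, 4, 4)
        ones = np.ones(shape)
        g = 25.0  # Hz/mm across 1 mm voxels
        x = np.arange(shape[0])[:, None, None] * 1.0
        spec = mw.PhantomSpec(
            voxel_size=(1, 1, 1), h2o_true=ones * 70, t1_true=ones * 1000,
            t2star_true=ones * 50, b1plus_true=ones, b1minus_true=ones,
            delta_f_true=np.broadcast_to(g * x, shape).copy(),
        )
        low = mw.simulate_megre(spec, mw.MEGRE_LOW)
        fm = mw.compute_te_max(mw.fieldmap_from_phase(low), spec.voxel_size)
        inner = (slice(1, -1), slice(None), slice(None))
        err_with = np.abs(mw.fit_t2star(low, te_max=fm).t2star - 50.0)[inner]
        err_without = np.abs(mw.fit_t2star(low).t2star - 50.0)[inner]
        assert err_with.mean() < err_without.mean()

    def test_cutoff_never_hurts_noiseless_clean_data(self):
        spec, low, _ = make_trains(t1=1000.0, grid=(4, 4, 4))
        fm = FieldGradientMap(delta_f=np.zeros((4, 4, 4)))
        fm = mw.compute_te_max(fm, (1, 1, 1))
        err_with = np.abs(mw.fit_t2star(low, te_max=fm).t2star - 50.0)
        err_without = np.abs(mw.fit_t2star(low).t2star - 50.0)
        assert np.all(err_with <= err_without + 1e-12)
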