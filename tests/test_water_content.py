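"""M0 correction, receive-bias estimation, CSF normalisation and error propagation."""

import warnings

import numpy as np
import pytest

import mriwater as mw
from mriwater.relaxometry import T1Map, T2StarMap
from mriwater.water_content import correct_m0, estimate_receive_bias


def maps_from_truth(spec):
    """Wrap the phantom's ground-truth maps as fitted-map objects."""
    ones = np.ones(spec.shape, dtype=bool)
    t1map = T1Map(
        t1=spec.t1_true, residual=np.zeros(spec.shape),
        clipped_mask=~ones, valid_mask=ones,
    )
    t2map = T2StarMap(
        t2star=spec.t2star_true, s0=spec.h2o_true, n_echoes_used=np.full(spec.shape, 18),
        clipped_mask=~ones, valid_mask=ones,
    )
    return t1map, t2map


class TestCorrectM0:
    def test_unit_corrections_give_echo_average(self):
        mag = np.stack([np.full((2, 2, 2), v) for v in (10.0, 8.0, 6.0, 4.0)], axis=-1)
        proto = mw.AcquisitionProtocol(tr=1e9, flip_nominal=90.0,
                                       te_list=np.array([1.0, 2.0, 3.0, 4.0]))
        vol = mw.EchoTrainVolume(magnitude=mag, protocol=proto)
        ones = np.ones((2, 2, 2))
        # TR >> T1 at 90 deg: the saturation factor is exactly 1
        t1map = T1Map(t1=ones * 1.0, residual=ones * 0, clipped_mask=ones < 0,
                      valid_mask=ones > 0)
        t2map = T2StarMap(t2star=ones * 1e12, s0=ones, n_echoes_used=ones,
                          clipped_mask=ones < 0, valid_mask=ones > 0)
        m0 = correct_m0(vol, t2map, t1map, ones, b1minus=ones)
        np.testing.assert_allclose(m0.m0, (10 + 8 + 6) / 3, rtol=1e-9)
        assert m0.corrections_applied == frozenset({"T2*", "T1B1a", "B1-"})

    def test_inverts_forward_model_with_true_maps(self):
        bp = mw.make_brain_phantom(grid=(24, 24, 24), delta_f_amplitude=0.0)
        spec = bp.spec
        low = mw.simulate_megre(spec, mw.MEGRE_LOW, seed=1)
        t1map, t2map = maps_from_truth(spec)
        m0 = correct_m0(low, t2map, t1map, spec.b1plus_true, b1minus=spec.b1minus_true)
        m = bp.brain_mask
        rel = np.abs(m0.m0[m] - spec.h2o_true[m]) / spec.h2o_true[m]
        assert rel.max() < 1e-6

    def test_degenerate_t2star_marks_voxel_invalid(self):
        spec, _ = mw.make_tube_phantom(grid=(4, 4, 4), ring_radius=0.0,
                                       h2o_levels=[80.0], t1_levels=[1000.0], tube_radius=50.0)
        low = mw.simulate_megre(spec, mw.MEGRE_LOW)
        t1map, t2map = maps_from_truth(spec)
        t2map.t2star = t2map.t2star.copy()
        t2map.t2star[0, 0, 0] = 0.0
        m0 = correct_m0(low, t2map, t1map, np.ones(spec.shape), b1minus=np.ones(spec.shape))
        assert not m0.valid_mask[0, 0, 0]
        assert np.isnan(m0.m0[0, 0, 0])
        assert m0.valid_mask[1, 1, 1]


class TestReceiveBias:
    def test_unbiased_input_yields_unit_field(self):
        bp = mw.make_brain_phantom(grid=(32, 32, 32), b1minus_amplitude=0.0,
                                   delta_f_amplitude=0.0)
        spec = bp.spec
        low = mw.simulate_megre(spec, mw.MEGRE_LOW, seed=1)
        t1map, t2map = maps_from_truth(spec)
        partial = correct_m0(low, t2map, t1map, spec.b1plus_true, b1minus=None)
        field = estimate_receive_bias(partial, bp.brain_mask)
        assert np.abs(field[bp.brain_mask] - 1.0).max() < 0.01

    def test_recovers_known_polynomial_field(self, brain48, brain48_maps):
        bp, low, high = brain48
        t1map, t2map = brain48_maps
        partial = correct_m0(low, t2map, t1map, bp.spec.b1plus_true, b1minus=None)
        field = estimate_receive_bias(partial, bp.brain_mask)
        m = bp.brain_mask
        truth = bp.spec.b1minus_true / bp.spec.b1minus_true[m].mean()
        rms = float(np.sqrt(np.mean((field[m] - truth[m]) ** 2)))
        assert rms < 0.02

    def test_empty_mask_raises(self):
        bp = mw.make_brain_phantom(grid=(8, 8, 8))
        low = mw.simulate_megre(bp.spec, mw.MEGRE_LOW)
        t1map, t2map = maps_from_truth(bp.spec)
        partial = correct_m0(low, t2map, t1map, bp.spec.b1plus_true)
        with pytest.raises(ValueError, match="empty"):
            estimate_receive_bias(partial, np.zeros(bp.spec.shape, dtype=bool))


class TestNormalisationMask:
    def make_maps(self, t1_val, t2_val, shape=(4, 4, 4)):
        arr = np.ones(shape, dtype=bool)
        t1map = T1Map(t1=np.full(shape, t1_val), residual=np.zeros(shape),
                      clipped_mask=~arr, valid_mask=arr)
        t2map = T2StarMap(t2star=np.full(shape, t2_val), s0=np.ones(shape),
                          n_echoes_used=np.full(shape, 18), clipped_mask=~arr, valid_mask=arr)
        return t1map, t2map

    def test_qualifying_voxel_included(self):
        t1map, t2map = self.make_maps(3000.0, 600.0)
        rule = mw.NormalisationRule()
        mask = mw.csf_normalization_mask(np.full((4, 4, 4), 0.995), t1map, t2map, rule)
        assert mask.all()

    @pytest.mark.parametrize(
        "prob,t1,t2", [(0.95, 3000.0, 600.0), (0.995, 2800.0, 600.0), (0.995, 3000.0, 450.0)]
    )
    def test_each_threshold_excludes(self, prob, t1, t2):
        t1map, t2map = self.make_maps(t1, t2)
        with pytest.raises(ValueError, match="empty"):
            mw.csf_normalization_mask(
                np.full((4, 4, 4), prob), t1map, t2map, mw.NormalisationRule()
            )

    def test_ellipsoid_restricts_mask(self):
        shape = (10, 10, 10)
        t1map, t2map = self.make_maps(3000.0, 600.0, shape)
        ell = mw.Ellipsoid(center=(0.0, 0.0, 0.0), semi_axes=(2.0, 2.0, 2.0))
        rule = mw.NormalisationRule(ellipsoid=ell)
        aff = mw.geometry.affine_from_voxel_size((1, 1, 1), shape)
        mask = mw.csf_normalization_mask(np.full(shape, 1.0), t1map, t2map, rule, affine=aff)
        assert mask.any() and not mask.all()
        x, y, z = mw.geometry.world_coordinates(shape, aff)
        assert not mask[(x**2 + y**2 + z**2) > 4.0**2].any()


class TestNormalizeH2O:
    def make_m0(self, data, valid=None):
        valid = np.ones_like(data, dtype=bool) if valid is None else valid
        return mw.M0Map(m0=data, corrections_applied=frozenset({"T2*", "T1B1a", "B1-"}),
                        valid_mask=valid)

    def test_uniform_map_normalises_to_hundred(self):
        m0 = self.make_m0(np.full((3, 3, 3), 7.3))
        h2o = mw.normalize_h2o(m0, np.ones((3, 3, 3), dtype=bool))
        np.testing.assert_allclose(h2o.h2o, 100.0)
        assert h2o.c_norm == pytest.approx(100 / 7.3)

    def test_mask_mean_is_exactly_hundred(self, rng):
        data = rng.uniform(5, 15, (6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.5
        h2o = mw.normalize_h2o(self.make_m0(data), mask)
        assert float(np.mean(h2o.h2o[mask])) == pytest.approx(100.0, abs=1e-10)

    def test_invariant_under_global_signal_scaling(self, rng):
        data = rng.uniform(5, 15, (5, 5, 5))
        mask = np.ones((5, 5, 5), dtype=bool)
        a = mw.normalize_h2o(self.make_m0(data), mask)
        b = mw.normalize_h2o(self.make_m0(data * 1234.5), mask)
        np.testing.assert_allclose(a.h2o, b.h2o, rtol=1e-12)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            mw.normalize_h2o(self.make_m0(np.ones((2, 2, 2))),
                             np.zeros((2, 2, 2), dtype=bool))


class TestLongTr:
    def make_spec(self, h2o_levels, t1_levels):
        spec, masks = mw.make_tube_phantom(h2o_levels=h2o_levels, t1_levels=t1_levels,
                                           grid=(32, 32, 8), ring_radius=20.0)
        return spec, masks

    def test_noiseless_long_tr_recovers_truth(self):
        # all T1 well below TR/5: saturation negligible
        spec, masks = self.make_spec([60, 75, 90, 100], [600, 800, 1000, 1200])
        vol = mw.simulate_megre(spec, mw.LONG_TR_REFERENCE)
        h2o = mw.h2o_long_tr(vol, masks[-1])
        for m, truth in zip(masks, (60, 75, 90, 100)):
            assert np.nanmean(h2o.h2o[m]) == pytest.approx(truth, abs=0.1)

    def test_short_tr_shows_saturation_bias(self):
        spec, masks = self.make_spec([60, 75, 90, 100], [600, 800, 1000, 1200])
        proto = mw.AcquisitionProtocol(tr=50.0, flip_nominal=90.0,
                                       te_list=mw.LONG_TR_REFERENCE.te_list)
        vol = mw.simulate_megre(spec, proto)
        with pytest.warns(UserWarning, match="saturation"):
            h2o = mw.h2o_long_tr(vol, masks[-1])
        # T1 differences between tubes are no longer corrected: visible bias
        assert abs(np.nanmean(h2o.h2o[masks[0]]) - 60.0) > 2.0

    def test_uniform_water_phantom_reads_hundred_everywhere(self):
        spec, masks = self.make_spec([100], [1000])
        vol = mw.simulate_megre(spec, mw.LONG_TR_REFERENCE)
        h2o = mw.h2o_long_tr(vol, masks[0])
        np.testing.assert_allclose(h2o.h2o[masks[0]], 100.0, atol=0.1)


class TestPropagateT1Error:
    def test_zero_error_propagates_to_zero(self):
        assert mw.propagate_t1_error(1000.0, 0.0, 7.0, 50.0) == 0.0

    def test_matches_finite_difference(self):
        t1, flip, tr = 1000.0, 7.0, 50.0
        h = 1e-3
        c = mw.signal_model.t1_correction_factor
        fd = abs(np.log(c(t1 + h, tr, flip)) - np.log(c(t1 - h, tr, flip))) / (2 * h)
        analytic = mw.propagate_t1_error(t1, 1.0, flip, tr)
        assert analytic == pytest.approx(fd, rel=1e-6)

    def test_monotone_in_delta_t1(self):
        errs = [mw.propagate_t1_error(1000.0, d, 7.0, 50.0) for d in (10, 50, 100)]
        assert errs[0] < errs[1] < errs[2]

    def test_larger_flip_angle_amplifies_t1_sensitivity(self):
        low = mw.propagate_t1_error(1000.0, 50.0, 7.0, 50.0)
        high = mw.propagate_t1_error(1000.0, 50.0, 40.0, 50.0)
        assert high > low
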