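import numpy as np
import pytest

from dnadapt.dn_model import (CategoryScaling, DNParams, csdn_forward,
                              dn_forward, dn_forward_batch, exp_decay,
                              gamma_irf, linear_response)
from dnadapt.trial_design import CATEGORIES, StimulusTimecourse
from dnadapt.summary_metrics import (compute_recovery_curve, time_to_peak)
from dnadapt.synthetic import AREAS, area_presets

from conftest import FS, brute_force_convolve


class TestKernels:
    @pytest.mark.parametrize("tau1", [0.02, 0.05, 0.1])
    def test_gamma_irf_peaks_at_tau1(self, tau1):
        k = gamma_irf(tau1, FS)
        assert abs(np.argmax(k) / FS - tau1) <= 1.0 / FS
        assert k.sum() == pytest.approx(1.0)

    def test_gamma_irf_scaling_symmetry(self):
        assert np.argmax(gamma_irf(0.04, FS)) == \
            pytest.approx(np.argmax(gamma_irf(0.08, FS)) / 2, abs=1)

    def test_gamma_irf_short_support_raises(self):
        with pytest.raises(ValueError, match="truncates"):
            gamma_irf(0.05, FS, support_s=0.25)   # 5 tau -> ~4% tail mass

    def test_exp_decay_shape(self):
        tau2 = 0.1
        k = exp_decay(tau2, FS)
        assert np.argmax(k) == 0
        assert k.sum() == pytest.approx(1.0)
        raw = exp_decay(tau2, FS, normalize=False)
        assert np.all(np.diff(raw) < 0)
        ratios = raw[1:] / raw[:-1]
        np.testing.assert_allclose(ratios, np.exp(-1 / (tau2 * FS)),
                                   rtol=1e-12)


class TestLinearResponse:
    def test_zero_and_impulse(self):
        zero = StimulusTimecourse(FS, 0, np.zeros(200))
        assert not np.any(linear_response(zero, 0.05))
        imp = StimulusTimecourse(FS, 0, np.r_[1.0, np.zeros(999)])
        k = gamma_irf(0.05, FS)
        expected = np.zeros(1000)
        expected[:k.size] = k
        np.testing.assert_allclose(linear_response(imp, 0.05), expected,
                                   atol=1e-14)

    def test_linearity_and_brute_force_equivalence(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 300)
        stim = StimulusTimecourse(FS, 0, x)
        k = gamma_irf(0.01, FS)
        fast = linear_response(stim, 0.01)
        np.testing.assert_allclose(fast, brute_force_convolve(x, k),
                                   atol=1e-10)
        doubled = linear_response(StimulusTimecourse(FS, 0, 2 * x), 0.01)
        np.testing.assert_allclose(doubled, 2 * fast, rtol=1e-12)


class TestDNForward:
    def test_zero_stimulus_zero_prediction(self):
        stim = StimulusTimecourse(FS, 0, np.zeros(400))
        p = DNParams(0.05, 0.1, 2.0, 0.5)
        assert not np.any(dn_forward(stim, p).values)

    @pytest.mark.parametrize("sigma,n", [(1.0, 2.0), (0.5, 1.5), (2.0, 3.0)])
    def test_sustained_steady_state_closed_form(self, sigma, n):
        # unit-sum kernels make the late-time value scale/(1 + sigma^n)
        stim = StimulusTimecourse(FS, 0, np.ones(int(6 * FS)))
        p = DNParams(0.05, 0.1, n, sigma, shift=0.0, scale=1.7)
        r = dn_forward(stim, p).values
        assert r[-1] == pytest.approx(1.7 / (1 + sigma ** n), abs=1e-3)

    def test_prediction_nonnegative_and_transient_exceeds_plateau(self):
        stim = StimulusTimecourse(FS, 0, np.ones(int(4 * FS)))
        for area in AREAS:
            r = dn_forward(stim, area_presets()[area]).values
            assert np.all(r >= 0)
            assert r.max() > r[-1]   # transient-sustained shape

    def test_shift_delays_output(self):
        stim = StimulusTimecourse(FS, 0, np.ones(600))
        p0 = DNParams(0.02, 0.05, 2.0, 0.5, shift=0.0)
        k = 24
        p1 = DNParams(0.02, 0.05, 2.0, 0.5, shift=k / FS)
        r0, r1 = dn_forward(stim, p0).values, dn_forward(stim, p1).values
        assert not np.any(r1[:k])
        np.testing.assert_allclose(r1[k:], r0[:-k], rtol=1e-12)
        # fractional shifts interpolate between neighbouring sample delays
        p_half = DNParams(0.02, 0.05, 2.0, 0.5, shift=(k + 0.5) / FS)
        r_half = dn_forward(stim, p_half).values
        r_next = dn_forward(stim, DNParams(0.02, 0.05, 2.0, 0.5,
                                           shift=(k + 1) / FS)).values
        np.testing.assert_allclose(r_half, 0.5 * (r1 + r_next), rtol=1e-12)

    def test_components_on_request(self):
        stim = StimulusTimecourse(FS, 0, np.ones(300))
        out = dn_forward(stim, DNParams(0.02, 0.05, 2.0, 0.5), True)
        assert set(out.components) == {"linear", "input_drive",
                                       "normalization_pool"}

    def test_invalid_params_rejected(self):
        for bad in [dict(tau1=-1), dict(sigma=0), dict(shift=-0.01),
                    dict(n=0)]:
            kw = dict(tau1=0.05, tau2=0.1, n=2.0, sigma=0.5, shift=0.0,
                      scale=1.0)
            kw.update(bad)
            with pytest.raises(ValueError):
                DNParams(**kw)


class TestCsDN:
    def test_sf_one_matches_dn(self, stimuli):
        stim = stimuli[("duration", 4)]
        p = DNParams(0.03, 0.1, 2.0, 0.1)
        cs = CategoryScaling.uniform(1.0)
        np.testing.assert_array_equal(
            csdn_forward(stim, p, cs, "faces").values,
            dn_forward(stim, p).values)

    def test_sf_zero_silences(self, stimuli):
        cs = CategoryScaling({c: 0.0 if c == "faces" else 1.0
                              for c in CATEGORIES})
        out = csdn_forward(stimuli[("duration", 4)],
                           DNParams(0.03, 0.1, 2.0, 0.1), cs, "faces")
        assert not np.any(out.values)

    def test_unknown_category_lists_valid(self, stimuli):
        with pytest.raises(KeyError, match="bodies"):
            csdn_forward(stimuli[("duration", 4)],
                         DNParams(0.03, 0.1, 2.0, 0.1),
                         CategoryScaling.uniform(), "houses")

    def test_auc_strictly_increases_with_sf(self, stimuli):
        stim = stimuli[("duration", 5)]
        p = DNParams(0.03, 0.1, 2.0, 0.5)
        aucs = []
        for sf in (0.5, 1.0, 2.0, 4.0):
            cs = CategoryScaling.uniform(sf)
            aucs.append(csdn_forward(stim, p, cs, "faces").values.sum())
        assert np.all(np.diff(aucs) > 0)

    def test_gauge_invariance_sf_sigma(self, stimuli):
        # (sf, sigma) -> (a*sf, a*sigma) leaves the prediction unchanged
        stim = stimuli[("repetition", 2)]
        p = DNParams(0.03, 0.1, 1.7, 0.2)
        cs = CategoryScaling.uniform(0.8)
        a = 2.5
        p2 = DNParams(0.03, 0.1, 1.7, 0.2 * a)
        cs2 = CategoryScaling.uniform(0.8 * a)
        a_vals = csdn_forward(stim, p, cs, "scenes").values
        b_vals = csdn_forward(stim, p2, cs2, "scenes").values
        np.testing.assert_allclose(a_vals, b_vals,
                                   atol=1e-10 * a_vals.max())


class TestBatchPath:
    def test_batch_matches_per_condition(self, stimuli):
        p = DNParams(0.03, 0.12, 1.8, 0.1, shift=0.04, scale=2.0)
        sf = np.array([0.5, 0.8, 1.0, 1.3, 2.0, 4.0])
        cs = CategoryScaling.from_vector(sf)
        keys = sorted(stimuli)
        mat = np.stack([stimuli[k].values for k in keys])
        batch = dn_forward_batch(mat, FS, p, sf)
        for i, cat in enumerate(CATEGORIES):
            for j, key in enumerate(keys):
                ref = csdn_forward(stimuli[key], p, cs, cat).values
                np.testing.assert_allclose(batch[i, j], ref, atol=1e-10)


class TestEmergentDynamics:
    def test_repetition_suppression_and_isi_recovery(self, stimuli,
                                                     onset_index):
        for area in AREAS:
            p = area_presets()[area]
            rep = {lv: dn_forward(stimuli[("repetition", lv)], p).values
                   for lv in range(6)}
            d134 = dn_forward(stimuli[("duration", 3)], p).values
            curve = compute_recovery_curve(rep, d134, FS, onset_index)
            assert np.all(curve.recovery <= 1.0 + 1e-9)       # suppression
            assert np.all(np.diff(curve.recovery) >= -1e-9)   # recovery

    def test_larger_tau1_later_peak(self, stimuli, onset_index):
        stim = stimuli[("duration", 5)]
        peaks = [time_to_peak(dn_forward(stim, DNParams(t1, 0.1, 2.0, 0.1)
                                         ).values, FS, onset_index)
                 for t1 in (0.02, 0.05, 0.1)]
        assert np.all(np.diff(peaks) > 0)

    def test_larger_n_deeper_decay(self, stimuli):
        # post-peak decay (plateau/peak ratio) deepens as n grows
        stim = stimuli[("duration", 5)]
        ratios = []
        for n in (1.2, 1.8, 2.4, 3.0):
            r = dn_forward(stim, DNParams(0.03, 0.1, n, 0.5)).values
            off = stim.pulses[0][1]
            ratios.append(r[off - 1] / r.max())
        assert np.all(np.diff(ratios) < 0)
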