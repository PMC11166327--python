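import numpy as np
import pytest

from dnadapt.dn_model import dn_forward
from dnadapt.summary_metrics import (RecoveryCurve, compute_recovery_curve,
                                     estimate_second_response,
                                     fit_recovery_curve, fwhm,
                                     overall_adaptation, recovery_ratio,
                                     time_to_peak)
from dnadapt.synthetic import area_presets
from dnadapt.trial_design import canonical_isis

from conftest import FS


class TestTimeToPeak:
    def test_basic_and_translation_invariance(self):
        tc = np.zeros(500)
        tc[100] = 1.0
        assert time_to_peak(tc, FS, 0) == pytest.approx(100 / FS)
        shifted = np.r_[np.zeros(40), tc]
        assert time_to_peak(shifted, FS, 40) == pytest.approx(100 / FS)

    def test_tie_goes_to_earlier_peak(self):
        tc = np.zeros(100)
        tc[[20, 60]] = 3.0
        assert time_to_peak(tc, FS, 0) == pytest.approx(20 / FS)

    def test_flat_raises(self):
        with pytest.raises(ValueError):
            time_to_peak(np.ones(50), FS, 0)


class TestFWHM:
    @pytest.mark.parametrize("k", [20, 31, 50])
    def test_symmetric_triangle_half_base(self, k):
        rise = np.arange(k + 1) / k
        tri = np.r_[np.zeros(5), rise, rise[::-1][1:], np.zeros(5)]
        assert fwhm(tri, FS) == pytest.approx(k / FS, rel=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        tc = np.convolve(rng.uniform(0, 1, 200), np.ones(20) / 20, "same")
        assert fwhm(5 * tc, FS) == pytest.approx(fwhm(tc, FS))

    def test_monotone_rise_is_undefined(self):
        assert np.isnan(fwhm(np.linspace(0, 1, 100), FS))

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            fwhm(np.zeros(10), FS)


class TestSecondResponse:
    def _template_setup(self, onset_index=51):
        # repetition responses equal to the 134 ms response before the
        # second onset make the template exactly the 134 ms time course
        T = 900
        rng = np.random.default_rng(2)
        dur134 = np.convolve(rng.uniform(0, 1, T), np.ones(30) / 30, "same")
        return T, dur134, onset_index

    def test_recovers_known_additive_bump(self, onset_index):
        T, dur134, oi = self._template_setup()
        isis = [float(x) for x in canonical_isis()]
        rep, bumps = {}, {}
        ests_probe = estimate_second_response(
            {lv: dur134 for lv in range(6)}, dur134, FS, oi, isis)
        for lv in range(6):
            o2 = ests_probe[lv].second_onset_index
            bump = np.zeros(T)
            bump[o2:o2 + 100] = np.hanning(100)
            rep[lv] = dur134 + bump
            bumps[lv] = bump
        ests = estimate_second_response(rep, dur134, FS, oi, isis)
        for lv in range(6):
            np.testing.assert_allclose(ests[lv].second_response, bumps[lv],
                                       atol=1e-8)

    def test_identical_to_template_gives_zero(self, onset_index):
        T, dur134, oi = self._template_setup()
        ests = estimate_second_response({lv: dur134 for lv in range(6)},
                                        dur134, FS, oi)
        for est in ests.values():
            np.testing.assert_allclose(est.second_response, 0.0, atol=1e-12)
            assert not np.any(est.second_response[:est.second_onset_index])

    def test_misaligned_lengths_raise(self, onset_index):
        T, dur134, oi = self._template_setup()
        rep = {lv: dur134 for lv in range(6)}
        rep[3] = dur134[:-1]
        with pytest.raises(ValueError, match="misaligned"):
            estimate_second_response(rep, dur134, FS, oi)


class TestRecoveryRatio:
    def _est(self, first, second, o1=0, o2=0):
        from dnadapt.summary_metrics import SecondResponseEstimate
        return SecondResponseEstimate(FS, first, second, 0.1, o1, o2)

    def test_identical_and_scaled_and_zero(self):
        first = np.r_[np.zeros(10), np.hanning(100), np.zeros(10)]
        assert recovery_ratio(self._est(first, first)) == pytest.approx(1.0)
        assert recovery_ratio(self._est(first, 0.5 * first)) == \
            pytest.approx(0.5)
        assert recovery_ratio(self._est(first, np.zeros_like(first))) == 0.0

    def test_zero_first_auc_raises(self):
        with pytest.raises(ValueError):
            recovery_ratio(self._est(np.zeros(50), np.ones(50)))

    def test_ratio_invariant_to_common_rescaling(self):
        first = np.r_[np.zeros(10), np.hanning(100), np.zeros(10)]
        second = 0.7 * first
        r1 = recovery_ratio(self._est(first, second))
        r2 = recovery_ratio(self._est(first * 13, second * 13))
        assert r1 == pytest.approx(r2)


class TestRecoveryCurveFit:
    def test_exact_log_linear_fit(self):
        x = np.array([float(v) for v in canonical_isis()])
        y = 0.9 + 0.1 * np.log(x)
        c, a = fit_recovery_curve(x, y)
        assert c == pytest.approx(0.9, abs=1e-10)
        assert a == pytest.approx(0.1, abs=1e-10)
        # evaluated at 1 s the fit returns c
        assert c + a * np.log(1.0) == pytest.approx(c)

    def test_constant_recovery(self):
        x = [0.1, 0.2, 0.4, 0.8]
        c, a = fit_recovery_curve(x, [0.7] * 4)
        assert c == pytest.approx(0.7) and a == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_isis_raise(self):
        with pytest.raises(ValueError):
            fit_recovery_curve([0.5, 0.5], [1, 1])
        with pytest.raises(ValueError):
            fit_recovery_curve([-1, 0.5], [1, 1])


class TestOverallAdaptation:
    def test_mean_and_permutation_invariance(self):
        isi = np.array([float(v) for v in canonical_isis()])
        curve = RecoveryCurve(isi, np.array([0, 0, 0, 0, 0, 1.0]))
        assert overall_adaptation(curve) == pytest.approx(1 / 6)
        curve2 = RecoveryCurve(isi, np.array([1.0, 0, 0, 0, 0, 0]))
        assert overall_adaptation(curve2) == pytest.approx(1 / 6)
        ones = RecoveryCurve(isi, np.ones(6))
        assert overall_adaptation(ones) == 1.0


class TestAreaOrdering:
    def test_presets_order_peak_latency_and_long_term_recovery(
            self, stimuli, onset_index):
        presets = area_presets()
        ttps, cs = [], []
        for area in ("V1V3like", "VOTClike", "LOTClike"):
            p = presets[area]
            r533 = dn_forward(stimuli[("duration", 5)], p).values
            ttps.append(time_to_peak(r533, FS, onset_index))
            rep = {lv: dn_forward(stimuli[("repetition", lv)], p).values
                   for lv in range(6)}
            d134 = dn_forward(stimuli[("duration", 3)], p).values
            cs.append(compute_recovery_curve(rep, d134, FS,
                                             onset_index).c)
        assert ttps[0] < ttps[1] < ttps[2]
        assert cs[0] > cs[1] > cs[2]
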