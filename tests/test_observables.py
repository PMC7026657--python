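"""Linear CD response, topology signature rule, peak integration."""

import numpy as np
import pytest

from quadkin import (
    CDCoefficients,
    FoldTopology,
    cd_signal,
    integrate_peak,
    predict_cd_signature,
    solve_populations,
)
from quadkin.kinetics import StateTrajectory


def _traj(times, states):
    return StateTrajectory(np.asarray(times, float), np.asarray(states, float))


class TestCDSignal:
    def test_baseline_only(self):
        traj = _traj([1, 2, 3], [[1, 0, 0, 0]] * 3)
        tr = cd_signal(traj, CDCoefficients(wavelength=265, baseline=7.0))
        np.testing.assert_array_equal(tr.signal, [7.0, 7.0, 7.0])

    def test_pure_g4i_channel_rises_then_decays(self, wt22m_rates):
        # With only c_B active the trace is B(t): a fast build-up on the
        # hairpin-unfolding scale, then slow drainage into G4(II).
        times = np.geomspace(0.5, 600, 300)
        traj = solve_populations(wt22m_rates, times=times)
        tr = cd_signal(traj, CDCoefficients(wavelength=265, c_b=1.0))
        np.testing.assert_allclose(tr.signal, traj.B)
        peak = times[np.argmax(tr.signal)]
        assert peak < 30
        assert tr.signal[-1] < 0.6 * tr.signal.max()

    def test_dual_channel_qualitative_pattern(self, wt22m_rates):
        # 265 nm: rapid growth then slow decay; 290/295 nm: slow growth.
        times = np.arange(1.0, 601.0)
        traj = solve_populations(wt22m_rates, times=times)
        tr265 = cd_signal(traj, CDCoefficients(wavelength=265, c_b=1.0, c_c=0.2))
        tr295 = cd_signal(traj, CDCoefficients(wavelength=295, c_b=0.1, c_c=1.0))
        i_peak = np.argmax(tr265.signal)
        assert times[i_peak] < 30 and tr265.signal[-1] < tr265.signal[i_peak]
        assert np.all(np.diff(tr295.signal[int(times[i_peak]):]) > -1e-12)

    def test_linearity_in_populations(self, wt22m_rates, rng):
        times = np.linspace(1, 100, 20)
        coeff = CDCoefficients(wavelength=265, c_a=0.5, c_b=2.0, c_c=-1.0, c_d=0.3)
        x = rng.random((20, 4))
        y = rng.random((20, 4))
        a, b = 0.7, 1.9
        sig = lambda s: cd_signal(_traj(times, s), coeff).signal
        np.testing.assert_allclose(
            sig(a * x + b * y) - coeff.baseline,
            a * (sig(x) - coeff.baseline) + b * (sig(y) - coeff.baseline),
            atol=1e-12,
        )

    def test_nonstandard_wavelength_warns(self):
        with pytest.warns(UserWarning):
            CDCoefficients(wavelength=222.0)


class TestCDSignature:
    def test_uniform_directionality_gives_265_band(self):
        topo = FoldTopology("WT22m-T4", ("clockwise",) * 3)
        assert predict_cd_signature(topo) == "265-dominant"

    def test_hybrid_mixed_interfaces(self):
        topo = FoldTopology("WT22m G4(II)", ("clockwise", "clockwise", "counterclockwise"))
        assert predict_cd_signature(topo) == "mixed 265+295"

    def test_two_layer_uniform(self):
        assert predict_cd_signature(
            FoldTopology("x", ("counterclockwise",) * 2)
        ) == "265-dominant"

    def test_alternating_is_295_dominant(self):
        topo = FoldTopology("antiparallel", ("clockwise", "counterclockwise", "clockwise"))
        assert predict_cd_signature(topo) == "295-dominant"

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            predict_cd_signature(FoldTopology("x", ("clockwise",)))


class TestIntegratePeak:
    def test_unit_rectangle(self):
        ppm = np.linspace(10, 11, 1001)
        intensity = np.where((ppm >= 10.4) & (ppm <= 10.6), 1.0, 0.0)
        assert integrate_peak(ppm, intensity, (10.4, 10.6)) == pytest.approx(0.2, abs=1e-3)

    def test_lorentzian_area(self):
        # Full area of a Lorentzian a*g^2/((x-x0)^2+g^2) is a*pi*g; over a
        # +/-20g window the exact integral is 2*a*g*atan(20), which still
        # captures ~97% of the peak (the heavy tails carry the rest).
        a, gamma, x0 = 3.0, 0.02, 12.0
        ppm = np.linspace(x0 - 25 * gamma, x0 + 25 * gamma, 4001)
        intensity = a * gamma**2 / ((ppm - x0) ** 2 + gamma**2)
        vol = integrate_peak(ppm, intensity, (x0 - 20 * gamma, x0 + 20 * gamma))
        assert vol == pytest.approx(2 * a * gamma * np.arctan(20.0), rel=1e-3)
        assert vol == pytest.approx(a * np.pi * gamma, rel=0.05)

    def test_zero_intensity(self):
        ppm = np.linspace(0, 1, 50)
        assert integrate_peak(ppm, np.zeros(50), (0.2, 0.8)) == 0.0

    def test_descending_axis_equivalent(self):
        ppm = np.linspace(10, 11, 501)
        intensity = np.exp(-((ppm - 10.5) ** 2) / 0.01)
        v1 = integrate_peak(ppm, intensity, (10.3, 10.7))
        v2 = integrate_peak(ppm[::-1], intensity[::-1], (10.3, 10.7))
        assert v1 == pytest.approx(v2)

    def test_empty_window_rejected(self):
        ppm = np.linspace(0, 1, 50)
        with pytest.raises(ValueError):
            integrate_peak(ppm, np.ones(50), (2.0, 3.0))
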