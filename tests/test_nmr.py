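"""HDX exchange times, population ratios, melting-curve Tm."""

import numpy as np
import pytest

from quadkin import (
    HDXSeries,
    MeltingCurve,
    NoTransitionError,
    NoiseSpec,
    PeakVolumeTable,
    estimate_populations,
    estimate_tm,
    gen_hdx_series,
    gen_melting_curve,
    gen_peak_table,
    hdx_exchange_time,
    unfolding_rate_from_hdx,
)


class TestHDX:
    def test_noiseless_self_consistency(self):
        fit = hdx_exchange_time(gen_hdx_series(25.0, noise=NoiseSpec(0.0, 0)))
        assert fit.tau == pytest.approx(25.0, rel=1e-6)

    @pytest.mark.parametrize("tau,tol", [(25.0, 0.20), (40.0, 0.20), (3800.0, 0.25)])
    def test_noisy_recovery_on_sparse_grid(self, tau, tol):
        # Middle-tetrad protons exchange in ~25 min in G4(I) and ~3800 min
        # in WT22m G4(II); the destabilized 5fC4 G4(II) drops to ~40 min.
        fit = hdx_exchange_time(gen_hdx_series(tau, noise=NoiseSpec(0.02, 5)))
        assert fit.tau == pytest.approx(tau, rel=tol)

    def test_order_preserved_for_distinct_exchange_times(self):
        fast = hdx_exchange_time(gen_hdx_series(25.0, noise=NoiseSpec(0, 0)))
        slow = hdx_exchange_time(gen_hdx_series(40.0, noise=NoiseSpec(0, 0)))
        assert fast.tau < slow.tau

    def test_rising_series_rejected(self):
        s = HDXSeries("G21", np.array([10.0, 30, 60, 120, 1440]),
                      np.array([0.1, 0.2, 0.4, 0.6, 1.0]))
        with pytest.raises(ValueError):
            hdx_exchange_time(s)

    def test_unfolding_rate_conversion(self):
        fit = hdx_exchange_time(gen_hdx_series(25.0, noise=NoiseSpec(0.0, 0)))
        assert unfolding_rate_from_hdx(fit) == pytest.approx(0.04, rel=1e-6)
        slow = hdx_exchange_time(gen_hdx_series(3800.0, noise=NoiseSpec(0.0, 0)))
        # 1/3800 printed to 2 significant figures
        assert float(f"{unfolding_rate_from_hdx(slow):.2g}") == 2.6e-4

    def test_floor_does_not_bias_tau(self):
        fit = hdx_exchange_time(
            gen_hdx_series(25.0, floor=0.1, noise=NoiseSpec(0.0, 0))
        )
        assert fit.tau == pytest.approx(25.0, rel=0.10)
        assert fit.offset == pytest.approx(0.1, abs=0.01)


class TestPopulations:
    def test_simple_ratio(self):
        table = PeakVolumeTable(("G16", "G18"), np.array([10.0, 10.0]),
                                np.array([90.0, 90.0]))
        est = estimate_populations(table)
        assert est.fraction_g4i == pytest.approx(0.10)
        assert est.fraction_g4ii == pytest.approx(0.90)

    def test_noisy_table_near_generating_fraction(self):
        table = gen_peak_table(0.85, noise=NoiseSpec(0.05, 12))
        est = estimate_populations(table)
        assert 0.80 <= est.fraction_g4i <= 0.90

    def test_noiseless_round_trip_exact(self):
        for f in (0.0, 0.10, 0.5, 0.85, 1.0):
            est = estimate_populations(gen_peak_table(f))
            assert est.fraction_g4i == pytest.approx(f, abs=1e-12)

    def test_discordant_reporters_flagged(self):
        table = PeakVolumeTable(("G16", "G18"), np.array([20.0, 60.0]),
                                np.array([80.0, 40.0]))
        with pytest.warns(UserWarning):
            est = estimate_populations(table)
        assert est.fraction_g4i == pytest.approx(0.4)
        assert est.dispersion == pytest.approx(0.4)
        assert est.discordant

    def test_missing_reporter_named(self):
        table = PeakVolumeTable(("G16",), np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="G18"):
            estimate_populations(table)


class TestEstimateTm:
    @pytest.mark.parametrize("tm", [73.0, 69.2])
    def test_noiseless_recovery(self, tm):
        curve = gen_melting_curve(tm, noise=NoiseSpec(0.0, 0))
        est, err = estimate_tm(curve)
        assert est == pytest.approx(tm, abs=0.2)

    @pytest.mark.parametrize("tm", [73.0, 69.2])
    def test_noisy_recovery_within_half_degree(self, tm):
        curve = gen_melting_curve(tm, noise=NoiseSpec(0.01, 4))
        est, err = estimate_tm(curve)
        assert est == pytest.approx(tm, abs=0.5)

    def test_affine_invariance(self):
        curve = gen_melting_curve(73.0, noise=NoiseSpec(0.01, 9))
        tm1, _ = estimate_tm(curve)
        scaled = MeltingCurve(curve.temperatures, 37.5 * curve.ellipticity - 11.0,
                              curve.wavelength)
        tm2, _ = estimate_tm(scaled)
        assert tm2 == pytest.approx(tm1, abs=0.1)

    def test_linear_signal_has_no_transition(self):
        temp = np.arange(10.0, 96.0)
        curve = MeltingCurve(temp, 0.5 - 0.001 * temp)
        with pytest.raises(NoTransitionError):
            estimate_tm(curve)

    def test_sharper_transition_has_larger_derivative(self):
        sharp = gen_melting_curve(50.0, width=0.5, noise=NoiseSpec(0.0, 0))
        broad = gen_melting_curve(50.0, width=5.0, noise=NoiseSpec(0.0, 0))
        d_sharp = np.max(np.abs(np.gradient(sharp.ellipticity, sharp.temperatures)))
        d_broad = np.max(np.abs(np.gradient(broad.ellipticity, broad.temperatures)))
        assert d_sharp > d_broad
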