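import numpy as np
import pytest

from thrombodyn import (
    ForwardOptions,
    InversionOptions,
    PCCurve,
    PlasmaProfile,
    RateConstants,
    TGCurve,
    extract_prothrombin_conversion,
    forward_simulate_tg,
)
from thrombodyn.conversion import (
    differentiate_curve,
    estimate_noise_sd,
    read_pc_curve,
    write_pc_curve,
)
from thrombodyn.synthetic import add_noise, generate_pc_curve


def flat_plasma(tdc=0.5):
    """Plasma whose AT channel alone gives the requested decay capacity."""
    return PlasmaProfile(at_level=tdc / 3e-4, a2m_level=0.0, fibrinogen=0.0,
                         fviii=1.0)


K_NO_MS = RateConstants(k_at=3e-4, k_a2m=1e-5, k_ms=0.0)


class TestDifferentiateCurve:
    def test_linear_ramp_exact(self):
        t = np.linspace(0, 20, 121)
        c = TGCurve(t, 5.0 * t)
        for w in (1, 9):
            d = differentiate_curve(c, window=w)
            np.testing.assert_allclose(d.values, 5.0, rtol=1e-9)

    def test_constant_curve_zero(self):
        c = TGCurve(np.linspace(0, 20, 61), np.full(61, 7.0))
        np.testing.assert_allclose(differentiate_curve(c, window=9).values, 0.0,
                                   atol=1e-12)

    def test_sine_matches_cosine(self):
        t = np.linspace(0, 20, 401)
        c = TGCurve(t, 10.0 + 5.0 * np.sin(t))
        for w in (1, 9):
            d = differentiate_curve(c, window=w).values
            interior = slice(10, -10)
            np.testing.assert_allclose(d[interior], 5.0 * np.cos(t)[interior],
                                       atol=0.005 * 5.0)

    def test_integral_returns_endpoint_difference(self):
        t = np.linspace(0, 20, 201)
        y = 10.0 + 5.0 * np.sin(t) + 0.3 * t
        c = TGCurve(t, y)
        d = differentiate_curve(c, window=1).values
        assert np.trapezoid(d, t) == pytest.approx(y[-1] - y[0], rel=1e-9)

    def test_window_larger_than_record(self):
        c = TGCurve(np.linspace(0, 20, 11), np.ones(11))
        with pytest.raises(ValueError, match="window"):
            differentiate_curve(c, window=13)


class TestNoiseEstimate:
    def test_clean_vs_noisy(self):
        t = np.linspace(0, 60, 181)
        clean = TGCurve(t, 100.0 * np.exp(-((t - 10) ** 2) / 8.0))
        assert estimate_noise_sd(clean) < 0.05
        noisy = add_noise(clean, sd=2.0, seed=5)
        assert 1.5 < estimate_noise_sd(noisy) < 2.5


class TestExtraction:
    def test_zero_curve(self, k):
        c = TGCurve(np.linspace(0, 30, 91), np.zeros(91))
        r = extract_prothrombin_conversion(c, flat_plasma(), k)
        assert r.pc_tot == 0.0 and r.pc_max == 0.0
        assert r.t_at_total == 0.0 and r.t_a2m_total == 0.0

    def test_constant_thrombin_closed_form(self):
        """With T constant, dT/dt = 0 and the rate is tdc*T throughout."""
        t = np.linspace(0, 20, 121)
        c = TGCurve(t, np.full(121, 10.0))
        r = extract_prothrombin_conversion(
            c, flat_plasma(0.5), K_NO_MS,
            InversionOptions(consume_inhibitors=False),
        )
        np.testing.assert_allclose(r.pc_curve.rate, 5.0, rtol=1e-9)
        assert r.pc_tot == pytest.approx(0.5 * 10.0 * 20.0, rel=1e-9)

    @pytest.mark.parametrize("pc_tot,theta", [(300.0, 1.0), (600.0, 1.5),
                                              (900.0, 2.5), (600.0, 0.8)])
    def test_forward_inverse_round_trip(self, k, control_plasma, pc_tot, theta):
        """Noise-free forward-simulated curves give back the true pulse."""
        pc = generate_pc_curve(pc_tot, 4.0, theta, onset=3.0,
                               grid=np.arange(0, 60.0 + 1e-9, 1 / 3))
        curve = forward_simulate_tg(pc, control_plasma, k,
                                    options=ForwardOptions(t_max=60.0,
                                                           stop_threshold=0.0,
                                                           output_dt=1 / 3))
        r = extract_prothrombin_conversion(curve, control_plasma, k)
        assert r.pc_tot == pytest.approx(pc.pc_tot, rel=0.01)
        assert r.pc_max == pytest.approx(pc.pc_max, rel=0.02)

    def test_conservation_identity(self, k, clean_cohort):
        for s in clean_cohort[::7]:
            r = extract_prothrombin_conversion(s.curve, s.plasma, k)
            assert abs(r.conservation_residual()) < 5e-3

    def test_monotone_sensitivity_to_at(self, k, clean_cohort):
        """The same observed curve under stronger inhibition implies more
        prothrombin must have been converted."""
        s = clean_cohort[0]
        r1 = extract_prothrombin_conversion(s.curve, s.plasma, k)
        stronger = PlasmaProfile(at_level=1.5 * s.plasma.at_level,
                                 a2m_level=s.plasma.a2m_level,
                                 fibrinogen=s.plasma.fibrinogen,
                                 fviii=s.plasma.fviii, group=s.plasma.group)
        r2 = extract_prothrombin_conversion(s.curve, stronger, k)
        assert r2.pc_tot > r1.pc_tot

    def test_noisy_recovery_median(self, k, clean_cohort):
        """Replicated noise on one clean curve: median PCtot error small."""
        s = clean_cohort[3]
        errs = []
        for rep in range(10):
            noisy = add_noise(s.curve, sd=2.0, seed=1000 + rep)
            r = extract_prothrombin_conversion(noisy, s.plasma, k)
            errs.append(abs(r.pc_tot - s.truth.pc_tot) / s.truth.pc_tot)
        assert np.median(errs) < 0.05

    def test_incomplete_decay_flagged(self, k):
        """A record cut off mid-decay carries the truncation warning."""
        pc = generate_pc_curve(600.0, 4.0, 1.5, onset=3.0,
                               grid=np.arange(0, 16.0 + 1e-9, 1 / 3),
                               max_integral_error=0.05)
        plasma = flat_plasma(0.3)
        curve = forward_simulate_tg(pc, plasma, K_NO_MS,
                                    options=ForwardOptions(t_max=16.0,
                                                           stop_threshold=0.0,
                                                           output_dt=1 / 3))
        r = extract_prothrombin_conversion(curve, plasma, K_NO_MS)
        assert r.incomplete_decay

    def test_settings_echoed(self, k, clean_cohort):
        s = clean_cohort[0]
        r = extract_prothrombin_conversion(s.curve, s.plasma, k)
        assert r.settings["rate_constants"]["k_at"] == k.k_at
        assert r.settings["smooth_window"] == 1  # clean record -> no smoothing


class TestPCCurveIO:
    def test_round_trip(self, tmp_path):
        pc = generate_pc_curve(600.0, 4.0, 1.5, onset=2.0)
        path = write_pc_curve(pc, tmp_path / "pc.csv")
        back = read_pc_curve(path)
        np.testing.assert_allclose(back.rate, pc.rate, rtol=1e-6, atol=1e-9)
        assert back.pc_tot == pytest.approx(pc.pc_tot, rel=1e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            PCCurve([0.0, 1.0, 2.0], [1.0, -0.5, 0.0])

    def test_consumed_is_nondecreasing(self):
        pc = generate_pc_curve(600.0, 4.0, 1.5, onset=2.0)
        assert np.all(np.diff(pc.prothrombin_consumed) >= 0)
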