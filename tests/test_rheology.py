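import numpy as np
import pytest

from nanolink.rheology import (
    ModulusSpectrum,
    MsdSeries,
    StressSeries,
    compute_msd,
    extract_plateau_crossover,
    fit_power_law,
    fit_stretched_exponential,
    green_kubo_relaxation,
    gser_moduli,
    predict_scaling_exponents,
)
from nanolink.synthetic import make_ou_stress, make_trap_msd


class TestComputeMsd:
    def test_linear_track_quadratic(self):
        t = np.arange(500) * 0.1
        track = np.outer(t, [1.0, 2.0, -1.0])
        msd = compute_msd(track, dt=0.1)
        np.testing.assert_allclose(msd.msd, 6.0 * msd.lags**2, rtol=1e-9)

    def test_static_track_zero(self):
        track = np.tile([1.0, 2.0, 3.0], (200, 1))
        msd = compute_msd(track, dt=0.1)
        np.testing.assert_allclose(msd.msd, 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_walk_slope(self, seed):
        """Origin-averaged MSD of a seeded 3-D walk recovers 6D within 5%
        over intermediate lags."""
        diffusion = 0.5
        rng = np.random.default_rng(seed)
        track = np.cumsum(
            rng.normal(scale=np.sqrt(2 * diffusion * 0.1), size=(100_000, 3)),
            axis=0,
        )
        msd = compute_msd(track, dt=0.1, n_lags=80)
        mask = (msd.lags > 0.5) & (msd.lags < 20)
        slope = np.polyfit(msd.lags[mask], msd.msd[mask], 1)[0]
        assert slope == pytest.approx(6 * diffusion, rel=0.05)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            compute_msd(np.zeros((50, 3)), dt=0.1)


class TestGser:
    def test_diffusive_msd_pure_viscous(self):
        """MSD = 6Dt maps to G' = 0 and G'' = omega * k_B T / (6 pi a D)."""
        msd = make_trap_msd(spring_constant=0.0, tracer_radius=2.5)
        spec = gser_moduli(msd)
        eta = 1.0 / (6 * np.pi * 2.5 * (1.0 / (6 * np.pi * 2.5)))
        np.testing.assert_allclose(spec.g_loss, spec.omega * eta, rtol=0.02)
        assert np.all(np.abs(spec.g_storage) < 1e-10 * spec.g_loss.max())

    def test_trap_msd_plateau(self):
        """A harmonic-trap MSD plateau maps to G' = k / (6 pi a) within 2%
        in the plateau region."""
        k = 2.0
        a = 2.5
        msd = make_trap_msd(spring_constant=k, tracer_radius=a)
        spec = gser_moduli(msd)
        tau_k = 6 * np.pi * a / k
        assert spec.storage_at(1.0 / (10 * tau_k)) == pytest.approx(
            k / (6 * np.pi * a), rel=0.02
        )

    def test_half_power_msd_loss_tangent_one(self):
        """MSD ~ t^0.5 gives G' = G'' at every frequency (alpha = 1/2
        identity of the local power-law approximation)."""
        lags = np.geomspace(0.01, 100, 60)
        spec = gser_moduli(MsdSeries(lags=lags, msd=lags**0.5, tracer_radius=2.5))
        np.testing.assert_allclose(spec.g_storage, spec.g_loss, rtol=0.02)

    def test_nonpositive_interior_rejected(self):
        lags = np.geomspace(0.1, 10, 30)
        msd = np.ones(30)
        msd[15] = 0.0
        with pytest.raises(ValueError):
            gser_moduli(MsdSeries(lags=lags, msd=msd, tracer_radius=1.0))


class TestGreenKubo:
    def test_zero_stress_zero_modulus(self):
        series = StressSeries(
            times=np.arange(1000) * 0.1, components=np.zeros((1000, 3)),
            volume=100.0,
        )
        _, g = green_kubo_relaxation(series)
        np.testing.assert_allclose(g, 0.0, atol=1e-25)

    def test_ou_ground_truth(self):
        """Three OU components with ACF A e^{-t/tau} give
        G(t) = (V / k_B T) A e^{-t/tau} within 10% for t <= 3 tau."""
        amp, tau, vol = 0.01, 5.0, 1000.0
        series = make_ou_stress(amplitude=amp, tau_c=tau, n_samples=100_000,
                                dt=0.1, seed=3, volume=vol)
        lags, g = green_kubo_relaxation(series)
        mask = lags <= 3 * tau
        expected = vol * amp * np.exp(-lags[mask] / tau)
        assert np.abs(g[mask] - expected).max() <= 0.1 * vol * amp

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(0)
        series = StressSeries(
            times=np.arange(20_000) * 0.1,
            components=rng.normal(size=(20_000, 3)),
            volume=30.0,
        )
        lags, g = green_kubo_relaxation(series)
        assert np.abs(g[1:]).max() < 0.05 * g[0]

    def test_ordered_pair_convention_doubles(self):
        series = make_ou_stress(n_samples=5000, seed=1)
        _, g3 = green_kubo_relaxation(series, n_off_diagonal=3)
        _, g6 = green_kubo_relaxation(series, n_off_diagonal=6)
        np.testing.assert_allclose(g6, 2 * g3)

    def test_short_series_rejected(self):
        series = StressSeries(
            times=np.arange(10) * 0.1, components=np.zeros((10, 3)), volume=1.0
        )
        with pytest.raises(ValueError):
            green_kubo_relaxation(series)


def test_gel_stress_series_yields_finite_modulus(small_gel):
    """The simulator's off-diagonal stress series feeds Green-Kubo directly:
    G(t) is finite with a positive zero-lag value (the instantaneous
    modulus) that bounds the later lags of the transient gel."""
    lags, g = green_kubo_relaxation(small_gel.stress)
    assert np.isfinite(g).all()
    assert g[0] > 0
    assert np.abs(g[1:]).max() <= g[0] * 1.5


class TestStretchedExponential:
    def test_exact_recovery(self):
        t = np.linspace(0, 30, 100)
        fit = fit_stretched_exponential(t, 2 * np.exp(-t / 5))
        assert fit.a == pytest.approx(2.0, abs=1e-6)
        assert fit.tau == pytest.approx(5.0, abs=1e-5)
        assert fit.b == pytest.approx(1.0, abs=1e-6)

    def test_noisy_stretched_recovery(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 20, 200)
        g = 1.5 * np.exp(-((t / 3) ** 0.6))
        g_noisy = g * (1 + 0.01 * rng.normal(size=len(t)))
        fit = fit_stretched_exponential(t, g_noisy)
        assert fit.a == pytest.approx(1.5, rel=0.05)
        assert fit.tau == pytest.approx(3.0, rel=0.05)
        assert fit.b == pytest.approx(0.6, rel=0.05)

    def test_rising_series_rejected(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(ValueError, match="rising"):
            fit_stretched_exponential(t, np.exp(t / 10))


class TestPlateauCrossover:
    def test_maxwell_model(self):
        """Maxwell spectrum: crossover at omega = 1/tau; G' approaches G at
        high frequency."""
        G0, tau = 3.0, 2.0
        w = np.geomspace(1e-3, 100, 300)
        spec = ModulusSpectrum(
            omega=w,
            g_storage=G0 * w**2 * tau**2 / (1 + w**2 * tau**2),
            g_loss=G0 * w * tau / (1 + w**2 * tau**2),
        )
        out = extract_plateau_crossover(spec)
        assert out["crossover_found"]
        assert out["omega0"] == pytest.approx(1 / tau, rel=0.01)
        assert out["tau_u"] == pytest.approx(tau, rel=0.01)
        assert out["plateau"] == pytest.approx(G0, rel=0.01)

    def test_pure_viscous_flags_absent(self):
        w = np.geomspace(0.01, 10, 50)
        spec = ModulusSpectrum(omega=w, g_storage=np.zeros_like(w), g_loss=w)
        out = extract_plateau_crossover(spec)
        assert not out["crossover_found"]
        assert out["omega0"] is None

    def test_single_frequency_rejected(self):
        spec = ModulusSpectrum(
            omega=np.array([1.0]), g_storage=np.array([1.0]),
            g_loss=np.array([2.0]),
        )
        with pytest.raises(ValueError):
            extract_plateau_crossover(spec)


class TestPowerLaw:
    def test_exact_cubic(self):
        x = np.geomspace(0.01, 1.0, 10)
        fit = fit_power_law(x, 2 * x**3)
        assert fit.slope == pytest.approx(3.0, abs=1e-12)
        assert fit.stderr == pytest.approx(0.0, abs=1e-10)

    def test_noisy_recovery_within_two_se(self):
        rng = np.random.default_rng(5)
        x = np.geomspace(0.01, 0.14, 8)
        y = x**2.5 * np.exp(0.1 * rng.normal(size=8))
        fit = fit_power_law(x, y)
        assert abs(fit.slope - 2.5) <= 2 * fit.stderr + 1e-12

    def test_breakpoint_two_slopes(self):
        rng = np.random.default_rng(6)
        x = np.geomspace(0.01, 0.14, 14)
        bp = 0.056
        y = np.where(x < bp, x**-0.6, bp**(-0.6 + 0.9) * x**-0.9)
        y = y * np.exp(0.02 * rng.normal(size=len(x)))
        fit = fit_power_law(x, y, breakpoint=bp)
        assert fit.slopes[0] == pytest.approx(-0.6, abs=2 * fit.stderrs[0] + 0.02)
        assert fit.slopes[1] == pytest.approx(-0.9, abs=2 * fit.stderrs[1] + 0.02)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(np.array([1.0, 2, 3]), np.array([1.0, -2, 3]))


class TestExponentAlgebra:
    def test_mesh_combination(self):
        out = predict_scaling_exponents(
            n_minloop_slope=(1.0, 0.0), xi_slope=(-0.84, 0.0)
        )
        assert out["mesh_exponent"][0] == pytest.approx(3.52)

    def test_link_combination(self):
        out = predict_scaling_exponents(
            n_minloop_slope=(1.0, 0.0), z_slope=(1.4, 0.0)
        )
        assert out["link_exponent"][0] == pytest.approx(2.4)

    def test_geometric_combination(self):
        out = predict_scaling_exponents(lmin_slope=(0.1, 0.0))
        assert out["geometric_z_exponent"][0] == pytest.approx(1.3)

    def test_phantom_comparators(self):
        out = predict_scaling_exponents(lmin_slope=(0.1, 0.0))
        assert out["phantom_exponent"] == 1.0
        assert out["phantom_prefactor"] == pytest.approx(1.0 / 3.0)
        assert out["disordered_phantom_exponent"] == pytest.approx(1.0 / 3.0)

    def test_error_propagation_quadrature(self):
        out = predict_scaling_exponents(
            n_minloop_slope=(1.0, 0.05), z_slope=(1.4, 0.1)
        )
        assert out["link_exponent"][1] == pytest.approx(np.hypot(0.05, 0.1))

    def test_missing_slopes_rejected(self):
        with pytest.raises(ValueError):
            predict_scaling_exponents()
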