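"""HN model evaluation, loss-spectrum fitting, relaxation map and VFT/Tg."""

import numpy as np
import pytest

from mesokit.dielectric import (
    EPS_VACUUM,
    DielectricSpectrum,
    HNFitResult,
    HNProcess,
    VFTFit,
    build_relaxation_map,
    dielectric_loss,
    fit_spectrum,
    fit_vft,
    hn_eps,
    tau_max,
    tg_from_vft,
)
from mesokit.synthetic import dielectric_preset, generate_dielectric_series


def _model(processes, sigma_dc=0.0, eps_inf=3.0, temperature=350.0):
    return HNFitResult(
        sigma_dc=sigma_dc, eps_inf=eps_inf, processes=processes, temperature=temperature
    )


def _loss_spectrum(model, fmin=1e-1, fmax=1e6, ppd=10, temperature=350.0):
    n = int(round(np.log10(fmax / fmin) * ppd)) + 1
    freq = np.logspace(np.log10(fmin), np.log10(fmax), n)
    loss = dielectric_loss(2 * np.pi * freq, model)
    eps_real = hn_eps(2 * np.pi * freq, model).real
    return DielectricSpectrum(freq=freq, eps_imag=loss, eps_real=eps_real,
                              temperature=temperature)


class TestHNModel:
    def test_debye_peak_height_and_position(self):
        proc = HNProcess(delta_eps=2.0, tau_hn=1e-3, alpha_hn=1.0, beta_hn=1.0)
        model = _model([proc])
        # at omega tau = 1 the Debye loss is exactly delta_eps / 2
        assert dielectric_loss(1.0 / proc.tau_hn, model) == pytest.approx(1.0, rel=1e-12)
        w = np.logspace(0, 6, 20000)
        peak_w = w[np.argmax(dielectric_loss(w, model))]
        assert peak_w == pytest.approx(1.0 / proc.tau_hn, rel=1e-3)

    def test_dc_only_slope_minus_one(self):
        proc = HNProcess(delta_eps=1e-9, tau_hn=1e-12, alpha_hn=1.0, beta_hn=1.0)
        model = _model([proc], sigma_dc=1e-10)
        w = np.logspace(0, 4, 50)
        slope = np.gradient(np.log10(dielectric_loss(w, model)), np.log10(w))
        assert np.allclose(slope, -1.0, atol=1e-3)

    def test_matches_independent_complex_arithmetic(self):
        proc1 = HNProcess(delta_eps=3.1, tau_hn=2.3e-4, alpha_hn=0.77, beta_hn=0.41)
        proc2 = HNProcess(delta_eps=0.4, tau_hn=5.0e-7, alpha_hn=0.93, beta_hn=0.88)
        sigma = 3.3e-11
        model = _model([proc1, proc2], sigma_dc=sigma, eps_inf=2.7)
        w = np.logspace(-1, 7, 200)
        expected = np.full(w.shape, 2.7, dtype=complex)
        for p in (proc1, proc2):
            expected += p.delta_eps / (1 + (1j * w * p.tau_hn) ** p.alpha_hn) ** p.beta_hn
        expected -= 1j * sigma / (EPS_VACUUM * w)
        got = hn_eps(w, model)
        assert np.max(np.abs(got - expected)) < 1e-14 * np.max(np.abs(expected))

    def test_loss_nonnegative(self):
        model = _model(
            [HNProcess(delta_eps=5.0, tau_hn=1e-2, alpha_hn=0.5, beta_hn=0.3)],
            sigma_dc=1e-12,
        )
        w = np.logspace(-3, 8, 300)
        assert np.all(dielectric_loss(w, model) >= 0)


class TestTauMax:
    def test_debye_limit(self):
        proc = HNProcess(delta_eps=1.0, tau_hn=3.7e-5, alpha_hn=1.0, beta_hn=1.0)
        assert tau_max(proc) == pytest.approx(proc.tau_hn, rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.4, 0.7, 1.0])
    @pytest.mark.parametrize("beta", [0.4, 0.7, 1.0])
    def test_matches_grid_argmax(self, alpha, beta):
        proc = HNProcess(delta_eps=1.0, tau_hn=1e-3, alpha_hn=alpha, beta_hn=beta)
        model = _model([proc])
        w = np.logspace(-1, 7, 400000)
        w_peak = w[np.argmax(dielectric_loss(w, model))]
        assert 1.0 / w_peak == pytest.approx(tau_max(proc), rel=1e-3)

    def test_small_alpha_stays_finite_positive(self):
        proc = HNProcess(delta_eps=1.0, tau_hn=1e-3, alpha_hn=0.08, beta_hn=0.9)
        t = tau_max(proc)
        assert np.isfinite(t) and t > 0

    def test_monotone_in_tau_hn(self):
        taus = [
            tau_max(HNProcess(delta_eps=1.0, tau_hn=t, alpha_hn=0.7, beta_hn=0.5))
            for t in np.logspace(-6, 0, 13)
        ]
        assert np.all(np.diff(taus) > 0)


class TestFitSpectrum:
    def test_noiseless_two_process_recovery(self):
        true = [
            HNProcess(delta_eps=3.5, tau_hn=1.2e-2, alpha_hn=0.88, beta_hn=0.52),
            HNProcess(delta_eps=0.45, tau_hn=2.0e-5, alpha_hn=0.95, beta_hn=0.99),
        ]
        model = _model(true, sigma_dc=5e-11)
        spec = _loss_spectrum(model)
        fit = fit_spectrum(spec, n_processes=2)
        assert fit.converged
        assert fit.sigma_dc == pytest.approx(5e-11, rel=1e-4)
        for got, want in zip(fit.processes, true):
            assert got.delta_eps == pytest.approx(want.delta_eps, rel=1e-4)
            assert got.tau_hn == pytest.approx(want.tau_hn, rel=1e-4)
            assert got.alpha_hn == pytest.approx(want.alpha_hn, rel=1e-4)
            assert got.beta_hn == pytest.approx(want.beta_hn, rel=1e-4)

    @pytest.mark.parametrize("alpha", [0.4, 0.7, 1.0])
    @pytest.mark.parametrize("beta", [0.4, 0.7, 1.0])
    def test_shape_grid_recovery(self, alpha, beta):
        true = HNProcess(delta_eps=2.0, tau_hn=1e-3, alpha_hn=alpha, beta_hn=beta)
        spec = _loss_spectrum(_model([true], sigma_dc=2e-11))
        fit = fit_spectrum(spec, n_processes=1)
        got = fit.processes[0]
        assert got.delta_eps == pytest.approx(true.delta_eps, rel=1e-3)
        assert got.tau_hn == pytest.approx(true.tau_hn, rel=1e-3)
        assert got.alpha_hn == pytest.approx(alpha, rel=1e-3)
        assert got.beta_hn == pytest.approx(beta, rel=1e-3)

    def test_second_process_shrinks_on_single_process_data(self):
        true = HNProcess(delta_eps=3.0, tau_hn=1e-3, alpha_hn=0.9, beta_hn=0.6)
        spec = _loss_spectrum(_model([true], sigma_dc=2e-11))
        fit2 = fit_spectrum(spec, n_processes=2)
        strengths = sorted(p.delta_eps for p in fit2.processes)
        assert strengths[0] < 0.05 * strengths[1]

    def test_noise_robustness_tau_of_dominant_process(self):
        # 2% multiplicative noise, many replicates: median tau_max error < 5%
        true = [
            HNProcess(delta_eps=3.5, tau_hn=1.2e-2, alpha_hn=0.88, beta_hn=0.52),
            HNProcess(delta_eps=0.45, tau_hn=2.0e-5, alpha_hn=0.95, beta_hn=0.99),
        ]
        model = _model(true, sigma_dc=5e-11)
        clean = _loss_spectrum(model)
        target = tau_max(true[0])
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = DielectricSpectrum(
                freq=clean.freq,
                eps_imag=clean.eps_imag * rng.lognormal(0, 0.02, len(clean.freq)),
                temperature=clean.temperature,
            )
            fit = fit_spectrum(noisy, n_processes=2)
            errors.append(abs(tau_max(fit.processes[0]) / target - 1))
        assert np.median(errors) < 0.05

    def test_debye_strength_matches_real_part_step(self):
        # Kramers-Kronig sanity: delta_eps fitted from the loss equals the
        # step height of eps' across the dispersion
        true = HNProcess(delta_eps=2.5, tau_hn=1e-3, alpha_hn=1.0, beta_hn=1.0)
        spec = _loss_spectrum(_model([true], sigma_dc=1e-12), fmin=1e-2, fmax=1e6)
        fit = fit_spectrum(spec, n_processes=1)
        step = spec.eps_real[0] - spec.eps_real[-1]
        assert fit.processes[0].delta_eps == pytest.approx(step, rel=0.01)

    def test_input_validation(self):
        freq = np.logspace(0, 2, 25)  # only 2 decades
        spec = DielectricSpectrum(freq=freq, eps_imag=np.ones_like(freq), temperature=300)
        with pytest.raises(ValueError):
            fit_spectrum(spec)
        with pytest.raises(ValueError):
            DielectricSpectrum(freq=freq, eps_imag=-np.ones_like(freq), temperature=300)


class TestRelaxationMap:
    def test_single_temperature_single_row(self):
        model = _model(
            [HNProcess(delta_eps=2.0, tau_hn=1e-3, alpha_hn=0.9, beta_hn=0.7)],
            temperature=340.0,
        )
        df = build_relaxation_map([_fit_of(model)])
        assert len(df) == 1
        assert df.loc[0, "temperature"] == 340.0

    def test_recovers_vft_ground_truth(self):
        series = generate_dielectric_series(dielectric_preset("SE-ITZ-20"))
        fits = [fit_spectrum(s, n_processes=2) for s in series.spectra[:3]]
        df = build_relaxation_map(fits)
        truth = series.truth.iloc[:3]
        assert np.allclose(df["tau_alpha"], truth["tau_alpha"], rtol=1e-3)
        assert np.allclose(df["tau_delta"], truth["tau_delta"], rtol=1e-3)

    def test_solvent_evaporated_faster_than_vitrified_near_tg(self):
        t_low = (337.0, 340.0, 343.0)
        maps = {}
        for name in ("V-ITZ", "SE-ITZ-20"):
            series = generate_dielectric_series(
                dielectric_preset(name, temperatures=t_low)
            )
            fits = [fit_spectrum(s, n_processes=2) for s in series.spectra]
            maps[name] = build_relaxation_map(fits)
        assert np.all(
            maps["SE-ITZ-20"]["tau_alpha"].to_numpy()
            < maps["V-ITZ"]["tau_alpha"].to_numpy()
        )


def _fit_of(model):
    model.residual_rms = 0.0
    return model


class TestVFT:
    def test_noiseless_recovery_and_closed_form_tg(self):
        tau_inf, B, T0 = 1e-14, 2000.0, 250.0
        T = np.arange(280.0, 340.0, 5.0)
        tau = tau_inf * np.exp(B / (T - T0))
        fit = fit_vft(T, tau)
        assert fit.tau_inf == pytest.approx(tau_inf, rel=1e-6)
        assert fit.B == pytest.approx(B, rel=1e-6)
        assert fit.T0 == pytest.approx(T0, abs=1e-4)
        assert fit.tg == pytest.approx(250 + 2000 / np.log(1e16), abs=0.01)
        assert fit.tg == pytest.approx(304.29, abs=0.01)

    def test_arrhenius_limit(self):
        # T0 = 0 reduces to Arrhenius; fitted B equals the activation slope
        tau_inf, B = 1e-13, 4000.0
        T = np.arange(250.0, 400.0, 10.0)
        tau = tau_inf * np.exp(B / T)
        fit = fit_vft(T, tau)
        assert fit.T0 == pytest.approx(0.0, abs=0.5)
        assert fit.B == pytest.approx(B, rel=5e-3)

    def test_tg_unit_invariance(self):
        T = np.arange(280.0, 340.0, 5.0)
        tau_s = 1e-14 * np.exp(2000.0 / (T - 250.0))
        fit_s = fit_vft(T, tau_s)
        fit_ms = fit_vft(T, tau_s * 1e3)  # same data in milliseconds
        tg_s = tg_from_vft(fit_s, tau_ref=100.0)
        tg_ms = tg_from_vft(fit_ms, tau_ref=100.0 * 1e3)
        assert tg_ms == pytest.approx(tg_s, abs=1e-6)

    def test_rejects_tau_inf_at_or_above_reference(self):
        with pytest.raises(ValueError):
            VFTFit(tau_inf=200.0, B=1000.0, T0=250.0)
        fit = VFTFit(tau_inf=1e-12, B=1500.0, T0=250.0)
        with pytest.raises(ValueError):
            tg_from_vft(fit, tau_ref=1e-13)

    def test_requires_four_points(self):
        with pytest.raises(ValueError):
            fit_vft([300.0, 310.0, 320.0], [1.0, 0.1, 0.01])

    def test_preset_tg_targets(self):
        for name, target in (("V-ITZ", 326.4), ("SE-ITZ-20", 324.2)):
            series = generate_dielectric_series(dielectric_preset(name))
            fits = [fit_spectrum(s, n_processes=2) for s in series.spectra]
            df = build_relaxation_map(fits)
            vft = fit_vft(df["temperature"].to_numpy(), df["tau_alpha"].to_numpy())
            assert vft.tg == pytest.approx(target, abs=0.5)
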