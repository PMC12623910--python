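"""Havriliak-Negami fitting of dielectric loss spectra and VFT/Tg analysis.

The complex permittivity of a relaxing glass-former with mobile charges is
modelled as up to two Havriliak-Negami (HN) processes plus an ohmic
DC-conductivity loss:

    eps*(omega) = eps_inf
                  + sum_i  Delta_eps_i / (1 + (i omega tau_HN,i)^alpha_i)^beta_i
                  - i sigma_DC / (eps_f omega),

with eps_f the vacuum permittivity.  The DC term is implemented as purely
imaginary (it only adds ohmic loss); alpha, beta in (0, 1] reduce to a Debye
process at alpha = beta = 1.  Per-temperature loss spectra are fitted in
log-log space, the peak relaxation time tau_max is derived from tau_HN by
the standard closed form, its temperature dependence is fitted with the
Vogel-Fulcher-Tammann law

    tau(T) = tau_inf * exp(B / (T - T0)),

and the glass-transition temperature Tg is read off as the temperature at
which the structural relaxation time reaches 100 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "EPS_VACUUM",
    "DielectricSpectrum",
    "HNProcess",
    "HNFitResult",
    "VFTFit",
    "hn_eps",
    "dielectric_loss",
    "tau_max",
    "fit_spectrum",
    "build_relaxation_map",
    "fit_vft",
    "tg_from_vft",
]

def _minimize_quiet(resid, params):
    """lmfit least_squares with tight tolerances; covariance post-processing
    warnings (singular Jacobians at parameter bounds) are suppressed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return lmfit.minimize(
            resid, params, method="least_squares", calc_covar=False,
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )


#: vacuum permittivity in F/m
EPS_VACUUM = 8.8541878128e-12


@dataclass
class DielectricSpectrum:
    """One isothermal spectrum: frequency grid (Hz), loss, optional eps'."""

    freq: np.ndarray
    eps_imag: np.ndarray
    eps_real: Optional[np.ndarray] = None
    temperature: float = 0.0  # Kelvin

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.eps_imag = np.asarray(self.eps_imag, dtype=float)
        if self.freq.ndim != 1 or len(self.freq) != len(self.eps_imag):
            raise ValueError("freq and eps_imag must be 1-D of equal length")
        if np.any(self.freq <= 0) or np.any(np.diff(self.freq) <= 0):
            raise ValueError("freq must be positive and strictly ascending")
        if np.any(self.eps_imag < 0) or not np.all(np.isfinite(self.eps_imag)):
            raise ValueError("eps_imag must be finite and non-negative")
        if self.eps_real is not None:
            self.eps_real = np.asarray(self.eps_real, dtype=float)
            if len(self.eps_real) != len(self.freq):
                raise ValueError("eps_real length mismatch")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.freq


@dataclass(frozen=True)
class HNProcess:
    """One Havriliak-Negami relaxation process."""

    delta_eps: float
    tau_hn: float  # seconds
    alpha_hn: float
    beta_hn: float

    def __post_init__(self):
        if self.delta_eps <= 0 or self.tau_hn <= 0:
            raise ValueError("delta_eps and tau_hn must be positive")
        if not (0 < self.alpha_hn <= 1 and 0 < self.beta_hn <= 1):
            raise ValueError("alpha_hn and beta_hn must lie in (0, 1]")

    @property
    def is_debye(self) -> bool:
        return self.alpha_hn == 1.0 and self.beta_hn == 1.0


@dataclass
class HNFitResult:
    """Fitted model for one temperature: DC term, eps_inf and 1-2 HN processes.

    Processes are ordered by tau_max descending (slower process first, i.e.
    the structural alpha-process precedes the faster delta-process when the
    faster branch lies on the high-frequency side).
    """

    sigma_dc: float
    eps_inf: float
    processes: List[HNProcess]
    temperature: float
    residual_rms: float = 0.0
    converged: bool = True
    message: str = ""

    def __post_init__(self):
        if self.sigma_dc < 0:
            raise ValueError("sigma_dc must be >= 0")
        if not (1 <= len(self.processes) <= 2):
            raise ValueError("need 1 or 2 HN processes")
        if not np.isfinite(self.residual_rms):
            raise ValueError("residual must be finite")
        self.processes = sorted(self.processes, key=tau_max, reverse=True)


def _hn_term(omega: np.ndarray, proc: HNProcess) -> np.ndarray:
    iwt = (1j * omega * proc.tau_hn) ** proc.alpha_hn
    return proc.delta_eps / (1.0 + iwt) ** proc.beta_hn


def hn_eps(omega, fit: HNFitResult) -> np.ndarray:
    """Complex permittivity eps*(omega) = eps' - i eps'' at angular frequency omega.

    Returned with the physics sign convention: ``.real`` is eps' and
    ``-.imag`` is the loss eps'' (always >= 0 for valid parameters).
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    out = np.full(omega.shape, fit.eps_inf, dtype=complex)
    for proc in fit.processes:
        out += _hn_term(omega, proc)
    out -= 1j * fit.sigma_dc / (EPS_VACUUM * omega)
    return out


def dielectric_loss(omega, fit: HNFitResult) -> np.ndarray:
    """Loss eps''(omega) of the full model (HN processes + DC term)."""
    return -hn_eps(omega, fit).imag


def tau_max(process: HNProcess) -> float:
    """Relaxation time at the loss-peak maximum of a single HN process.

        tau_max = tau_HN * [sin(pi a / (2 + 2b))]^(-1/a)
                         * [sin(pi a b / (2 + 2b))]^(1/a)

    reduces to tau_HN in the Debye limit a = b = 1.
    """
    a, b = process.alpha_hn, process.beta_hn
    s1 = np.sin(np.pi * a / (2.0 + 2.0 * b))
    s2 = np.sin(np.pi * a * b / (2.0 + 2.0 * b))
    return float(process.tau_hn * s1 ** (-1.0 / a) * s2 ** (1.0 / a))


def _initial_guess(spec: DielectricSpectrum, n_processes: int) -> dict:
    """Data-driven starting point: DC slope from the lowest frequencies,
    process positions from loss maxima after removing the DC estimate."""
    w = spec.omega
    loss = spec.eps_imag
    n_dc = min(5, len(w) // 4)
    sigma0 = float(np.median(loss[:n_dc] * EPS_VACUUM * w[:n_dc]))
    sigma0 = max(sigma0, 1e-30)
    rem = np.clip(loss - sigma0 / (EPS_VACUUM * w), 1e-12 * loss.max(), None)
    i1 = int(np.argmax(rem))
    tau1 = 1.0 / w[i1]
    deps1 = max(2.0 * rem[i1], 1e-6)
    guess = {
        "sigma": sigma0,
        "procs": [(deps1, tau1, 0.85, 0.6)],
    }
    if n_processes == 2:
        # secondary maximum at least one decade away from the primary
        far = np.abs(np.log10(w / w[i1])) > 1.0
        if far.any():
            masked = np.where(far, rem, -np.inf)
            i2 = int(np.argmax(masked))
        else:
            i2 = i1
        tau2 = 1.0 / w[i2] if i2 != i1 else tau1 / 1e3
        deps2 = max(2.0 * rem[i2] if i2 != i1 else deps1 / 20.0, 1e-6)
        guess["procs"].append((deps2, tau2, 0.9, 0.8))
    return guess


def fit_spectrum(
    spec: DielectricSpectrum,
    n_processes: int = 2,
    init: Optional[Sequence[HNProcess]] = None,
    sigma_init: Optional[float] = None,
    fit_real: bool = False,
    eps_inf: float = 3.0,
) -> HNFitResult:
    """Fit the loss spectrum with n HN processes plus a DC term.

    The default target is log10(eps'') (the loss spans decades, so a log
    residual weights all processes fairly); ``fit_real=True`` adds eps'
    residuals and lets eps_inf vary.  Strength, time and conductivity
    parameters are fitted in log10 space for conditioning.  The result is
    deterministic given the data and the starting point; non-convergence is
    flagged on the result rather than raised.
    """
    if len(spec.freq) < 20:
        raise ValueError("need at least 20 frequency points")
    if np.log10(spec.freq[-1] / spec.freq[0]) < 3:
        raise ValueError("spectrum must span at least 3 decades")
    if not (1 <= n_processes <= 2):
        raise ValueError("n_processes must be 1 or 2")
    if np.any(spec.eps_imag <= 0):
        raise ValueError("loss values must be positive to fit in log space")

    guess = _initial_guess(spec, n_processes)
    if init is not None:
        guess["procs"] = [
            (p.delta_eps, p.tau_hn, p.alpha_hn, p.beta_hn) for p in init
        ]
        if len(guess["procs"]) != n_processes:
            raise ValueError("init must supply one HNProcess per fitted process")
    if sigma_init is not None:
        guess["sigma"] = sigma_init

    w = spec.omega
    loss = spec.eps_imag
    params = lmfit.Parameters()
    params.add("lsig", value=np.log10(guess["sigma"]), min=-30, max=5)
    params.add("eps_inf", value=eps_inf, min=1.0, max=100.0, vary=fit_real)
    for i, (deps, tau, a, b) in enumerate(guess["procs"]):
        params.add(f"ldeps{i}", value=np.log10(deps), min=-6, max=6)
        params.add(f"ltau{i}", value=np.log10(tau), min=-12, max=6)
        params.add(f"alpha{i}", value=a, min=0.05, max=1.0)
        params.add(f"beta{i}", value=b, min=0.05, max=1.0)

    def build(p) -> HNFitResult:
        procs = [
            HNProcess(
                delta_eps=10.0 ** p[f"ldeps{i}"].value,
                tau_hn=10.0 ** p[f"ltau{i}"].value,
                alpha_hn=p[f"alpha{i}"].value,
                beta_hn=p[f"beta{i}"].value,
            )
            for i in range(n_processes)
        ]
        return HNFitResult(
            sigma_dc=10.0 ** p["lsig"].value,
            eps_inf=p["eps_inf"].value,
            processes=procs,
            temperature=spec.temperature,
        )

    def resid(p):
        model = build(p)
        r = np.log10(dielectric_loss(w, model)) - np.log10(loss)
        if fit_real and spec.eps_real is not None:
            r = np.concatenate([r, hn_eps(w, model).real - spec.eps_real])
        return r

    def attempt(par):
        res = _minimize_quiet(resid, par)
        return res, float(np.sqrt(np.mean(res.residual**2)))

    out, rms = attempt(params)
    if rms > 1e-3 and init is None:
        # deterministic multi-start: a peak hidden under the DC tail or at
        # the low-frequency edge defeats the subtraction-based initializer
        i_top = int(np.argmax(loss))
        for sig_scale, tau1 in (
            (0.1, 1.0 / w[i_top]),
            (0.1, 10.0 / w[0]),
            (1.0, 1.0 / w[0]),
        ):
            alt = params.copy()
            alt["lsig"].value = np.log10(guess["sigma"] * sig_scale)
            alt["ltau0"].value = np.log10(tau1)
            alt["ldeps0"].value = np.log10(max(2.0 * loss[i_top], 1e-6))
            out2, rms2 = attempt(alt)
            if rms2 < rms:
                out, rms = out2, rms2
            if rms < 1e-3:
                break
    fit = build(out.params)
    fit.residual_rms = rms
    fit.converged = bool(out.success)
    fit.message = str(out.message)
    return fit


def build_relaxation_map(fits: Sequence[HNFitResult]) -> pd.DataFrame:
    """Tabulate tau_max per process versus temperature.

    The slower branch (structural alpha-relaxation, rotation about the long
    molecular axis) and the faster delta-branch (reorientation about the
    short axis) are tracked across temperatures by continuity in log tau;
    a row is flagged when the two branches approach within a fifth of a
    decade and the assignment becomes ambiguous.
    """
    if len(fits) == 0:
        raise ValueError("need at least one fit")
    rows = []
    for fit in sorted(fits, key=lambda f: f.temperature):
        taus = sorted((tau_max(p) for p in fit.processes), reverse=True)
        t_alpha = taus[0]
        t_delta = taus[1] if len(taus) > 1 else np.nan
        flagged = (
            len(taus) > 1 and abs(np.log10(t_alpha / t_delta)) < 0.2
        )
        rows.append(
            {
                "temperature": fit.temperature,
                "tau_alpha": t_alpha,
                "tau_delta": t_delta,
                "flagged": flagged,
            }
        )
    df = pd.DataFrame(rows)
    # continuity check across temperatures on the alpha branch
    la = np.log10(df["tau_alpha"].to_numpy())
    jumps = np.abs(np.diff(la))
    if len(jumps) >= 2:
        typical = np.median(jumps) + 1e-12
        bad = np.flatnonzero(jumps > 5 * typical + 1.0) + 1
        df.loc[df.index[bad], "flagged"] = True
    return df


@dataclass(frozen=True)
class VFTFit:
    """Vogel-Fulcher-Tammann parameters with the derived Tg (tau = 100 s)."""

    tau_inf: float  # seconds
    B: float  # Kelvin
    T0: float  # Kelvin (Vogel temperature)
    tg: float = field(init=False)

    def __post_init__(self):
        if self.tau_inf <= 0 or self.B <= 0:
            raise ValueError("tau_inf and B must be positive")
        object.__setattr__(self, "tg", tg_from_vft_params(self.tau_inf, self.B, self.T0))

    def tau(self, temperature) -> np.ndarray:
        temperature = np.asarray(temperature, dtype=float)
        if np.any(temperature <= self.T0):
            raise ValueError("temperature must exceed T0")
        return self.tau_inf * np.exp(self.B / (temperature - self.T0))


def tg_from_vft_params(tau_inf: float, B: float, T0: float, tau_ref: float = 100.0) -> float:
    if tau_inf >= tau_ref:
        raise ValueError("tau_inf must be below tau_ref for Tg to exist")
    return T0 + B / np.log(tau_ref / tau_inf)


def tg_from_vft(fit: VFTFit, tau_ref: float = 100.0) -> float:
    """Temperature at which the extrapolated relaxation time equals tau_ref."""
    return tg_from_vft_params(fit.tau_inf, fit.B, fit.T0, tau_ref)


def fit_vft(temperatures, taus) -> VFTFit:
    """Fit tau(T) = tau_inf exp(B/(T - T0)) by least squares on log tau.

    A coarse scan over T0 (with the linear ln tau vs 1/(T - T0) fit solved
    exactly at each trial) supplies the starting point; a bounded
    least-squares refinement follows.  Requires >= 4 (T, tau) pairs.
    """
    T = np.asarray(temperatures, dtype=float)
    tau = np.asarray(taus, dtype=float)
    if T.shape != tau.shape or T.ndim != 1:
        raise ValueError("temperatures and taus must be 1-D of equal length")
    if len(T) < 4:
        raise ValueError("need at least 4 (T, tau) pairs")
    if np.any(tau <= 0) or np.any(T <= 0):
        raise ValueError("temperatures and taus must be positive")
    order = np.argsort(T)
    T, tau = T[order], tau[order]
    ln_tau = np.log(tau)
    t_min = T.min()

    best = None
    for t0 in np.arange(0.0, t_min - 5.0, 0.5):
        x = 1.0 / (T - t0)
        A = np.vstack([np.ones_like(x), x]).T
        coef, res, *_ = np.linalg.lstsq(A, ln_tau, rcond=None)
        sse = float(res[0]) if len(res) else float(np.sum((A @ coef - ln_tau) ** 2))
        if coef[1] > 0 and (best is None or sse < best[0]):
            best = (sse, coef[0], coef[1], t0)
    if best is None:
        raise ValueError("degenerate tau(T) data: no VFT curvature found")
    _, ln_tinf0, b0, t00 = best

    params = lmfit.Parameters()
    params.add("ln_tau_inf", value=ln_tinf0, min=-80, max=np.log(tau.max()))
    params.add("B", value=b0, min=1e-6)
    params.add("T0", value=t00, min=0.0, max=t_min - 1e-3)

    def resid(p):
        return p["ln_tau_inf"] + p["B"] / (T - p["T0"]) - ln_tau

    out = lmfit.minimize(
        resid, params, method="least_squares", calc_covar=False,
            xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    pv = out.params
    return VFTFit(
        tau_inf=float(np.exp(pv["ln_tau_inf"].value)),
        B=float(pv["B"].value),
        T0=float(pv["T0"].value),
    )
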