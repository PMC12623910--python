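"""Reduction of raw scattering patterns to S(Q) and the pair distribution function.

The chain implemented here mirrors standard total-scattering practice for
disordered molecular solids:

1. optional polarization correction and 2-theta -> Q conversion
   (Q = 4 pi sin(theta) / lambda);
2. normalization to electron units against the composition's self-scattering
   level over a high-Q window (default 4-20 1/A), where only the
   intramolecular structure contributes;
3. conversion to the structure factor

       S(Q) = [I(Q) - (<f^2> - <f>^2)] / <f>^2,

   with I(Q) the coherent intensity in electron units;
4. sine Fourier transform to the reduced pair distribution function

       G(r) = (2/pi) * int_0^Qmax  Q [S(Q) - 1] W(Q) sin(Q r) dQ,

   with the window W(Q) = sin(pi Q / Qmax) / (pi Q / Qmax) suppressing
   termination ripples;
5. a thresholded-envelope estimate of the structural coherence length from
   the extent of the G(r) oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Tuple

import numpy as np

from .composition import Composition, incoherent_intensity, mean_f, mean_f2

__all__ = [
    "ScatteringPattern",
    "StructureFactor",
    "PDFCurve",
    "CoherenceResult",
    "two_theta_to_q",
    "polarization_factor",
    "correct_polarization",
    "normalize_high_q",
    "to_structure_factor",
    "lorch_window",
    "pdf_transform",
    "default_r_grid",
    "coherence_length",
]


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains NaN or infinite values")
    return arr


@dataclass
class ScatteringPattern:
    """A 1-D scattering pattern I(Q) on a strictly ascending Q grid (1/A)."""

    q: np.ndarray
    intensity: np.ndarray
    wavelength: Optional[float] = None  # Angstrom; needed only for 2theta work
    label: str = ""

    def __post_init__(self):
        self.q = _as_array(self.q, "q")
        self.intensity = _as_array(self.intensity, "intensity")
        if len(self.q) != len(self.intensity):
            raise ValueError("q and intensity must have equal length")
        if len(self.q) < 16:
            raise ValueError("pattern must contain at least 16 points")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.wavelength is not None and self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


@dataclass
class StructureFactor:
    """Structure factor S(Q); ``qmax`` is the Fourier-transform upper limit."""

    q: np.ndarray
    s: np.ndarray
    qmax: float = field(default=0.0)
    label: str = ""

    def __post_init__(self):
        self.q = _as_array(self.q, "q")
        self.s = _as_array(self.s, "s")
        if len(self.q) != len(self.s):
            raise ValueError("q and s must have equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if not self.qmax:
            self.qmax = float(self.q[-1])


@dataclass
class PDFCurve:
    """Reduced pair distribution function G(r) = 4 pi r [rho(r) - rho0].

    ``number_density`` (atoms/A^3) is interpretive metadata only; G(r) is
    produced by the sine transform, never via rho(r).
    """

    r: np.ndarray
    g: np.ndarray
    number_density: Optional[float] = None
    label: str = ""

    def __post_init__(self):
        self.r = _as_array(self.r, "r")
        self.g = _as_array(self.g, "g")
        if len(self.r) != len(self.g):
            raise ValueError("r and g must have equal length")
        if len(self.r) < 2 or self.r[0] < 0:
            raise ValueError("r grid must start at >= 0 with >= 2 points")
        dr = np.diff(self.r)
        if np.any(dr <= 0) or not np.allclose(dr, dr[0], rtol=1e-8):
            raise ValueError("r grid must be uniform and ascending")


def two_theta_to_q(two_theta, wavelength: float) -> np.ndarray:
    """Convert scattering angle 2-theta (degrees) to Q = 4 pi sin(theta)/lambda."""
    tt = np.asarray(two_theta, dtype=float)
    if np.any((tt < 0) | (tt >= 180)):
        raise ValueError("2theta must lie in [0, 180) degrees")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return 4.0 * np.pi * np.sin(np.radians(tt / 2.0)) / wavelength


def polarization_factor(two_theta, monochromator_two_theta: float = 0.0) -> np.ndarray:
    """Unpolarized-beam polarization factor, optionally with a monochromator.

    P = (1 + cos^2(2theta_m) cos^2(2theta)) / (1 + cos^2(2theta_m)); with no
    monochromator (2theta_m = 0) this is the familiar (1 + cos^2 2theta)/2.
    """
    tt = np.radians(np.asarray(two_theta, dtype=float))
    cm2 = np.cos(np.radians(monochromator_two_theta)) ** 2
    return (1.0 + cm2 * np.cos(tt) ** 2) / (1.0 + cm2)


def correct_polarization(
    pattern: ScatteringPattern, monochromator_two_theta: float = 0.0
) -> ScatteringPattern:
    """Divide out the polarization factor (requires pattern.wavelength)."""
    if pattern.wavelength is None:
        raise ValueError("polarization correction requires a wavelength")
    sin_theta = pattern.q * pattern.wavelength / (4.0 * np.pi)
    if np.any(sin_theta > 1.0):
        raise ValueError("Q grid inconsistent with wavelength (sin theta > 1)")
    two_theta = 2.0 * np.degrees(np.arcsin(sin_theta))
    p = polarization_factor(two_theta, monochromator_two_theta)
    return ScatteringPattern(
        q=pattern.q, intensity=pattern.intensity / p,
        wavelength=pattern.wavelength, label=pattern.label,
    )


def _self_scattering(comp: Composition, q, include_incoherent: bool) -> np.ndarray:
    target = mean_f2(comp, q)
    if include_incoherent:
        target = target + incoherent_intensity(comp, q)
    return target


def normalize_high_q(
    pattern: ScatteringPattern,
    comp: Composition,
    q_window: Tuple[float, float] = (4.0, 20.0),
    include_incoherent: bool = True,
    method: str = "mean",
) -> Tuple[ScatteringPattern, float]:
    """Rescale a pattern to electron units against the self-scattering level.

    At high Q the structure factor oscillates around 1, so the measured
    intensity there is proportional to <f^2>(Q) (plus the incoherent part if
    it has not been removed).  The default ``"mean"`` method matches the mean
    intensity over ``q_window`` to the mean of the target curve; the
    ``"krogh-moe"`` method matches Q^2-weighted integrals instead.

    Returns the rescaled pattern and the scale factor applied.
    """
    lo, hi = q_window
    if hi <= lo:
        raise ValueError("q_window must be (low, high) with low < high")
    mask = (pattern.q >= lo) & (pattern.q <= hi)
    if mask.sum() < 2:
        raise ValueError("pattern does not intersect the normalization window")
    covered = pattern.q[mask][-1] - pattern.q[mask][0]
    if covered < 0.5 * (hi - lo):
        raise ValueError(
            f"pattern covers only {covered:.2f} of the {hi - lo:.2f} wide "
            "normalization window (need at least half)"
        )
    qw = pattern.q[mask]
    target = _self_scattering(comp, qw, include_incoherent)
    if method == "mean":
        scale = np.trapezoid(target, qw) / np.trapezoid(pattern.intensity[mask], qw)
    elif method == "krogh-moe":
        scale = np.trapezoid(qw**2 * target, qw) / np.trapezoid(
            qw**2 * pattern.intensity[mask], qw
        )
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    out = ScatteringPattern(
        q=pattern.q, intensity=pattern.intensity * scale,
        wavelength=pattern.wavelength, label=pattern.label,
    )
    return out, float(scale)


def to_structure_factor(
    pattern_eu: ScatteringPattern,
    comp: Composition,
    incoherent: str = "none",
    qmax: Optional[float] = None,
) -> StructureFactor:
    """Apply S(Q) = [I(Q) - (<f^2> - <f>^2)] / <f>^2 pointwise.

    ``pattern_eu`` must already be in electron units.  With
    ``incoherent="subtract"`` the package's Compton estimate is removed
    first; ``"none"`` assumes the intensity is already purely coherent.
    """
    if incoherent not in ("none", "subtract"):
        raise ValueError("incoherent must be 'none' or 'subtract'")
    q = pattern_eu.q
    intensity = pattern_eu.intensity.astype(float)
    if incoherent == "subtract":
        intensity = intensity - incoherent_intensity(comp, q)
    f_mean = mean_f(comp, q)
    f2_mean = mean_f2(comp, q)
    denom = f_mean**2
    if np.any(denom <= 0):
        raise ValueError("<f>^2 vanishes on the grid; unphysical composition")
    s = (intensity - (f2_mean - denom)) / denom
    return StructureFactor(q=q, s=s, qmax=qmax or float(q[-1]), label=pattern_eu.label)


def lorch_window(q, qmax: float) -> np.ndarray:
    """Termination window W(Q) = sin(pi Q/Qmax) / (pi Q/Qmax) on [0, Qmax]."""
    q = np.asarray(q, dtype=float)
    if qmax <= 0:
        raise ValueError("qmax must be positive")
    if np.any((q < 0) | (q > qmax * (1 + 1e-12))):
        raise ValueError("Q must lie within [0, Qmax]")
    x = np.pi * q / qmax
    return np.sinc(x / np.pi)  # numpy sinc(x) = sin(pi x)/(pi x)


def default_r_grid(r_max: float = 200.0, dr: float = 0.02) -> np.ndarray:
    """Default real-space grid: 0-200 A in 0.02 A steps.

    Fine enough to resolve the lamellar oscillation period (~30 A) and long
    enough to follow PDF attenuation out beyond 150 A.
    """
    n = int(round(r_max / dr))
    return np.linspace(0.0, r_max, n + 1)


def pdf_transform(
    sf: StructureFactor,
    r: Optional[np.ndarray] = None,
    window: bool = True,
    qmax: Optional[float] = None,
    chunk: int = 2048,
) -> PDFCurve:
    """Sine Fourier transform of S(Q) to G(r).

    Trapezoidal quadrature of (2/pi) Q [S-1] W(Q) sin(Qr) on the native
    (possibly non-uniform) Q grid, truncated at ``qmax`` (default: the
    structure factor's own Qmax).  ``window=False`` disables W(Q).
    """
    if r is None:
        r = default_r_grid()
    r = _as_array(r, "r")
    if len(r) == 0 or len(sf.q) < 2:
        raise ValueError("empty r or Q grid")
    qmax = float(qmax if qmax is not None else sf.qmax)
    mask = sf.q <= qmax * (1 + 1e-12)
    q = sf.q[mask]
    if len(q) < 2:
        raise ValueError("no Q points below qmax")
    dev = sf.s[mask] - 1.0
    integrand = q * dev
    if window:
        integrand = integrand * lorch_window(q, qmax)
    # trapezoid weights on the native grid
    w = np.empty_like(q)
    w[0] = 0.5 * (q[1] - q[0])
    w[-1] = 0.5 * (q[-1] - q[-2])
    w[1:-1] = 0.5 * (q[2:] - q[:-2])
    weighted = integrand * w
    g = np.empty_like(r)
    for start in range(0, len(r), chunk):
        rr = r[start : start + chunk]
        g[start : start + chunk] = np.sin(np.outer(rr, q)) @ weighted
    g *= 2.0 / np.pi
    return PDFCurve(r=r, g=g, label=sf.label)


class CoherenceResult(NamedTuple):
    """Coherence length estimate from PDF attenuation."""

    length: float  # Angstrom
    attenuated: bool  # False if oscillations persist to the end of the grid
    threshold_value: float  # absolute |G| level used as the cutoff


def coherence_length(
    pdf: PDFCurve,
    r_min: float = 10.0,
    threshold: float = 0.05,
    window_width: float = 5.0,
) -> CoherenceResult:
    """Spatial extent of G(r) oscillations (the structural coherence length).

    The estimate is the largest r >= ``r_min`` at which |G| still reaches
    ``threshold`` times the maximum |G| of the whole curve; beyond it every
    rolling window of ``window_width`` stays below the cutoff.  If the
    oscillations have not dropped below the cutoff at least ``window_width``
    before the end of the grid the result is flagged as not attenuated and
    the upper grid bound is returned.
    """
    if pdf.r[-1] < r_min + window_width:
        raise ValueError("PDF must extend beyond r_min + window_width")
    abs_g = np.abs(pdf.g)
    ref = abs_g.max()
    if ref == 0:
        raise ValueError("coherence length undefined for an all-zero PDF")
    cut = threshold * ref
    beyond = pdf.r >= r_min
    exceed = np.flatnonzero(beyond & (abs_g >= cut))
    if len(exceed) == 0:
        return CoherenceResult(float(r_min), True, float(cut))
    r_last = float(pdf.r[exceed[-1]])
    if r_last > pdf.r[-1] - window_width:
        return CoherenceResult(float(pdf.r[-1]), False, float(cut))
    return CoherenceResult(r_last, True, float(cut))
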