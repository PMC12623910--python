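"""Lamellar (00l) peak analysis: positions, d-spacings, amplitudes, widths.

Fits pseudo-Voigt profiles to the smectic reflections of both sample
presets, converts positions to repeat distances via d = 2 pi l / Q, and
compares the (002) amplitudes (the study's measure of how well the layers
are developed).  Also demonstrates the Gaussian-offset model for the
(002)/(001) intensity ratio of a 1-D layer stack.
"""

import mesokit as mk
from mesokit.peaks import (
    d_spacing,
    detect_peaks,
    fit_peaks,
    label_harmonics,
    lamellar_intensity_ratio,
)
from mesokit.reduction import normalize_high_q, to_structure_factor

comp = mk.parse_formula(mk.ITZ_FORMULA)
amps = {}
for name in ("V-ITZ", "SE-ITZ-20"):
    sim = mk.generate_pattern(mk.diffraction_preset(name), comp=comp)
    pattern_eu, _ = normalize_high_q(sim.pattern, comp)
    sf = to_structure_factor(pattern_eu, comp, incoherent="subtract", qmax=20.0)
    centers = detect_peaks(sf.q, sf.s, q_window=(0.17, 0.85), min_prominence=0.02)
    fit = label_harmonics(fit_peaks(sf.q, sf.s, centers, q_window=(0.17, 0.85)))
    print(f"{name}:")
    for p in fit.peaks:
        print(f"  ({p.label}) Q = {p.center:.3f} 1/A  d = {p.d_spacing():.1f} A  "
              f"height = {p.amplitude:.2f}  FWHM = {p.fwhm:.4f} 1/A")
    amps[name] = fit.peak("002").amplitude

print(f"\n(002) amplitude ratio V-ITZ : SE-ITZ-20 = 1 : "
      f"{amps['SE-ITZ-20'] / amps['V-ITZ']:.1f}")
print(f"halo at Q = 1.35 1/A -> intermolecular distance {d_spacing(1.35):.2f} A")

print("\nGaussian-offset model (how intralayer molecular offsets suppress (002)):")
for sigma in (0.0, 1.0, 2.0, 3.0):
    ratio = lamellar_intensity_ratio(sigma, d=29.2, f1=1.0, f2=0.8)
    print(f"  offset sigma = {sigma:.0f} A -> I(002)/I(001) = {ratio:.3f}")
print("Smaller random offsets (tighter layers) raise the second harmonic —")
print("the signature of enhanced smectic order in solvent-evaporated samples.")
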