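# mesokit

Characterization of smectic liquid-crystalline order in glassy drug solids
from wide-angle X-ray scattering (WAXS) and broadband dielectric
spectroscopy, built around itraconazole (ITZ, C₃₅H₃₈Cl₂N₈O₄,
705.64 g/mol) — a rod-like antifungal that forms lamellar mesophases when
vitrified from the melt or recovered by rapid solvent evaporation from
dichloromethane/chloroform solutions.

The package is for solid-state pharmaceutics and soft-matter scattering
people who need a reproducible, testable implementation of the full
analysis chain rather than one-off spreadsheet reductions:

1. **Reduction** — raw I(Q) patterns (Q = 4π sin θ/λ) are normalized to
   electron units against the composition's self-scattering level over the
   high-Q window (4–20 Å⁻¹), converted to the structure factor

       S(Q) = [I(Q) − (⟨f²⟩ − ⟨f⟩²)] / ⟨f⟩²,

   with Cromer–Mann form factors ⟨f⟩, ⟨f²⟩ and an analytic Compton
   estimate, and sine-transformed to the reduced pair distribution function

       G(r) = (2/π) ∫₀^Qmax Q [S(Q) − 1] W(Q) sin(Qr) dQ,   Qmax = 20 Å⁻¹,

   with the termination window W(Q) = sin(πQ/Qmax)/(πQ/Qmax).  The spatial
   extent of the G(r) oscillations yields the **structural coherence
   length** of the smectic stack.
2. **Lamellar peak analysis** — pseudo-Voigt fits of the (00l) quasi-Bragg
   harmonics at Q_l = 2πl/d and of the intermolecular halo (~1.35 Å⁻¹),
   d-spacings d = 2πl/Q, FWHM, amplitude ratios, a two-component (002)
   decomposition, and a Gaussian-offset model for the (002)/(001)
   intensity ratio of a 1-D layer stack.
3. **Dielectric analysis** — per-temperature loss spectra fitted with two
   Havriliak–Negami processes plus DC conductivity,

       ε*(ω) = ε∞ + Σᵢ Δεᵢ/[1 + (iωτ_HN,i)^αᵢ]^βᵢ − i σ_DC/(ε_f ω),

   relaxation maps τ_max(T) for the structural α-process and the faster
   δ-process, Vogel–Fulcher–Tammann fits τ = τ∞ exp[B/(T − T₀)], and the
   glass-transition temperature read at τ_α = 100 s.
4. **Synthetic data** — seeded generators for smectic/crystalline
   diffraction patterns and dielectric temperature series with complete
   ground truth, including presets calibrated to the study samples
   (vitrified "V-ITZ" and solvent-evaporated "SE-ITZ-20").

## Worked example

```python
import mesokit as mk
from mesokit.reduction import (normalize_high_q, to_structure_factor,
                               pdf_transform, default_r_grid, coherence_length)

comp = mk.parse_formula(mk.ITZ_FORMULA)
for name in ("V-ITZ", "SE-ITZ-20"):
    sim = mk.generate_pattern(mk.diffraction_preset(name), comp=comp)
    pattern_eu, scale = normalize_high_q(sim.pattern, comp)
    sf = to_structure_factor(pattern_eu, comp, incoherent="subtract", qmax=20.0)
    pdf = pdf_transform(sf, r=default_r_grid(), window=True, qmax=20.0)
    coh = coherence_length(pdf)
    print(f"{name}: coherence length {coh.length:.1f} A")
```

prints

```
V-ITZ: coherence length 70.0 A
SE-ITZ-20: coherence length 150.8 A
```

i.e. the vitrified glass keeps layer correlations over ~70 Å while the
solvent-evaporated particles stay correlated out to ~150 Å — the central
structural contrast between the two preparation routes.  The dielectric
side of the same comparison (`examples/dielectric_tg.py`) prints
Tg = 326.4 K for V-ITZ and 324.2 K for SE-ITZ-20: the longer-range-ordered
material is nonetheless the more mobile one near the glass transition.

The `examples/` directory holds one short narrative script per capability
(reduction → PDF, lamellar peak analysis, dielectric Tg extraction,
writing synthetic datasets to disk).  A thin CLI mirrors the chain:

```bash
mesokit simulate SE-ITZ-20 --out data/
mesokit reduce data/SE-ITZ-20.xy --out data/se20.sq
mesokit pdf data/se20.sq --out data/se20.gr
mesokit peaks data/se20.sq --out data/se20.peaks.json
```

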