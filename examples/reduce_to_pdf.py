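"""WAXS reduction walkthrough: raw intensity -> S(Q) -> G(r) -> coherence length.

Generates the solvent-evaporated and vitrified sample presets, normalizes
each pattern to electron units over the 4-20 1/A window, applies
S(Q) = [I - (<f^2> - <f>^2)]/<f>^2, sine-transforms to the PDF with the
termination window, and reads the coherence length off the attenuation of
the G(r) oscillations.
"""

import mesokit as mk
from mesokit.reduction import (
    coherence_length,
    default_r_grid,
    normalize_high_q,
    pdf_transform,
    to_structure_factor,
)

comp = mk.parse_formula(mk.ITZ_FORMULA)

for name in ("V-ITZ", "SE-ITZ-20"):
    sim = mk.generate_pattern(mk.diffraction_preset(name), comp=comp)
    pattern_eu, scale = normalize_high_q(sim.pattern, comp)
    sf = to_structure_factor(pattern_eu, comp, incoherent="subtract", qmax=20.0)
    pdf = pdf_transform(sf, r=default_r_grid(), window=True, qmax=20.0)
    coh = coherence_length(pdf)
    print(f"{name}: electron-unit scale {scale:.3f}, "
          f"coherence length {coh.length:.1f} A (attenuated: {coh.attenuated})")

print()
print("The vitrified glass keeps smectic order over ~70 A; the")
print("solvent-evaporated particles stay layer-correlated out to ~150 A —")
print("the longer the PDF oscillations persist, the better developed the")
print("lamellar stack.")
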