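"""Dielectric analysis walkthrough: loss spectra -> HN fits -> VFT -> Tg.

Generates per-temperature loss spectra for both sample presets (two
Havriliak-Negami processes + DC conductivity), fits each spectrum, builds
the relaxation map tau(T) for the structural alpha-process and the faster
delta-process, fits the Vogel-Fulcher-Tammann law, and extrapolates to the
glass-transition temperature where tau_alpha = 100 s.
"""

import mesokit as mk
from mesokit.dielectric import build_relaxation_map, fit_spectrum, fit_vft

for name in ("V-ITZ", "SE-ITZ-20"):
    series = mk.generate_dielectric_series(mk.dielectric_preset(name))
    fits = [fit_spectrum(spec, n_processes=2) for spec in series.spectra]
    rmap = build_relaxation_map(fits)
    vft = fit_vft(rmap["temperature"].to_numpy(), rmap["tau_alpha"].to_numpy())
    print(f"{name}:")
    for _, row in rmap.iloc[::4].iterrows():
        print(f"  T = {row['temperature']:.0f} K  tau_alpha = {row['tau_alpha']:.2e} s"
              f"  tau_delta = {row['tau_delta']:.2e} s")
    print(f"  VFT: tau_inf = {vft.tau_inf:.2e} s, B = {vft.B:.0f} K, "
          f"T0 = {vft.T0:.1f} K")
    print(f"  Tg (tau_alpha = 100 s) = {vft.tg:.1f} K\n")

print("The solvent-evaporated sample relaxes faster near Tg (shorter")
print("tau_alpha) and has a ~2 K lower glass-transition temperature than the")
print("vitrified glass — more mobile despite its longer-ranged smectic order.")
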