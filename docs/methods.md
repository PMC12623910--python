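# Methods

This note documents the models, conventions, numerical choices and
limitations behind `mesokit`, in the spirit of a methods appendix.

## Scattering conventions and composition quantities

All reciprocal-space coordinates are Q = 4π sin θ/λ in Å⁻¹ (θ half the
scattering angle); real space is r in Å.  Grids are values at points, not
bins, on closed intervals.

Coherent atomic form factors use the four-Gaussian Cromer–Mann
parameterisation f(s) = Σⱼ aⱼ exp(−bⱼs²) + c with s = Q/4π, coefficients
for H, C, N, O, P, S, Cl shipped as `data/elements.csv` (International
Tables Vol. C values; each satisfies |f(0) − Z| ≤ 0.2).  The
parameterisation is physical only up to s ≈ 2; the incoherent model clamps
f to [0, Z] so extreme-Q evaluations stay sane.  Composition averages are
⟨f⟩ = Σ cᵢfᵢ and ⟨f²⟩ = Σ cᵢfᵢ², with cᵢ the atomic fractions parsed from
a chemical formula.

Incoherent (Compton) scattering is modelled per element as
(Z − f²/Z)(1 − exp(−k Q^p)) — zero at Q = 0, approaching the free-electron
limit Z from below.  The two coefficients (k, p) per element were chosen
once to follow the qualitative saturation of tabulated Compton profiles
(hydrogen saturates fastest, chlorine slowest).  This is deliberately a
smooth analytic stand-in: synthetic data are generated and corrected with
the same model, so the reduction plumbing is exercised exactly, and a
`"none"` mode exists for intensities that are already Compton-corrected.
The model's absolute accuracy against measured Compton cross sections is
untested and does not matter for any quantity the package reports.

## Electron-unit normalization and S(Q)

Above ~4 Å⁻¹ the structure factor of a molecular solid oscillates around 1,
so the measured intensity there is proportional to ⟨f²⟩ (+ incoherent).
The default normalization matches trapezoid means of I(Q) and of the target
curve over the 4–20 Å⁻¹ window (a single multiplicative factor); a
Krogh-Moe/Norman-style mode matching Q²-weighted integrals is available.
Which of the two a given laboratory used for the original data is usually
unstated; both are provided and the choice is a config option, defaulting
to the windowed mean.  The structure factor is then the pointwise formula
S = [I − (⟨f²⟩ − ⟨f⟩²)]/⟨f⟩² on coherent electron-unit intensity.  An
optional unpolarized-beam/monochromator polarization pre-correction is
provided; absorption correction is out of scope (synthetic data carry
none).

## PDF transform

G(r) = (2/π) ∫₀^Qmax Q[S−1] W(Q) sin(Qr) dQ is evaluated by trapezoidal
quadrature directly on the native Q grid (the trapezoid rule needs no
uniform spacing, so no resampling step is introduced), with
W(Q) = sinc(πQ/Qmax) and Qmax defaulting to 20 Å⁻¹, the upper limit of the
measured range.  The default r grid is 0–200 Å in 0.02 Å steps — fine
enough to resolve the ~29 Å lamellar period and long enough to follow
attenuation past 150 Å.  The implementation is verified against an
independent direct-sum quadrature oracle to < 1e−10 and is exactly linear
in S − 1.

## Coherence length

The coherence length is defined as the largest r ≥ r_min (default 10 Å) at
which |G| still reaches a threshold fraction (default 5%) of the maximum
|G| of the curve; beyond it every rolling window (default 5 Å) stays below
the cutoff.  If the oscillations persist to within one window of the end
of the grid, the result is flagged "not attenuated".  On an exponentially
damped sinusoid G = sin(2πr/30)e^(−r/ξ) this estimator tracks the envelope
crossing ξ·ln 20 to within one window width for ξ = 10–60 Å.  Two caveats
are inherent to any threshold criterion: (i) the reading can only land on
local maxima of |G|, so for strictly periodic content it is quantized to
the oscillation comb (~7 Å spacing for a dominant 0.43 Å⁻¹ component); and
(ii) the reference amplitude includes the large short-range correlations
at low r, which is what makes 5% a reasonable default.  Threshold, r_min
and window width are exposed as configuration.

## Lamellar peaks

Reflections are fitted as pseudo-Voigt profiles (height-parameterised,
shared FWHM between the Gaussian and Lorentzian parts, mixing η ∈ [0, 1])
over a local polynomial baseline of degree ≤ 2 (linear by default —
the diffuse background varies slowly over 0.1 Å⁻¹ windows).  A pseudo-Voigt
was chosen because the true profile is unknown; it subsumes both limiting
shapes.  "Amplitude" means baseline-subtracted peak height (the integrated
area is also available); amplitude comparisons across samples are only
meaningful after the common high-Q normalization.  d-spacings use
d = 2πl/Q, computed as l·(2π/Q) so harmonic linearity is exact in floating
point.  A Scherrer-like 2π/FWHM coherence estimate is provided as a
convenience, but the PDF-based estimator is authoritative.  The
two-component (002) decomposition fits sharp + broad profiles with the
broad width structurally constrained to exceed the sharp width (broad FWHM
= sharp FWHM × factor ≥ 1) and is started from both orderings of the
initial centers, keeping the lower-residual solution.

The (002)/(001) intensity-ratio model treats the layer stack as a 1-D
electron-density profile with Fourier amplitudes |F₁|, |F₂| and Gaussian
random molecular offsets of r.m.s. σ along the layer normal, which act as
a Debye–Waller factor: I₂/I₁ = |F₂/F₁|² exp[−(Q₂² − Q₁²)σ²].  This is the
qualitative mechanism by which tighter layers boost the second harmonic; a
quantitative density-modulation refinement is out of scope.

## Dielectric model and fitting

The permittivity model is ε* = ε∞ + Σᵢ Δεᵢ/[1 + (iωτ_HN,i)^αᵢ]^βᵢ − i
σ_DC/(ε_f ω) with ε_f = 8.8541878128e−12 F/m fixed.  The DC term is
implemented as purely imaginary (ohmic conduction contributes only loss);
writing it into complex ε* would imply a diverging real part at low
frequency.  Fits target log₁₀ ε″ (the loss spans decades; a log residual
weights both processes fairly), with an optional simultaneous ε′/ε″ mode
behind a flag.  Strengths, times and conductivity are fitted in log₁₀
space, shapes bounded to (0.05, 1].  Initialization is data-driven: σ_DC
from the five lowest frequencies, the primary process from the loss
maximum after removing the DC estimate; when that start leaves a large
residual (e.g. an α-peak buried under the DC tail at the lowest
temperatures) a small fixed set of alternative starts is tried and the
best kept, so the procedure remains deterministic.  Non-convergence flags
the result instead of raising.

Reported relaxation times are τ_max, the loss-peak time,
τ_max = τ_HN [sin(πα/(2+2β))]^(−1/α) [sin(παβ/(2+2β))]^(1/α) (equal to
τ_HN in the Debye limit); τ_HN is stored alongside since conventions vary.
Relaxation maps assign the slower branch to the structural α-process
(rotation about the long molecular axis) and the faster branch to the
δ-process (reorientation about the short axis), flagging temperatures
where the branches approach within 0.2 decade and tracking continuity of
log τ_α across temperatures.

VFT fits of τ(T) = τ∞ exp[B/(T − T₀)] run a coarse scan over T₀ (solving
the then-linear ln τ vs 1/(T − T₀) problem exactly at each trial) followed
by bounded least squares on ln τ.  Tg is T₀ + B/ln(τ_ref/τ∞) with
τ_ref = 100 s; τ∞ ≥ τ_ref is rejected as having no solution.

## Synthetic data: what it emulates, and what it does not

The diffraction generator builds S(Q) = 1 + lamellar peaks + halo and
converts it to measurable intensity I = scale·[⟨f⟩²S + (⟨f²⟩ − ⟨f⟩²) +
I_inc], optionally with Poisson counting noise on a counts scale
(image-plate-like statistics without a detector model).  Lamellar peaks
are Lorentzian with FWHM = 2/ξ, the exact Fourier pair of an e^(−r/ξ)
decay of the PDF oscillations, so the coherence estimator is testable in
closed form; the lamellar sum is tapered smoothly to zero between 1.5 and
2.5 Å⁻¹ and the halo is Gaussian, so that the intensity above 4 Å⁻¹ equals
the self-scattering level exactly and normalization round-trips to machine
precision.  Crystalline control patterns use resolution-limited
(FWHM = 0.01 Å⁻¹) Gaussian peaks; a peak-width classifier (threshold
0.02 Å⁻¹) separates them from the ≥ 0.028 Å⁻¹ quasi-Bragg peaks of the
liquid-crystalline presets.

The calibrated presets encode the study contrasts: one lamellar
periodicity d = 29.22 Å (fundamental 0.215 Å⁻¹ — the closest single
harmonic series to the reported 0.21/0.43/0.65 positions, which round to
two decimals), halo at 1.35 Å⁻¹, (002) heights 2.0 (V-ITZ) vs 6.0
(SE-ITZ-20) fixing the 1:3 amplitude ratio, and damping ξ = 52 vs 70 Å,
calibrated once so the full pipeline reads coherence lengths of ~70 and
~150 Å.  The V-ITZ preset is (002)-dominated — emulating the measured
pattern, in which the (001) is largely cut by the beam stop and the (003)
of the weakest-ordered sample is below detection.  Because both presets
share one periodicity, the reported 28-vs-29 Å distinction between the
vitrified and solvent-evaporated (002) positions is exercised through the
d-spacing operation on the printed Q values, not through the presets.

The dielectric generator forward-models two HN processes + DC at each
temperature (337–361 K in 3 K steps, 0.1–10⁶ Hz, 10 points/decade —
matching the measurement window while stopping below the temperatures
where the real samples crystallize).  The α-process peak time follows a
VFT law anchored to the target Tg (326.4 K for V-ITZ with T₀ = 270 K,
324.2 K for SE-ITZ-20 with T₀ = 268 K, τ∞ = 1e−14 s); the generator
converts τ_max to τ_HN through the fixed shape parameters (α = 0.88,
β = 0.52), so fitted peak times land exactly on the law.  The δ-process is
near-Debye (α = 0.95, β = 1), Arrhenius with τ∞ = 1e−12 s and B = 5500–
5600 K, 1.2–4 decades faster than α across the range.  Δε(T) declines
mildly with temperature and σ_DC(T) is Arrhenius — plausible magnitudes
for a polar rod-like glass-former; the true temperature dependences of
these quantities for ITZ are not tabulated and the values are explicit
placeholders.

What passing tests therefore demonstrate: the reduction, transform,
peak-fitting and relaxation analyses recover known ground truth exactly or
within stated tolerances, and the pipeline can express the reported
structural and dynamic contrasts.  What they do not demonstrate: detector
geometry/absorption effects, non-ideal backgrounds, electrode polarization,
conductivity relaxation, or any re-measurement of the original samples.

## Numerical choices and degenerate inputs

Quadrature: trapezoid everywhere; FT evaluated in r-chunks of 2048 to
bound memory.  Peak and HN fits: lmfit/least-squares (trust-region
reflective) with xtol = ftol = gtol = 1e−14/1e−15; fits are deterministic
given data and start.  Ties in peak detection resolve by prominence, then
lower Q; overlapping peaks closer than one FWHM merge into one candidate.
Degenerate inputs raise with specific messages (empty formula, unknown
element, non-ascending grids, negative loss, τ∞ ≥ τ_ref, all-zero PDF) —
except inside pipeline runs, where a failing stage marks its record
`failed` and dependent stages are skipped.  Problem sizes in the default
test run are chosen for desk-scale execution: ~4000-point Q grids,
10 001-point r grids, 9 temperatures per dielectric series, 50–100
replicates in noise-robustness checks.

## Known limitations

* The Compton model is qualitative (see above); quantitative electron-unit
  work on real data should substitute measured incoherent corrections.
* 2-D image azimuthal integration, absorption and instrument smearing are
  out of scope; input patterns are assumed already 1-D and corrected.
* The coherence-length criterion is one admissible reading of "extent of
  PDF oscillations"; its quantization to the oscillation comb means
  sub-period differences between samples are not resolvable.
* Relaxation-branch tracking assumes the α- and δ-processes do not cross
  within the fitted range; crossing data are flagged, not resolved.
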