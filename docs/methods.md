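# Methods

This note documents the models, parameter choices and numerical decisions
behind `tdnirs`, and what the synthetic-data tests do and do not
demonstrate about real instrument data.

## Units and conventions

Time in picoseconds, lengths in centimetres, absorption μa and reduced
scattering μs′ in cm⁻¹, speed of light c = 0.0299792458 cm/ps (in-medium
speed v = c/n). Concentrations in µM, water as a volume fraction.
Extinction coefficients are natural-log based, cm⁻¹·µM⁻¹
(`eps_log10_to_ln` converts log10-convention tables). Histogram bin times
are bin centers, `(i + ½)·Δt`. All randomness flows through explicit
seeds or `numpy.random.Generator` objects; there is no hidden global
state.

## Forward model

Time-resolved reflectance of a homogeneous semi-infinite medium is the
diffusion dipole (image-source) solution with extrapolated boundary
condition: positive source at depth `z0 = 1/μs′`, negative image at
`−(z0 + 2 zb)`, `zb = 2AD`, `D = 1/(3μs′)`. The internal-reflection
factor `A` uses the Groenhuis/Egan–Hilgeman polynomial approximation of
the diffuse Fresnel reflectance (A = 1 for matched indices). Because `D`
excludes μa, absorption factorizes exactly:
`R(t; μa) = R(t; 0)·exp(−μa v t)` — this identity is asserted to machine
precision in the tests.

The amplitude of `R` is arbitrary (absolute photometric throughput is not
modeled); all downstream analyses either normalize (moments, contrasts)
or carry a free amplitude (curve fit).

**IRF.** A Gaussian main peak (default FWHM 150 ps, at t0 = 1000 ps on
the grid) plus a Gaussian afterpulse (default 1.5 % of the main peak,
1 ns later), unit-normalized on the instrument grid. The default grid is
1024 bins × 9.77 ps (≈10 ns span at an 80 MHz repetition rate); the
default 16 channel centers are 680–867.5 nm in 12.5 nm steps (with the
instrument's 767.5 → 780.5 nm step included), of which 11 fall in the
705–830 nm oximetry band.

**Detection chain.** Expected counts are the discrete causal convolution
of the model curve with the IRF, scaled so the signal sums to the photon
budget, plus a uniform background (default 1 count/bin); recorded counts
are Poisson. A mean-1 per-bin gain pattern can emulate the differential
nonlinearity of the TCSPC time base. Pile-up, detector overload and
wrap-around of late photons are not modeled.

## DTOF measurands

**Background** is estimated as the mean of up to 100 bins that end 500 ps
before the IRF maximum (or, when no IRF time is supplied, 200 ps before
the rising edge, defined as the first 5 %-of-maximum crossing). The
window is deliberately not anchored on the DTOF peak: diffusion delays
the peak several hundred ps past the rising edge, and a peak-anchored
window would overlap signal and bias μa high. Negative residuals are
clipped at zero.

**Moments** N, m1, V are computed over the contiguous run of bins above
`threshold × max` that contains the global maximum (contiguity keeps the
afterpulse island out of the support). The default threshold is 1 %
(strictly greater); depth-sensitivity scans use ≥ 0.1 % (solid) or ≥ 2 %
(liquid). V is the plain central second moment — the Sheppard bin-width
correction (Δt²/12 ≈ 8 ps²) is negligible against physiological V of
~10⁵ ps².

For *repeated* acquisitions, `moment_series` determines the threshold
region once on the summed histogram and holds it fixed across frames.
Re-thresholding every frame adds the jitter of the integration limits
(~0.5 ps on m1 at 10⁶ counts) to the photon noise; with a fixed region
the measured std(m1) sits on the delta-method floor `sqrt(V/N)`, which is
the quantity a stability assessment is after. At 10⁶ photons on a
B2-like medium (μa = 0.07, μs′ = 8 cm⁻¹, ρ = 3 cm) the photon-only
fluctuations are ≈0.55 ps for m1 and ≈0.1 % for N.

**Contrasts** against a far-perturbation reference:
`ΔA_TW = −ln(N_TW/N_TW,0)` for the total counts and the early (0.5–1 ns)
and late (3–4 ns) windows measured from the IRF maximum;
`Δm1 = m1,0 − m1`; `ΔV = V0 − V`.

**Drift correction** interpolates the moment offsets of two bracketing
IRF acquisitions linearly in time and removes them (additively for m1
and V, multiplicatively for N), assuming a constant drift rate.

## Curve fitting

Absolute μa and μs′ are recovered by bounded trust-region least squares
(μa ∈ [0, 1], μs′ ∈ [1, 40] cm⁻¹, `xtol = 1e-8`) on the residual
`(amp·(model ⊛ IRF) − counts) / sqrt(max(counts, 1))`, restricted to the
percentage-of-maximum fit range determined on the measured DTOF (first
crossing of the rise fraction on the rising edge to the last bin above
the tail fraction). The weights are the Poisson-motivated
`1/max(counts, 1)` per squared residual. The amplitude is not a search
dimension: its weighted least-squares optimum is closed-form, so it is
profiled out (variable projection). Extreme initializations can still
reach a spurious basin pinned to the μs′ bound; when the solution lands
on a bound the fit restarts once from the default init (μa = 0.1,
μs′ = 10) and keeps the lower cost. With this, ten random
initializations agree to better than 1 %, and at 10⁶ photons the
recovered properties are within ~1 % of truth (worst case over seeds),
comfortably inside the 5 % accuracy expected at ~10 ps binning.

## Chromophore analysis

The absolute route unmixes μa(λ) over the 705–830 nm channels by
ordinary least squares against HbO₂, Hb and water spectra — no
nonnegativity constraint by default (commercial oximeters report slightly
negative values too; NNLS is available). Water is handled in two steps:
unmix three chromophores per time point, fix the time-mean water
fraction, subtract its absorption and re-unmix HbO₂/Hb only, which is
measurably less noisy. StO₂ is reported as NaN when HbT ≤ 0.1 µM.

The MBLL route converts attenuation changes to concentration changes
with pathlengths `L(λ) = v·m1(λ)` from the baseline mean time of flight
(a per-sample m1 series is an option). In a homogeneous medium with a
model-consistent pathlength the MBLL and absolute routes agree to first
order in Δμa; the in-vivo depth discrepancy between the two methods
arises from tissue layering, which the homogeneous generator cannot
produce — the occlusion tests therefore check sign patterns, not
method-difference magnitudes.

**Extinction table.** The bundled
`data/extinction_nir_synthetic.csv` is a constructed stand-in, not a
published dataset: smooth curves through widely known NIR landmark
values (deoxy-Hb 760 nm band, ~800 nm isosbestic point, water shoulder
rising past 800 nm), 660–900 nm at 2 nm. The generators and the
unmixing share this table, so recovery tests are self-consistent;
absolute concentrations from real data would require substituting
measured extinction tables in the same CSV layout.

## Perturbation sensitivity

A localized absorption change (volume V mm³, strength Δμa) is modeled to
first Born order with extrapolated-boundary fluence Green's functions:
`δΦ(t) = −Δμa·V·(G_s→p ⊛ G_p→d)(t)`, the perturbation treated as a point
at its center (an equivalent-sphere submerged-fraction rule handles
centers near or above the surface). Source at the origin, detector at
(ρ, 0, 0); depth scans move the inclusion under the midpoint, lateral
scans along y at fixed depth. Sensitivity factors are contrasts per unit
Δμa: MPP = ΔA/Δμa, MTSF = Δm1/Δμa, VSF = ΔV/Δμa.

Two conservation/consistency checks anchor the implementation: the
time-domain kernel's CW integral equals the closed-form CW product
`G(s→p)·G(p→d)` to machine precision, and unit perturbations summed over
the model's whole domain recover the total mean pathlength `v·m1` within
5 %. Note the image solution formally lives on the extended half-space
`z > −zb`; the sum rule closes over that domain.

**Monte-Carlo oracle.** An independent photon-packet random walk
(isotropic scattering with μs = μs′, absorption as `exp(−μa L)`
weighting, Fresnel internal reflection, partial pathlengths recorded
through the volume-equivalent sphere) cross-checks the Born contrasts.
The detector is a disc patch (default radius 0.25 cm) at the detector
position — not a full annulus around the source: an off-axis
perturbation breaks the cylindrical symmetry, and ring-averaging the
sensitivity would dilute the contrast severalfold relative to the
point-detector Born geometry. The same photon set yields perturbed and
unperturbed estimates (via `exp(−Δμa·L_pert)`), so the contrast
estimator is strongly correlated and its bootstrap standard errors are
small. Energy bookkeeping (detected + escaped + absorbed + truncated =
launched) closes to 1e-6. At 2×10⁶ photons the Born ΔA agrees with MC
within ~1–2 standard errors at 1.5 cm depth; the early-window contrast
deviates more, as expected where quasi-ballistic photons defeat the
diffusion approximation. The strongly absorbing black inclusion of the
liquid phantom is emulated as Δμa = 1.0 cm⁻¹, a first-order stand-in for
a saturated absorber; measured-magnitude reproduction of real scans is
out of scope.

## Protocol reports

The phantom grid spans μs′ ∈ {5,10,15,20} (letters A–D) × μa ∈
{0…0.35 step 0.05} cm⁻¹ (digits 1–8) at 800 nm, n = 1.55. Exclusion
rules are data-driven parameters with defaults: drop digits 6–8 at
ρ = 3 cm (20 remain), drop only C8 at ρ = 2 cm (31 remain).

Linearity is the mean percentage distance of measured values from their
own best-fit line against the nominal values, with the fitted-line value
as denominator. Coupling is the raw OLS slope of one measured property
against the other property's nominal value (dimensionless; the nominal
step sizes define the abscissa, and a per-step normalization is an
option). Grand means are arithmetic (a median option exists).

Scan summaries report, per measurand, the maximum *signed* contrast and
its depth (parabolic sub-step refinement) — the deep positive
sensitivity lobe, not the shallow negative m1/V lobe a low-absorption
medium produces — the linearly interpolated contrast at a fixed depth
(1.5 cm solid / 1.2 cm liquid), and the lateral FWHM by interpolated
half-maximum crossings (absent when the profile never crosses half
maximum).

Oximeter comparison resamples both StO₂ traces to a common 10 s grid and
fits `StO₂(dev1) = a·StO₂(dev2) + b` by OLS over reference values in
[30, 90] %, reporting a, b, R².

## Scenario generators

Defaults are the study conditions: 0.3 s frames, 10⁶ photons per DTOF,
ρ = 3 cm. μs′(λ) follows a power law `(λ/800 nm)^(−1)` (a
lipid-emulsion-like slope; real media vary in exponent). Detected counts
scale with the medium's reflectance relative to the session's first
frame (constant excitation power), so intensity-based methods (MBLL) see
physical attenuation changes.

* **Phantom grid**: 32 phantoms, spectrally flat μa, power-law μs′,
  n = 1.55. A noiseless end-to-end run recovers linearity deviations
  below 1 %.
* **Perturbation scans**: solid preset μa = 0.1/μs′ = 8 cm⁻¹, n = 1.55,
  98 mm³, Δμa = 0.017 cm⁻¹, 1 mm depth steps, lateral depth 1.5 cm;
  liquid preset μa = 0.026/μs′ = 10.5 cm⁻¹, n = 1.33, 50 mm³ strongly
  absorbing, 2.5 mm steps, lateral depth 1.2 cm.
* **Blood–lipid phantom**: deoxygenation cycles ramp StO₂ from 100 % to
  0 % with a raised-cosine (sigmoidal) profile over 28 min (mean cycle
  duration), instantaneous reoxygenation; cumulative blood 20/35/55/70 ml
  at 74 ml Intralipid, or Intralipid 25/50/75/100/125 ml at 45 ml blood,
  in 2.5 l saline, n = 1.33. HbT follows the erythrocyte-bag dilution;
  the bag hemoglobin defaults to 2800 µM so that 45 ml in ~2.6 l gives
  ≈48 µM — a documented free parameter, not a measured value. Scattering
  is tied to the Intralipid dilution through the calibration
  74 ml + 45 ml blood in 2.5 l → μs′(800) ≈ 5.5 cm⁻¹. The transient HbT
  dip after oxygen bubbling is not simulated by default, and the 1 mm
  silicone window of the physical phantom is not modeled (homogeneous
  medium). Full-pipeline recovery at 10⁶ photons gives StO₂ RMSE ≈0.2
  percentage points over the 30–90 % range with a comparison slope
  ≈1.00 — far inside the ≤5-point / [0.9, 1.1] acceptance envelope,
  because the generator and the analysis share forward model and
  extinction table; real-instrument errors (model mismatch, calibration,
  spectral bandwidth) are additional.
* **Cuff occlusions**: 1 min baseline, 2 min occlusion, 2 min release,
  n = 1.4, homogeneous forearm-muscle-like baseline (HbO₂ 40 µM, Hb
  25 µM, water 0.7, μs′(800) = 9 cm⁻¹). Arterial truth: Hb rises more
  than HbO₂ falls (HbT rises), post-release overshoot and return;
  venous truth: both species rise fast then slowly. Being homogeneous,
  the scenario cannot reproduce the depth-sensitivity difference between
  the fit and MBLL methods seen on layered tissue; both methods recover
  the sign pattern and, here, also the magnitudes.

## Problem sizes in the test suite

The suite simulates at the study photon budgets (10⁶ per DTOF) but keeps
series short: 10 time points per deoxygenation cycle, 20 s occlusion
sampling, 100-frame fluctuation runs, 2×10⁶-photon Monte-Carlo
cross-checks. These sizes are the package's chosen desk-scale defaults;
all scale up linearly via function arguments.

## Known limitations

* Diffusion theory degrades for early photons, short ρ and low μs′; the
  early-window Born contrast deviates most from transport.
* First-order Born underestimates saturated (strongly absorbing)
  inclusions; the liquid-phantom preset is a linearized stand-in.
* The extinction table is synthetic (see above); absolute concentrations
  are internally consistent, not traceable to published compilations.
* Homogeneous media only: no layered tissue, no phantom windows, no
  rod-cavity structure; measured-data artifacts (negative ΔA at negative
  depths) have no counterpart here.
* No pile-up/dead-time modeling; afterpulse is simulated but never
  deconvolved.
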