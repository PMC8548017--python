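# tdnirs

Simulation and analysis of multi-wavelength **time-domain near-infrared
spectroscopy (TD-NIRS)** measurements: distributions of times of flight of
photons (DTOFs), recovery of absolute tissue optical properties, hemoglobin
oximetry, and the standardized instrument performance protocols used to
qualify photon-migration instruments.

It is written for researchers building or validating TD-NIRS tissue
oximeters: every analysis stage that would normally require a
time-correlated single-photon counting (TCSPC) instrument and a set of
calibrated phantoms can be exercised against a synthetic instrument model
with known ground truth.

## What it computes

**Forward model.** Time-resolved diffuse reflectance of a homogeneous
semi-infinite medium, in the diffusion dipole (image-source) solution with
extrapolated boundary condition,

```
R(ρ,t) ∝ (4πDv)^(-3/2) t^(-5/2) exp(-μa v t - ρ²/(4Dvt))
         · ½ [ z0 e^(-z0²/4Dvt) + (z0+2zb) e^(-(z0+2zb)²/4Dvt) ]
```

with `D = 1/(3μs′)`, `z0 = 1/μs′`, `zb = 2AD`, convolved with a
parametric instrument response function (150 ps FWHM, 1–2 % afterpulse
~1 ns after the main peak), uniform background, and Poisson counting noise
on a 1024 × 9.77 ps TCSPC grid (16 spectral channels, 674–874 nm).

**DTOF measurands.** Background subtraction, the statistical moments
N (total counts), m1 (mean time of flight) and V (variance) over an
above-threshold region, photon counts in early/late time windows,
perturbation contrasts ΔA = −ln(N/N₀), Δm1, ΔV, the differential
nonlinearity metric ε_DNL, temporal-fluctuation statistics, and
IRF-bracketed drift correction.

**Optical-property recovery.** Nonlinear least-squares fitting of the
IRF-convolved diffusion model to a measured DTOF over a
percentage-of-maximum fit range (85 %→1 % for solid phantoms, 75 %→3 % for
liquid phantoms and in-vivo), yielding absolute μa and μs′ per spectral
channel.

**Oximetry.** Beer–Lambert unmixing of μa spectra into HbO₂, Hb and water
(with the two-step mean-water subtraction), HbT = HbO₂+Hb,
StO₂ = HbO₂/HbT, and the modified Beer–Lambert law (MBLL) route for
concentration *changes* using pathlengths L(λ) = (c/n)·m1(λ).

**Depth sensitivity.** A first-order Born model for a small localized
absorption perturbation (image-source Green's functions), depth/lateral
contrast scans, the sensitivity factors MPP = ΔA/Δμa, MTSF = Δm1/Δμa,
VSF = ΔV/Δμa, and an independent photon-packet Monte-Carlo oracle.

**Protocols.** The 32-phantom linearity/coupling grid (with the published
signal-level exclusion rules), depth-scan summary tables, affine
StO₂-vs-StO₂ oximeter comparison fits, and the co-oximetry dilution
reference for HbT.

**Scenario generators** (`tdnirs.scenarios`) emulate complete experiments
with ground truth: the 32-phantom grid, solid/liquid perturbation scans,
blood–Intralipid deoxygenation cycles, and arterial/venous cuff
occlusions.

## Worked example

Simulate one realistic acquisition and recover the medium's optical
properties:

```python
import numpy as np
import tdnirs as td

cfg = td.InstrumentConfig()                      # 1024 bins x 9.77 ps
irf = td.synthesize_irf(td.IRFModel(), cfg)      # 150 ps FWHM + afterpulse
truth = td.OpticalProperties(mua=0.1, musp=10.0, n_medium=1.4)

curve = td.diffuse_reflectance_td(3.0, cfg.times(), truth)
expected = td.expected_dtof(curve, irf, total_photons=1e6, background_level=1.0)
dtof = td.sample_dtof(expected, seed=1, bin_width=cfg.bin_width, rho=3.0)

sub = td.subtract_background(dtof)
m = td.moments(sub, threshold_fraction=0.01)
fit = td.fit_optical_properties(sub, irf, rho=3.0, n_medium=1.4)
print(f"N={m.n:.0f}  m1={m.m1:.1f} ps  V={m.var:.0f} ps^2")
print(f"mua={fit.props.mua:.4f} /cm  musp={fit.props.musp:.3f} /cm")
```

prints

```
N=994633  m1=2033.5 ps  V=198784 ps^2
mua=0.1002 /cm  musp=10.027 /cm
```

i.e. ~10⁶ detected photons with a mean arrival delay of ~2 ns, and both
optical properties recovered within ~0.5 % of the simulated truth
(μa = 0.1 cm⁻¹, μs′ = 10 cm⁻¹) despite Poisson noise and the instrument
blur.

A command-line interface wraps the same library:

```sh
tdnirs simulate neuropt --seed 1 --out scan.h5
tdnirs metrics --dtof scan.h5 --out moments.tsv
tdnirs fit --dtof scan.h5 --out props.tsv
```

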