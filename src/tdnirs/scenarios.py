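"""Synthetic measurement scenarios with known ground truth.

Each generator emulates one laboratory experiment of a multi-wavelength
TD-NIRS performance assessment at desk scale, emitting DTOFs through the
full instrument model (diffusion forward curve, IRF convolution, uniform
background, Poisson noise) together with the ground truth that produced
them:

* MEDPHOT grid — 32 solid phantoms, all combinations of four nominal
  mus' and eight nominal mua values (epoxy, n = 1.55);
* nEUROPt scans — a small absorbing inclusion moved in depth or laterally
  below a solid (mua=0.1, mus'=8) or liquid (mua=0.026, mus'=10.5)
  phantom at rho = 3 cm;
* blood-lipid phantom — deoxygenation cycles (StO2 100 % -> 0 %) with
  stepwise additions of blood or Intralipid, HbT following the dilution
  of the erythrocyte-bag hemoglobin;
* cuff occlusions — arterial (Hb rises more than HbO2 falls, HbT rises,
  post-release overshoot) and venous (HbO2 and Hb both rise at a fast
  then a slow rate) hemodynamics on the forearm (n = 1.4).

All randomness flows from the single ``seed`` argument; identical
arguments give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromophores import ExtinctionTable, load_default_table
from .forward import (
    DTOF,
    IRFModel,
    InstrumentConfig,
    OpticalProperties,
    diffuse_reflectance_td,
    expected_dtof,
    sample_dtof,
    synthesize_irf,
)
from .protocols import co_oximetry_reference, phantom_grid
from .sensitivity import Perturbation, perturbed_tpsf, scan_contrasts

__all__ = [
    "NEUROPT_PRESETS",
    "BloodPhantomTruth",
    "OcclusionTruth",
    "simulate_dtof",
    "gen_medphot_set",
    "gen_neuropt_scan",
    "gen_blood_phantom",
    "gen_occlusion",
]

#: reference wavelength for scattering power laws, nm
LAMBDA_REF = 800.0
#: Intralipid-like scattering power-law exponent
SCATTER_POWER = 1.0


def musp_spectrum(musp_ref: float, wavelengths) -> np.ndarray:
    """Power-law reduced scattering (lambda / 800 nm)^-b with b = 1."""
    lam = np.asarray(wavelengths, dtype=float)
    return musp_ref * (lam / LAMBDA_REF) ** (-SCATTER_POWER)


def simulate_dtof(
    props: OpticalProperties,
    rho: float,
    wavelength: float,
    irf_curve: np.ndarray,
    config: InstrumentConfig,
    photons: float,
    rng,
    *,
    background: float = 1.0,
    noiseless: bool = False,
    model_curve: np.ndarray | None = None,
) -> DTOF:
    """One DTOF through the full instrument chain (optionally noise-free)."""
    if model_curve is None:
        model_curve = diffuse_reflectance_td(rho, config.times(), props)
    lam = expected_dtof(model_curve, irf_curve, photons, background)
    if noiseless:
        return DTOF(
            counts=lam,
            bin_width=config.bin_width,
            channel_wavelength=wavelength,
            rho=rho,
            acquisition_time=config.frame_time,
            background_level=background,
        )
    return sample_dtof(
        lam,
        rng,
        bin_width=config.bin_width,
        channel_wavelength=wavelength,
        rho=rho,
        acquisition_time=config.frame_time,
        background_level=background,
    )


def _setup(config, irf_model):
    config = config or InstrumentConfig()
    irf_model = irf_model or IRFModel()
    return config, irf_model, synthesize_irf(irf_model, config)


def gen_medphot_set(
    seed: int = 0,
    *,
    rho: float = 3.0,
    photons: float = 1e6,
    channels=None,
    config: InstrumentConfig | None = None,
    irf_model: IRFModel | None = None,
    noiseless: bool = False,
    background: float = 1.0,
) -> dict:
    """The 32-phantom grid: per-label, per-channel true properties and DTOFs.

    mua is spectrally flat at its nominal value; mus' follows the
    power law around its nominal value at 800 nm; n = 1.55.
    """
    config, irf_model, irf = _setup(config, irf_model)
    channels = tuple(channels) if channels is not None else config.channel_centers
    rng = np.random.default_rng(seed)
    grid = phantom_grid()
    truth: dict = {}
    dtofs: dict = {}
    for _, row in grid.iterrows():
        label = row["label"]
        musp_lam = musp_spectrum(row["nominal_musp"], channels)
        truth[label] = {}
        dtofs[label] = {}
        for lam, musp in zip(channels, musp_lam):
            props = OpticalProperties(row["nominal_mua"], float(musp), 1.55)
            truth[label][lam] = props
            dtofs[label][lam] = simulate_dtof(
                props, rho, lam, irf, config, photons, rng,
                background=background, noiseless=noiseless,
            )
    return {
        "nominal": grid,
        "truth": truth,
        "dtofs": dtofs,
        "irf": irf,
        "irf_model": irf_model,
        "config": config,
        "rho": rho,
    }


NEUROPT_PRESETS = {
    "solid": {
        "props": OpticalProperties(0.1, 8.0, 1.55),
        "pert": {"volume": 98.0, "delta_mua": 0.017},
        "depth_step": 0.1,
        "lateral_depth": 1.5,
        "lateral_step": 0.2,
        "threshold_fraction": 0.001,
    },
    "liquid": {
        "props": OpticalProperties(0.026, 10.5, 1.33),
        # totally absorbing black PVC cylinder emulated as a large
        # equivalent absorption increase (approximation)
        "pert": {"volume": 50.0, "delta_mua": 1.0},
        "depth_step": 0.25,
        "lateral_depth": 1.2,
        "lateral_step": 0.2,
        "threshold_fraction": 0.02,
    },
}


def gen_neuropt_scan(
    seed: int = 0,
    phantom: str = "solid",
    mode: str = "depth",
    *,
    rho: float = 3.0,
    positions=None,
    photons: float | None = None,
    config: InstrumentConfig | None = None,
    irf_model: IRFModel | None = None,
) -> dict:
    """Perturbation scan DTOF series plus its noiseless Born contrast truth.

    With ``photons=None`` the emitted DTOFs are noise-free theory curves;
    otherwise each position gets an IRF-convolved Poisson DTOF.  The
    reference measurement is the unperturbed medium (perturbation at
    infinity).
    """
    if phantom not in NEUROPT_PRESETS:
        raise ValueError("phantom must be 'solid' or 'liquid'")
    preset = NEUROPT_PRESETS[phantom]
    config, irf_model, irf = _setup(config, irf_model)
    props = preset["props"]
    if positions is None:
        if mode == "depth":
            positions = np.arange(-0.5, 3.0 + 1e-9, preset["depth_step"])
        else:
            positions = np.arange(-4.0, 4.0 + 1e-9, preset["lateral_step"])
    positions = np.asarray(positions, dtype=float)
    pert = Perturbation((0.0, 0.0, 0.0), **preset["pert"])
    scan = scan_contrasts(
        props,
        rho,
        pert,
        positions,
        mode,
        lateral_depth=preset["lateral_depth"],
        times=config.times(),
        threshold_fraction=preset["threshold_fraction"],
    )
    rng = np.random.default_rng(seed)
    times = config.times()
    dtofs = []
    for pos in positions:
        center = (
            (rho / 2.0, 0.0, pos) if mode == "depth" else (rho / 2.0, pos, preset["lateral_depth"])
        )
        _, rp, _ = perturbed_tpsf(props, rho, Perturbation(center, **preset["pert"]), times)
        dtofs.append(
            simulate_dtof(
                props, rho, 805.0, irf, config,
                photons or 1e6, rng,
                noiseless=photons is None,
                model_curve=rp,
            )
        )
    reference = simulate_dtof(
        props, rho, 805.0, irf, config, photons or 1e6, rng,
        noiseless=photons is None,
        model_curve=perturbed_tpsf(props, rho, Perturbation((0, 0, 1e6), **preset["pert"]), times)[0],
    )
    return {
        "phantom": phantom,
        "mode": mode,
        "positions": positions,
        "scan": scan,
        "dtofs": dtofs,
        "reference": reference,
        "props": props,
        "pert": preset["pert"],
        "irf": irf,
        "config": config,
        "rho": rho,
        "threshold_fraction": preset["threshold_fraction"],
    }


@dataclass
class BloodPhantomTruth:
    """Ground truth of a blood-lipid phantom session."""

    times_s: np.ndarray
    sto2: np.ndarray                 # [0, 1]
    hbt: np.ndarray                  # uM
    water_fraction: np.ndarray
    musp_ref: np.ndarray             # mus' at 800 nm, 1/cm
    cycle_index: np.ndarray
    schedule: list = field(default_factory=list)

    @property
    def hbo2(self) -> np.ndarray:
        return self.sto2 * self.hbt

    @property
    def hb(self) -> np.ndarray:
        return (1.0 - self.sto2) * self.hbt


def gen_blood_phantom(
    seed: int = 0,
    *,
    variant: str = "blood",
    photons: float = 1e6,
    cycle_duration_s: float = 28 * 60.0,
    points_per_cycle: int = 24,
    rho: float = 3.0,
    channels=None,
    bag_thb: float = 2800.0,
    base_volume_ml: float = 2500.0,
    config: InstrumentConfig | None = None,
    irf_model: IRFModel | None = None,
    table: ExtinctionTable | None = None,
    noiseless: bool = False,
) -> dict:
    """Deoxygenation cycles in a stirred blood-Intralipid phantom.

    ``variant='blood'`` holds 74 ml Intralipid and steps blood through
    20, 35, 55, 70 ml; ``variant='intralipid'`` holds 45 ml blood and
    steps Intralipid through 25, 50, 75, 100, 125 ml.  Each cycle ramps
    StO2 from 100 % to 0 % with a smooth sigmoidal (raised-cosine)
    profile and instantaneous reoxygenation at the cycle boundary.  The
    scattering is tied to the Intralipid dilution through the calibration
    74 ml Intralipid + 45 ml blood in 2.5 l -> mus'(800 nm) ~ 5.5 1/cm.
    """
    if variant == "blood":
        blood_cum = [20.0, 35.0, 55.0, 70.0]
        il_cum = [74.0] * 4
    elif variant == "intralipid":
        blood_cum = [45.0] * 5
        il_cum = [25.0, 50.0, 75.0, 100.0, 125.0]
    else:
        raise ValueError("variant must be 'blood' or 'intralipid'")
    config, irf_model, irf = _setup(config, irf_model)
    channels = tuple(channels) if channels is not None else config.channel_centers
    table = table or load_default_table()

    blood_adds = np.diff([0.0] + blood_cum)
    il_adds = np.diff([0.0] + il_cum)
    hbt_levels = co_oximetry_reference(bag_thb, blood_adds, base_volume_ml, il_adds)

    n_cycles = len(blood_cum)
    tau = (np.arange(points_per_cycle) + 0.5) / points_per_cycle
    sto2_cycle = 0.5 * (1.0 + np.cos(np.pi * tau))  # 1 -> 0, sigmoid-shaped
    sto2_cycle[0] = 1.0
    sto2_cycle[-1] = 0.0

    times, sto2, hbt, wf, musp_ref, cyc = [], [], [], [], [], []
    cal_dilution = 74.0 / (2500.0 + 74.0 + 45.0)
    for k in range(n_cycles):
        total = base_volume_ml + blood_cum[k] + il_cum[k]
        water_k = (base_volume_ml + 0.8 * blood_cum[k] + 0.8 * il_cum[k]) / total
        musp_k = 5.5 * (il_cum[k] / total) / cal_dilution
        for j in range(points_per_cycle):
            times.append(k * cycle_duration_s + tau[j] * cycle_duration_s)
            sto2.append(sto2_cycle[j])
            hbt.append(hbt_levels[k])
            wf.append(water_k)
            musp_ref.append(musp_k)
            cyc.append(k)
    truth = BloodPhantomTruth(
        times_s=np.array(times),
        sto2=np.array(sto2),
        hbt=np.array(hbt),
        water_fraction=np.array(wf),
        musp_ref=np.array(musp_ref),
        cycle_index=np.array(cyc),
        schedule=[
            {"blood_ml": b, "intralipid_ml": i} for b, i in zip(blood_cum, il_cum)
        ],
    )

    lam = np.asarray(channels, dtype=float)
    E = table.design_matrix(lam, ("hbo2", "hb", "water"))
    rng = np.random.default_rng(seed)
    times = config.times()
    dtofs = []
    ref_flux: dict = {}
    for i in range(truth.times_s.size):
        conc = np.array([truth.hbo2[i], truth.hb[i], truth.water_fraction[i]])
        mua_lam = E @ conc
        musp_lam = musp_spectrum(truth.musp_ref[i], lam)
        frame = {}
        for l, mua, musp in zip(lam, mua_lam, musp_lam):
            props = OpticalProperties(float(mua), float(musp), 1.33)
            curve = diffuse_reflectance_td(rho, times, props)
            # constant excitation power: detected counts track the medium's
            # reflectance relative to the first (reference) frame
            ref_flux.setdefault(float(l), curve.sum())
            n_phot = photons * curve.sum() / ref_flux[float(l)]
            frame[float(l)] = simulate_dtof(
                props, rho, float(l), irf, config, n_phot, rng,
                noiseless=noiseless, model_curve=curve,
            )
        dtofs.append(frame)
    return {
        "truth": truth,
        "dtofs": dtofs,
        "channels": lam,
        "irf": irf,
        "config": config,
        "rho": rho,
        "table": table,
        "n_medium": 1.33,
    }


@dataclass
class OcclusionTruth:
    """Piecewise hemodynamic ground truth of a cuff-occlusion session."""

    times_s: np.ndarray
    hbo2: np.ndarray                 # uM
    hb: np.ndarray                   # uM
    phase: np.ndarray                # 'baseline' | 'occlusion' | 'release'
    water_fraction: float
    musp_ref: float

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo2 + self.hb


def _occlusion_truth(kind, dt_s, baseline_s, occlusion_s, release_s):
    t = np.arange(0.0, baseline_s + occlusion_s + release_s, dt_s)
    hbo2 = np.full_like(t, 40.0)
    hb = np.full_like(t, 25.0)
    phase = np.where(
        t < baseline_s, "baseline", np.where(t < baseline_s + occlusion_s, "occlusion", "release")
    )
    occ = phase == "occlusion"
    rel = phase == "release"
    u = np.clip((t - baseline_s) / occlusion_s, 0.0, 1.0)
    if kind == "arterial":
        # Hb rises more than HbO2 falls -> HbT rises
        hbo2[occ] -= 5.0 * u[occ]
        hb[occ] += 8.0 * u[occ]
        tr = (t[rel] - baseline_s - occlusion_s) / 30.0
        hbo2[rel] += (-5.0 + 11.0) * np.exp(-tr) - 6.0 * np.exp(-2.0 * tr)  # overshoot then baseline
        hb[rel] += (8.0 - 11.0) * np.exp(-tr) + 3.0 * np.exp(-2.0 * tr)
    elif kind == "venous":
        # both rise: fast then slow rate
        fast = np.minimum(u, 0.25) / 0.25
        slow = np.clip((u - 0.25) / 0.75, 0.0, 1.0)
        hbo2[occ] += 4.0 * fast[occ] + 1.0 * slow[occ]
        hb[occ] += 5.0 * fast[occ] + 2.0 * slow[occ]
        tr = (t[rel] - baseline_s - occlusion_s) / 20.0
        hbo2[rel] += 5.0 * np.exp(-tr)
        hb[rel] += 7.0 * np.exp(-tr)
    else:
        raise ValueError("kind must be 'arterial' or 'venous'")
    return t, hbo2, hb, phase


def gen_occlusion(
    seed: int = 0,
    kind: str = "arterial",
    *,
    dt_s: float = 5.0,
    baseline_s: float = 60.0,
    occlusion_s: float = 120.0,
    release_s: float = 120.0,
    photons: float = 1e6,
    rho: float = 3.0,
    channels=None,
    config: InstrumentConfig | None = None,
    irf_model: IRFModel | None = None,
    table: ExtinctionTable | None = None,
    noiseless: bool = False,
) -> dict:
    """Forearm cuff-occlusion DTOF time series with hemodynamic ground truth.

    The occlusion window is 2 min by default; tissue refractive index 1.4.
    The medium is homogeneous (no superficial/muscle layering).
    """
    config, irf_model, irf = _setup(config, irf_model)
    channels = tuple(channels) if channels is not None else config.channel_centers
    table = table or load_default_table()
    t, hbo2, hb, phase = _occlusion_truth(kind, dt_s, baseline_s, occlusion_s, release_s)
    truth = OcclusionTruth(
        times_s=t, hbo2=hbo2, hb=hb, phase=phase, water_fraction=0.7, musp_ref=9.0
    )
    lam = np.asarray(channels, dtype=float)
    E = table.design_matrix(lam, ("hbo2", "hb", "water"))
    musp_lam = musp_spectrum(truth.musp_ref, lam)
    rng = np.random.default_rng(seed)
    times = config.times()
    dtofs = []
    ref_flux: dict = {}
    for i in range(t.size):
        mua_lam = E @ np.array([hbo2[i], hb[i], truth.water_fraction])
        frame = {}
        for l, mua, musp in zip(lam, mua_lam, musp_lam):
            props = OpticalProperties(float(mua), float(musp), 1.4)
            curve = diffuse_reflectance_td(rho, times, props)
            ref_flux.setdefault(float(l), curve.sum())
            n_phot = photons * curve.sum() / ref_flux[float(l)]
            frame[float(l)] = simulate_dtof(
                props, rho, float(l), irf, config, n_phot, rng,
                noiseless=noiseless, model_curve=curve,
            )
        dtofs.append(frame)
    return {
        "truth": truth,
        "dtofs": dtofs,
        "channels": lam,
        "irf": irf,
        "config": config,
        "rho": rho,
        "table": table,
        "n_medium": 1.4,
    }
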