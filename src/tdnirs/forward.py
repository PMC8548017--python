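"""Instrument and photon-migration forward model.

Produces expected and noisy photon time-of-flight histograms (DTOFs) for a
homogeneous semi-infinite turbid medium observed through a realistic
instrument response function (IRF) of a time-correlated single-photon
counting (TCSPC) system.

The time-resolved reflectance follows the diffusion dipole (image-source)
solution with extrapolated boundary condition:

    R(rho, t) ~ (4 pi D v)^(-3/2) t^(-5/2) exp(-mua v t - rho^2 / (4 D v t))
                * [ z0 exp(-z0^2/(4 D v t)) + (z0 + 2 zb) exp(-(z0+2zb)^2/(4 D v t)) ] / 2

with D = 1/(3 mus'), z0 = 1/mus', zb = 2 A D and A from the Fresnel index
mismatch.  Absorption enters only through exp(-mua v t), so the absorption
scaling identity R(t; mua) = R(t; 0) exp(-mua v t) holds exactly.

Units: time in ps, lengths in cm, mua / mus' in 1/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "C_CM_PS",
    "InstrumentConfig",
    "OpticalProperties",
    "IRFModel",
    "DTOF",
    "InvalidGeometryError",
    "boundary_mismatch_factor",
    "diffuse_reflectance_td",
    "synthesize_irf",
    "expected_dtof",
    "sample_dtof",
]

#: speed of light in vacuum, cm/ps
C_CM_PS = 0.0299792458

#: spectral channel centers (nm) of the 16-channel polychromator, 674-874 nm range
DEFAULT_CHANNELS = (
    680.0, 692.5, 705.0, 717.5, 730.0, 742.5, 755.0, 767.5,
    780.5, 792.5, 805.0, 817.5, 830.0, 842.5, 855.0, 867.5,
)


class InvalidGeometryError(ValueError):
    """Raised for nonphysical geometry or medium parameters."""


@dataclass(frozen=True)
class InstrumentConfig:
    """Static acquisition parameters of the 16-channel TCSPC instrument."""

    n_bins: int = 1024
    bin_width: float = 9.77          # ps
    rep_period: float = 12.5         # ns (80 MHz laser)
    channel_centers: tuple = DEFAULT_CHANNELS
    channel_width: float = 12.5      # nm, metadata only
    frame_time: float = 0.3          # s

    def __post_init__(self):
        if self.n_bins <= 0 or self.bin_width <= 0 or self.rep_period <= 0:
            raise ValueError("n_bins, bin_width and rep_period must be positive")
        if self.n_bins * self.bin_width > self.rep_period * 1000.0:
            raise ValueError("histogram span exceeds the laser repetition period")
        centers = np.asarray(self.channel_centers, dtype=float)
        if centers.size and np.any(np.diff(centers) <= 0):
            raise ValueError("channel_centers must be strictly increasing")

    def times(self) -> np.ndarray:
        """Bin-center time coordinates in ps."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption / reduced scattering (1/cm) and refractive index of a medium."""

    mua: float
    musp: float
    n_medium: float = 1.4

    def __post_init__(self):
        if self.mua < 0:
            raise ValueError("mua must be >= 0")
        if self.musp <= 0:
            raise InvalidGeometryError("musp must be > 0")
        if self.n_medium < 1:
            raise ValueError("n_medium must be >= 1")


@dataclass(frozen=True)
class IRFModel:
    """Parametric IRF: Gaussian main peak plus a small Gaussian afterpulse.

    The photomultiplier afterpulse sits ~1 ns after the main peak with an
    amplitude of 1-2 % of the maximum.
    """

    fwhm: float = 150.0              # ps
    afterpulse_delay: float = 1000.0  # ps
    afterpulse_fraction: float = 0.015
    t0: float = 1000.0               # ps, main peak position on the grid

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if not 0.0 <= self.afterpulse_fraction <= 0.05:
            raise ValueError("afterpulse_fraction must be within [0, 0.05]")


@dataclass
class DTOF:
    """One photon time-of-flight histogram with its acquisition metadata."""

    counts: np.ndarray
    bin_width: float                 # ps
    channel_wavelength: float = float("nan")  # nm
    rho: float = float("nan")        # cm
    acquisition_time: float = 0.3    # s
    background_level: float = 0.0    # counts per bin

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    def times(self) -> np.ndarray:
        """Bin-center times in ps."""
        return (np.arange(self.counts.size) + 0.5) * self.bin_width


def boundary_mismatch_factor(n_medium: float, n_external: float = 1.0) -> float:
    """Internal-reflection factor A for the extrapolated boundary distance zb = 2 A D.

    Uses the Groenhuis/Egan-Hilgeman polynomial approximation of the
    diffuse Fresnel reflectance for the relative index n = n_in / n_out.
    """
    n = n_medium / n_external
    if abs(n - 1.0) < 1e-12:
        return 1.0
    r_d = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


def diffuse_reflectance_td(
    rho: float,
    times: np.ndarray,
    props: OpticalProperties,
    n_external: float = 1.0,
) -> np.ndarray:
    """Time-resolved diffuse reflectance of a semi-infinite medium (relative units).

    Parameters
    ----------
    rho
        Source-detector separation, cm (> 0).
    times
        Times in ps; entries <= 0 yield exactly 0 (causality).
    props
        Medium optical properties.
    n_external
        Refractive index of the outside medium.

    Returns
    -------
    Nonnegative photon flux per unit time on an arbitrary amplitude scale.
    """
    if rho <= 0:
        raise InvalidGeometryError("rho must be > 0")
    if props.musp <= 0:
        raise InvalidGeometryError("musp must be > 0")
    t = np.asarray(times, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if not np.any(pos):
        return out
    tp = t[pos]

    v = C_CM_PS / props.n_medium
    D = 1.0 / (3.0 * props.musp)
    z0 = 1.0 / props.musp
    zb = 2.0 * boundary_mismatch_factor(props.n_medium, n_external) * D
    z1 = z0 + 2.0 * zb

    k = 1.0 / (4.0 * D * v * tp)
    pref = 0.5 * (4.0 * np.pi * D * v) ** -1.5 * tp**-2.5
    decay = np.exp(-props.mua * v * tp - rho**2 * k)
    dipole = z0 * np.exp(-(z0**2) * k) + z1 * np.exp(-(z1**2) * k)
    out[pos] = pref * decay * dipole
    return out


def synthesize_irf(model: IRFModel, config: InstrumentConfig) -> np.ndarray:
    """Unit-normalized IRF curve on the instrument time grid.

    Raises a resolution error when the requested FWHM is not resolvable
    (less than two time bins).
    """
    if model.fwhm < 2.0 * config.bin_width:
        raise ValueError("IRF FWHM must span at least two time bins")
    t = config.times()
    sigma = model.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    curve = np.exp(-0.5 * ((t - model.t0) / sigma) ** 2)
    if model.afterpulse_fraction > 0:
        curve = curve + model.afterpulse_fraction * np.exp(
            -0.5 * ((t - model.t0 - model.afterpulse_delay) / sigma) ** 2
        )
    s = curve.sum()
    if s <= 0:
        raise ValueError("IRF peak falls outside the time grid")
    return curve / s


def expected_dtof(
    model_curve: np.ndarray,
    irf_curve: np.ndarray,
    total_photons: float,
    background_level: float = 0.0,
) -> np.ndarray:
    """Expected counts per bin: model (x) IRF, scaled to ``total_photons`` plus background.

    Both curves must live on the same time grid.  The discrete causal
    convolution is truncated to the histogram length, then scaled so the
    signal part (excluding background) sums to ``total_photons``.
    """
    m = np.asarray(model_curve, dtype=float)
    h = np.asarray(irf_curve, dtype=float)
    if m.shape != h.shape:
        raise ValueError("model and IRF curves must share one time grid")
    conv = np.convolve(m, h)[: m.size]
    s = conv.sum()
    if s <= 0:
        raise ValueError("convolution has no signal to normalize")
    return conv * (total_photons / s) + background_level


def sample_dtof(
    expected: np.ndarray,
    seed,
    dnl_pattern: np.ndarray | None = None,
    *,
    bin_width: float = 9.77,
    channel_wavelength: float = float("nan"),
    rho: float = float("nan"),
    acquisition_time: float = 0.3,
    background_level: float = 0.0,
) -> DTOF:
    """Draw a Poisson realization of an expected DTOF.

    ``seed`` may be an int or a ``numpy.random.Generator``.  ``dnl_pattern``
    emulates the differential nonlinearity of the TCSPC time base as a
    mean-1 multiplicative per-bin gain.
    """
    lam = np.asarray(expected, dtype=float)
    if np.any(lam < 0):
        raise ValueError("expected counts must be nonnegative")
    if dnl_pattern is not None:
        g = np.asarray(dnl_pattern, dtype=float)
        if g.shape != lam.shape:
            raise ValueError("dnl_pattern must match the histogram shape")
        if abs(g.mean() - 1.0) > 1e-6:
            raise ValueError("dnl_pattern must have mean 1")
        lam = lam * g
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.poisson(lam)
    return DTOF(
        counts=counts,
        bin_width=bin_width,
        channel_wavelength=channel_wavelength,
        rho=rho,
        acquisition_time=acquisition_time,
        background_level=background_level,
    )
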