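"""Chromophore unmixing and tissue oximetry.

Converts absorption spectra (absolute method) or attenuation changes
(modified Beer-Lambert law, MBLL) into oxy-/deoxy-hemoglobin
concentrations, total hemoglobin HbT = HbO2 + Hb and oxygen saturation
StO2 = HbO2 / HbT.

Conventions
-----------
* concentrations in uM, water as a volume fraction;
* extinction coefficients in 1/(cm uM) on the natural-log (ln) scale, so
  mua(lambda) = sum_c eps_c(lambda) * C_c  directly in 1/cm
  (``eps_log10_to_ln`` converts tables published in the log10 convention);
* plain least squares without a nonnegativity constraint by default
  (commercial oximeters report slightly negative values too); pass
  ``nonneg=True`` to clip via NNLS;
* StO2 is NaN when HbT <= 0.1 uM.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .forward import C_CM_PS

__all__ = [
    "ExtinctionTable",
    "ConcentrationRecord",
    "load_default_table",
    "eps_log10_to_ln",
    "select_channels",
    "unmix_concentrations",
    "water_subtract_two_step",
    "mbll_changes",
]

HBT_FLOOR_UM = 0.1
CHROMOPHORES = ("hbo2", "hb", "water")


def eps_log10_to_ln(eps: np.ndarray) -> np.ndarray:
    """Convert extinction coefficients from the log10 to the ln convention."""
    return np.asarray(eps, dtype=float) * np.log(10.0)


@dataclass(frozen=True)
class ExtinctionTable:
    """Specific absorption spectra of HbO2, Hb (1/(cm uM), ln base) and water (1/cm)."""

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    mua_water: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        for name in ("eps_hbo2", "eps_hb", "mua_water"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != lam.shape:
                raise ValueError(f"{name} must match the wavelength grid")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        data = pd.read_csv(path, comment="#")
        return cls(
            wavelengths=data["wavelength_nm"].to_numpy(),
            eps_hbo2=data["eps_hbo2"].to_numpy(),
            eps_hb=data["eps_hb"].to_numpy(),
            mua_water=data["mua_water"].to_numpy(),
        )

    def design_matrix(self, wavelengths, chromophores=CHROMOPHORES) -> np.ndarray:
        """Columns of specific absorptions linearly interpolated to channel centers."""
        lam = np.asarray(wavelengths, dtype=float)
        if lam.min() < self.wavelengths[0] or lam.max() > self.wavelengths[-1]:
            raise ValueError("requested wavelengths outside the tabulated range")
        cols = {
            "hbo2": self.eps_hbo2,
            "hb": self.eps_hb,
            "water": self.mua_water,
        }
        return np.column_stack(
            [np.interp(lam, self.wavelengths, cols[c]) for c in chromophores]
        )


def load_default_table() -> ExtinctionTable:
    """Bundled synthetic NIR extinction table (see the file header for provenance)."""
    ref = resources.files("tdnirs.data").joinpath("extinction_nir_synthetic.csv")
    with resources.as_file(ref) as path:
        return ExtinctionTable.from_csv(path)


@dataclass(frozen=True)
class ConcentrationRecord:
    """Hemoglobin concentrations (uM), water volume fraction, HbT and StO2."""

    hbo2: float
    hb: float
    water_fraction: float
    residual_norm: float = 0.0

    @property
    def hbt(self) -> float:
        return self.hbo2 + self.hb

    @property
    def sto2(self) -> float:
        if self.hbt <= HBT_FLOOR_UM:
            return float("nan")
        return self.hbo2 / self.hbt


def select_channels(channel_centers, lo: float, hi: float) -> list:
    """Channels with centers in [lo, hi] inclusive, order preserved."""
    centers = list(channel_centers)
    if not centers:
        raise ValueError("empty channel list")
    out = [c for c in centers if lo <= c <= hi]
    if not out:
        raise ValueError(f"no channels within [{lo}, {hi}] nm")
    return out


def unmix_concentrations(
    mua_spectrum,
    wavelengths,
    table: ExtinctionTable,
    chromophores=CHROMOPHORES,
    *,
    nonneg: bool = False,
) -> ConcentrationRecord:
    """Least-squares Beer-Lambert inversion of a mua spectrum."""
    y = np.asarray(mua_spectrum, dtype=float)
    lam = np.asarray(wavelengths, dtype=float)
    if y.shape != lam.shape:
        raise ValueError("spectrum and wavelengths must align")
    if y.size < len(chromophores):
        raise ValueError("need at least as many wavelengths as chromophores")
    A = table.design_matrix(lam, chromophores)
    if np.linalg.matrix_rank(A) < len(chromophores):
        raise ValueError("rank-deficient extinction design matrix")
    if nonneg:
        x, rnorm = nnls(A, y)
    else:
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        rnorm = float(np.linalg.norm(A @ x - y))
    vals = dict(zip(chromophores, x))
    return ConcentrationRecord(
        hbo2=float(vals.get("hbo2", 0.0)),
        hb=float(vals.get("hb", 0.0)),
        water_fraction=float(vals.get("water", float("nan"))),
        residual_norm=float(rnorm),
    )


def water_subtract_two_step(
    mua_series,
    wavelengths,
    table: ExtinctionTable,
    *,
    nonneg: bool = False,
):
    """Two-step water handling for absolute concentration time series.

    Step 1 unmixes {HbO2, Hb, water} at every time point; the time-mean
    water fraction is then fixed, its absorption subtracted from every
    spectrum, and step 2 unmixes {HbO2, Hb} only — resolving two
    chromophores instead of three gives less noisy results.

    Returns (step2 records, step1 records, mean water fraction).
    """
    mua = np.atleast_2d(np.asarray(mua_series, dtype=float))
    if mua.shape[0] < 2:
        raise ValueError("need a series of at least two spectra")
    step1 = [
        unmix_concentrations(row, wavelengths, table, CHROMOPHORES, nonneg=nonneg)
        for row in mua
    ]
    mean_water = float(np.mean([r.water_fraction for r in step1]))
    water_mua = mean_water * table.design_matrix(wavelengths, ("water",))[:, 0]
    step2 = [
        unmix_concentrations(
            row - water_mua, wavelengths, table, ("hbo2", "hb"), nonneg=nonneg
        )
        for row in mua
    ]
    step2 = [
        ConcentrationRecord(r.hbo2, r.hb, mean_water, r.residual_norm) for r in step2
    ]
    return step2, step1, mean_water


def mbll_changes(
    dA_series,
    m1_baseline,
    n_medium: float,
    wavelengths,
    table: ExtinctionTable,
    chromophores=("hbo2", "hb"),
    *,
    m1_series=None,
):
    """Concentration changes from attenuation changes via the MBLL.

    The mean optical pathlength per channel is L(lambda) = (c/n) * m1(lambda)
    from the measured mean time of flight (baseline m1 by default; pass a
    time-resolved ``m1_series`` to use per-sample pathlengths).

    Returns an (n_times, n_chromophores) array of concentration changes in uM.
    """
    dA = np.atleast_2d(np.asarray(dA_series, dtype=float))
    lam = np.asarray(wavelengths, dtype=float)
    m1 = np.asarray(m1_baseline, dtype=float)
    if m1.shape != lam.shape or dA.shape[1] != lam.size:
        raise ValueError("dA and m1 must be on the same channel set")
    if np.any(m1 <= 0):
        raise ValueError("mean time of flight must be positive")
    A = table.design_matrix(lam, chromophores)
    v = C_CM_PS / n_medium
    out = np.empty((dA.shape[0], len(chromophores)))
    for i, row in enumerate(dA):
        if m1_series is not None:
            L = v * np.asarray(m1_series)[i]
            if np.any(L <= 0):
                raise ValueError("mean time of flight must be positive")
        else:
            L = v * m1
        x, *_ = np.linalg.lstsq(A, row / L, rcond=None)
        out[i] = x
    return out
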