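"""Protocol-level performance reports.

Implements the bookkeeping and statistics of the three standardized
performance-assessment protocols for photon-migration instruments:

* MEDPHOT — linearity and crosstalk (coupling) of recovered mua / mus'
  on the 32-phantom grid (letters A-D: nominal mus' 5..20 in steps of 5;
  digits 1-8: nominal mua 0..0.35 in steps of 0.05, 1/cm);
* nEUROPt — summary statistics of depth / lateral contrast scans
  (maximum contrast and its depth, contrast at a fixed depth, lateral
  FWHM);
* tissue-oximeter comparison — affine regression between two StO2 traces
  resampled to a common time base, and the co-oximetry dilution
  reference for HbT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sensitivity import ContrastScan

__all__ = [
    "NOMINAL_MUSP",
    "NOMINAL_MUA",
    "phantom_grid",
    "apply_exclusions",
    "linearity",
    "coupling",
    "neuropt_summary",
    "ComparisonFit",
    "oximeter_comparison",
    "co_oximetry_reference",
]

#: nominal reduced scattering per letter, 1/cm
NOMINAL_MUSP = {"A": 5.0, "B": 10.0, "C": 15.0, "D": 20.0}
#: nominal absorption per digit, 1/cm
NOMINAL_MUA = {str(d): 0.05 * (d - 1) for d in range(1, 9)}


def phantom_grid() -> pd.DataFrame:
    """The full 32-phantom MEDPHOT grid with nominal properties."""
    rows = [
        {
            "label": f"{letter}{digit}",
            "letter": letter,
            "digit": int(digit),
            "nominal_musp": NOMINAL_MUSP[letter],
            "nominal_mua": NOMINAL_MUA[digit],
        }
        for letter in "ABCD"
        for digit in map(str, range(1, 9))
    ]
    return pd.DataFrame(rows)


def apply_exclusions(grid: pd.DataFrame, rho: float, rules: dict | None = None) -> pd.DataFrame:
    """Signal-level exclusion rules: at rho = 3 cm the high-absorption digits
    6-8 are dropped (20 phantoms remain); at rho = 2 cm only C8 (31 remain)."""
    if rules is None:
        rules = {
            3.0: {"exclude_digits": (6, 7, 8)},
            2.0: {"exclude_labels": ("C8",)},
        }
    if rho not in rules:
        raise ValueError(f"no exclusion policy for rho = {rho} cm")
    rule = rules[rho]
    out = grid
    if "exclude_digits" in rule:
        out = out[~out["digit"].isin(rule["exclude_digits"])]
    if "exclude_labels" in rule:
        out = out[~out["label"].isin(rule["exclude_labels"])]
    return out.reset_index(drop=True)


def _ols_line(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate nominal values")
    slope, intercept = np.polyfit(x, y, 1)
    return slope, intercept


def linearity(measured, nominal) -> float:
    """Mean percentage deviation of measured values from their own best-fit
    line versus the nominal values (denominator: the fitted-line value)."""
    x = np.asarray(nominal, dtype=float)
    y = np.asarray(measured, dtype=float)
    slope, intercept = _ols_line(x, y)
    line = slope * x + intercept
    if np.any(line == 0):
        raise ValueError("fitted line crosses zero at a data point")
    return float(np.mean(100.0 * np.abs(y - line) / np.abs(line)))


def coupling(measured, nominal_cross, *, step_abscissa=None, step_ordinate=None) -> float:
    """Crosstalk slope of a measured property versus the nominal value of the
    other property.

    By default this is the raw OLS slope (dimensionless, both axes in
    1/cm): a coupling of 2e-4 means mua rises by 2e-4 cm^-1 per 1 cm^-1 of
    mus'.  Pass both nominal step sizes to normalize per-step instead.
    """
    slope, _ = _ols_line(nominal_cross, measured)
    if step_abscissa is not None and step_ordinate is not None:
        return float(slope * step_abscissa / step_ordinate)
    return float(slope)


def _parabolic_peak(x, y):
    """Vertex of the parabola through the discrete maximum and its neighbors."""
    i = int(np.argmax(y))
    if 0 < i < len(y) - 1:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1.0:
                xs = x[i] + delta * (x[i] - x[i - 1])
                ys = y1 - 0.25 * (y0 - y2) * delta
                return float(xs), float(ys)
    return float(x[i]), float(y[i])


def _fwhm(x, y):
    """Full width at half maximum by linear interpolation of the crossings."""
    i = int(np.argmax(y))
    half = y[i] / 2.0
    left = None
    for j in range(i, 0, -1):
        if y[j - 1] < half <= y[j]:
            left = np.interp(half, [y[j - 1], y[j]], [x[j - 1], x[j]])
            break
    right = None
    for j in range(i, len(y) - 1):
        if y[j + 1] < half <= y[j]:
            right = np.interp(half, [y[j + 1], y[j]], [x[j + 1], x[j]])
            break
    if left is None or right is None:
        return None
    return float(right - left)


MEASURANDS = ("dA_early", "dA_total", "dA_late", "dm1", "dV")


def neuropt_summary(
    depth_scan: ContrastScan,
    lateral_scan: ContrastScan | None = None,
    fixed_depth: float = 1.5,
) -> pd.DataFrame:
    """Per-measurand scan summary: maximum signed contrast and its depth
    (parabolic sub-step refinement), contrast at a fixed depth (linear
    interpolation) and lateral FWHM (None when the profile never crosses
    half maximum)."""
    rows = []
    for name in MEASURANDS:
        # signed maximum: the deep positive sensitivity lobe (a shallow
        # perturbation can give a negative m1/V lobe that is not the
        # quantity summarized here)
        prof = depth_scan.array(name)
        depth_max, peak = _parabolic_peak(depth_scan.positions, prof)
        at_fixed = float(np.interp(fixed_depth, depth_scan.positions, prof))
        fwhm = None
        if lateral_scan is not None:
            fwhm = _fwhm(lateral_scan.positions, lateral_scan.array(name))
        rows.append(
            {
                "measurand": name,
                "depth_of_max": depth_max,
                "max_contrast": peak,
                "contrast_at_fixed_depth": at_fixed,
                "lateral_fwhm": fwhm,
            }
        )
    return pd.DataFrame(rows).set_index("measurand")


@dataclass(frozen=True)
class ComparisonFit:
    """Affine relation StO2(device 1) = a * StO2(device 2) + b."""

    slope: float
    intercept: float         # StO2 percentage points
    r2: float

    def __post_init__(self):
        if self.r2 > 1.0 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")


def oximeter_comparison(
    t_a,
    sto2_a,
    t_b,
    sto2_b,
    fit_lo: float = 30.0,
    fit_hi: float = 90.0,
    resample: float = 10.0,
) -> ComparisonFit:
    """Affine comparison of two StO2 traces (percent scale).

    Both traces are linearly resampled to a common ``resample``-second
    grid over the overlapping time support; points with the reference
    trace (device 2) within [fit_lo, fit_hi] enter an ordinary
    least-squares fit of a, b plus the coefficient of determination.
    """
    t_a = np.asarray(t_a, dtype=float)
    t_b = np.asarray(t_b, dtype=float)
    lo = max(t_a.min(), t_b.min())
    hi = min(t_a.max(), t_b.max())
    if hi <= lo:
        raise ValueError("traces do not overlap in time")
    grid = np.arange(lo, hi + 1e-9, resample)
    a = np.interp(grid, t_a, np.asarray(sto2_a, dtype=float))
    b = np.interp(grid, t_b, np.asarray(sto2_b, dtype=float))
    sel = (b >= fit_lo) & (b <= fit_hi) & np.isfinite(a) & np.isfinite(b)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 points inside the fit range")
    slope, intercept = np.polyfit(b[sel], a[sel], 1)
    pred = slope * b[sel] + intercept
    ss_res = np.sum((a[sel] - pred) ** 2)
    ss_tot = np.sum((a[sel] - a[sel].mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ComparisonFit(slope=float(slope), intercept=float(intercept), r2=float(min(r2, 1.0)))


def co_oximetry_reference(
    bag_thb: float,
    blood_volumes,
    base_volume: float,
    other_additions=None,
) -> np.ndarray:
    """HbT (uM) in the phantom after each blood addition, from the dilution of
    the erythrocyte-bag total hemoglobin.

    ``blood_volumes`` are the per-addition blood volumes (ml);
    ``other_additions`` the non-blood volumes (e.g. Intralipid) added at the
    same events.  HbT_k = bag_thb * cum_blood_k / cum_total_k.
    """
    blood = np.asarray(blood_volumes, dtype=float)
    if other_additions is None:
        other = np.zeros_like(blood)
    else:
        other = np.asarray(other_additions, dtype=float)
    if np.any(blood < 0) or np.any(other < 0) or base_volume <= 0:
        raise ValueError("volumes must be positive")
    cum_blood = np.cumsum(blood)
    total = base_volume + cum_blood + np.cumsum(other)
    if np.any(total <= 0):
        raise ValueError("zero total volume")
    return bag_thb * cum_blood / total
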