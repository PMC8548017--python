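"""Statistical measurands of DTOFs.

Background subtraction, photon-count thresholding, the first statistical
moments (total photons N, mean time of flight m1, variance V), time-window
counts, perturbation contrasts, the differential-nonlinearity metric, and
the fluctuation / drift bookkeeping of a TCSPC session.

Moment conventions: bin times are bin centers; N, m1 and V are computed on
the contiguous above-threshold region that contains the global maximum of
the background-subtracted histogram (this keeps afterpulse islands out of
the support); V is the plain central second moment (no Sheppard
correction, which is far below 1 ps^2 at ~10 ps bins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .forward import DTOF

__all__ = [
    "Moments",
    "TimeWindow",
    "ContrastRecord",
    "BackgroundError",
    "subtract_background",
    "moments",
    "moment_series",
    "window_counts",
    "contrasts",
    "epsilon_dnl",
    "temporal_fluctuations",
    "FluctuationReport",
    "drift_correct",
    "rebin_time",
]

log = logging.getLogger(__name__)


class BackgroundError(ValueError):
    """Raised when the pre-peak background cannot be estimated."""


@dataclass(frozen=True)
class Moments:
    """First statistical moments of a DTOF."""

    n: float                 # total photons
    m1: float                # mean time of flight, ps
    var: float               # variance of time of flight, ps^2
    threshold_fraction: float
    bins_used: tuple         # half-open bin index range [i0, i1)


@dataclass(frozen=True)
class TimeWindow:
    """Time window in ps, measured from the maximum of the IRF."""

    t_start: float
    t_end: float

    def __post_init__(self):
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")


#: windows used for depth-sensitivity contrasts: 0.5-1 ns early, 3-4 ns late
EARLY_WINDOW = TimeWindow(500.0, 1000.0)
LATE_WINDOW = TimeWindow(3000.0, 4000.0)


@dataclass(frozen=True)
class ContrastRecord:
    """Changes of five DTOF measurands relative to an unperturbed reference.

    dA_* = -ln(N_TW / N_TW,0); dm1 = m1,0 - m1; dV = V0 - V.
    """

    dA_early: float
    dA_total: float
    dA_late: float
    dm1: float               # ps
    dV: float                # ps^2
    position: float = float("nan")  # cm


def subtract_background(
    dtof: DTOF,
    irf_max_time: float | None = None,
    *,
    n_bins: int = 100,
    guard_ps: float = 500.0,
    rise_guard_ps: float = 200.0,
) -> DTOF:
    """Remove the uniform background estimated from pre-signal bins.

    The background is the mean of up to ``n_bins`` bins preceding
    (IRF maximum - ``guard_ps``) when ``irf_max_time`` is given, or
    preceding (rising edge - ``rise_guard_ps``) otherwise, where the
    rising edge is the first crossing of 5 % of the maximum.  The window
    must not touch the signal: anchoring on the DTOF peak would be wrong
    because diffusion delays the peak well past the rising edge.
    Negative residuals are clipped at zero so downstream moment sums stay
    nonnegative.
    """
    counts = np.asarray(dtof.counts, dtype=float)
    ipk = int(np.argmax(counts))
    if irf_max_time is not None:
        edge = int((irf_max_time - guard_ps) / dtof.bin_width)
    else:
        i_rise = int(np.nonzero(counts >= 0.05 * counts[ipk])[0][0])
        edge = i_rise - int(round(rise_guard_ps / dtof.bin_width))
    if ipk < 50 or edge < 50:
        raise BackgroundError("peak too close to the start of the histogram")
    lo = max(0, edge - n_bins)
    bkg = counts[lo:edge].mean()
    if counts[ipk] <= bkg + 10.0 * np.sqrt(bkg + 1.0):
        raise BackgroundError("no significant peak above the background level")
    sub = np.clip(counts - bkg, 0.0, None)
    out = replace(dtof, counts=sub)
    out.background_level = bkg
    return out


def _threshold_region(counts: np.ndarray, threshold_fraction: float, inclusive: bool):
    cmax = counts.max()
    if cmax <= 0:
        raise ValueError("histogram has no positive counts")
    level = threshold_fraction * cmax
    mask = counts >= level if inclusive else counts > level
    if not mask.any():
        raise ValueError("no bins above the threshold")
    ipk = int(np.argmax(counts))
    i0 = ipk
    while i0 > 0 and mask[i0 - 1]:
        i0 -= 1
    i1 = ipk + 1
    while i1 < counts.size and mask[i1]:
        i1 += 1
    return i0, i1


def moments(
    dtof: DTOF,
    threshold_fraction: float = 0.01,
    *,
    inclusive: bool = False,
    region: tuple | None = None,
) -> Moments:
    """N, m1, V of a background-subtracted DTOF.

    Only time bins whose counts exceed ``threshold_fraction`` of the
    maximum are used (strictly greater by default; set ``inclusive`` for
    the >= convention used in depth-sensitivity scans), restricted to the
    contiguous region containing the peak.  A precomputed half-open bin
    ``region`` overrides the threshold search — used to hold the
    integration limits fixed across repeated acquisitions so temporal
    fluctuations reflect photon and instrument noise, not the jitter of
    the limits themselves.
    """
    counts = np.asarray(dtof.counts, dtype=float)
    if region is not None:
        i0, i1 = int(region[0]), int(region[1])
        if i1 <= i0 or i0 < 0 or i1 > counts.size:
            raise ValueError("invalid moment integration region")
    else:
        i0, i1 = _threshold_region(counts, threshold_fraction, inclusive)
    c = counts[i0:i1]
    t = dtof.times()[i0:i1]
    n = c.sum()
    m1 = float(np.dot(t, c) / n)
    var = float(np.dot(t * t, c) / n - m1 * m1)
    return Moments(n=float(n), m1=m1, var=max(var, 0.0), threshold_fraction=threshold_fraction, bins_used=(i0, i1))


def moment_series(
    dtofs: list,
    threshold_fraction: float = 0.01,
    *,
    inclusive: bool = False,
    fixed_region: bool = True,
) -> list:
    """Moments of repeated acquisitions of the same measurand.

    With ``fixed_region`` (default) the above-threshold region is
    determined once on the summed histogram and applied to every frame,
    so the series reflects the stability of the signal rather than the
    frame-to-frame jitter of the integration limits.
    """
    if not dtofs:
        raise ValueError("empty series")
    if not fixed_region:
        return [moments(d, threshold_fraction, inclusive=inclusive) for d in dtofs]
    summed = np.sum([np.asarray(d.counts, dtype=float) for d in dtofs], axis=0)
    region = _threshold_region(summed, threshold_fraction, inclusive)
    return [
        moments(d, threshold_fraction, inclusive=inclusive, region=region)
        for d in dtofs
    ]


def window_counts(dtof: DTOF, window: TimeWindow, irf_max_time: float) -> float:
    """Sum of counts with bin centers in [t_start, t_end) measured from the IRF maximum."""
    if window.t_end == window.t_start:
        return 0.0
    t = dtof.times() - irf_max_time
    if window.t_start >= t[-1] or window.t_end <= t[0]:
        raise ValueError("time window outside the histogram support")
    sel = (t >= window.t_start) & (t < window.t_end)
    return float(np.asarray(dtof.counts, dtype=float)[sel].sum())


def contrasts(
    measured: DTOF,
    reference: DTOF,
    irf_max_time: float,
    *,
    early: TimeWindow = EARLY_WINDOW,
    late: TimeWindow = LATE_WINDOW,
    threshold_fraction: float = 0.001,
    inclusive: bool = True,
    position: float = float("nan"),
) -> ContrastRecord:
    """Contrasts of N_early, N, N_late, m1 and V against the far-perturbation reference."""
    if measured.n_bins != reference.n_bins or measured.bin_width != reference.bin_width:
        raise ValueError("measured and reference DTOFs must share binning")
    mm = moments(measured, threshold_fraction, inclusive=inclusive)
    mr = moments(reference, threshold_fraction, inclusive=inclusive)
    pairs = []
    for win in (early, None, late):
        if win is None:
            n, n0 = mm.n, mr.n
        else:
            n = window_counts(measured, win, irf_max_time)
            n0 = window_counts(reference, win, irf_max_time)
        if n <= 0 or n0 <= 0:
            raise ValueError("zero window counts: attenuation change undefined")
        pairs.append(-np.log(n / n0))
    return ContrastRecord(
        dA_early=pairs[0],
        dA_total=pairs[1],
        dA_late=pairs[2],
        dm1=mr.m1 - mm.m1,
        dV=mr.var - mm.var,
        position=position,
    )


def epsilon_dnl(counts: np.ndarray, t_range: tuple, bin_width: float) -> float:
    """Differential nonlinearity: peak-to-peak over mean of counts inside ``t_range`` (ps)."""
    c = np.asarray(counts, dtype=float)
    t = (np.arange(c.size) + 0.5) * bin_width
    sel = (t >= t_range[0]) & (t < t_range[1])
    if not sel.any():
        raise ValueError("empty time range")
    sub = c[sel]
    mean = sub.mean()
    if mean <= 0:
        raise ValueError("mean counts in range must be > 0")
    return float((sub.max() - sub.min()) / mean)


@dataclass(frozen=True)
class FluctuationReport:
    """Temporal stability of repeated moment measurements."""

    std_n_percent: float     # std(N) as percent of mean(N)
    std_m1: float            # ps
    std_var: float           # ps^2


def temporal_fluctuations(series: list) -> FluctuationReport:
    """Sample standard deviations of N (relative, %), m1 and V over repeated acquisitions."""
    if len(series) < 2:
        raise ValueError("need at least two repeated measurements")
    n = np.array([m.n for m in series])
    m1 = np.array([m.m1 for m in series])
    v = np.array([m.var for m in series])
    return FluctuationReport(
        std_n_percent=float(100.0 * n.std(ddof=1) / n.mean()),
        std_m1=float(m1.std(ddof=1)),
        std_var=float(v.std(ddof=1)),
    )


def drift_correct(
    series: list,
    timestamps: np.ndarray,
    irf_start: Moments,
    t_start: float,
    irf_end: Moments,
    t_end: float,
) -> list:
    """Remove a linear-in-time instrument drift bracketed by two IRF acquisitions.

    The IRF moment offsets are interpolated linearly in time and removed
    from each sample: additively for m1 and V, multiplicatively for N.
    """
    ts = np.asarray(timestamps, dtype=float)
    if len(series) != ts.size:
        raise ValueError("series and timestamps must align")
    if np.any(ts < t_start) or np.any(ts > t_end):
        raise ValueError("timestamps must lie between the two IRF acquisitions")
    frac = (ts - t_start) / (t_end - t_start)
    dm1 = irf_end.m1 - irf_start.m1
    dv = irf_end.var - irf_start.var
    ratio = irf_end.n / irf_start.n
    out = []
    for m, f in zip(series, frac):
        gain = (1.0 - f) + f * ratio
        out.append(
            Moments(
                n=m.n / gain,
                m1=m.m1 - f * dm1,
                var=m.var - f * dv,
                threshold_fraction=m.threshold_fraction,
                bins_used=m.bins_used,
            )
        )
    return out


def rebin_time(series: list, k: int) -> list:
    """Sum consecutive DTOFs k-at-a-time (trailing remainder dropped with a log note)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return list(series)
    n_full = len(series) // k
    if len(series) % k:
        log.info("rebin_time: dropping %d trailing frame(s)", len(series) % k)
    out = []
    for i in range(n_full):
        chunk = series[i * k : (i + 1) * k]
        counts = np.sum([np.asarray(d.counts) for d in chunk], axis=0)
        first = chunk[0]
        out.append(
            replace(
                first,
                counts=counts,
                acquisition_time=first.acquisition_time * k,
            )
        )
    return out
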