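"""Depth and lateral sensitivity to a small localized absorption change.

The primary engine is a first-order Born model built from image-source
diffusion Green's functions for the semi-infinite medium: a perturbation
of strength delta_mua * V at point r_p changes the detected time-resolved
signal by

    dPhi(t) = -delta_mua * V * int_0^t G(r_s -> r_p, tau) G(r_p -> r_d, t - tau) dtau

where G is the extrapolated-boundary fluence Green's function.  The
measured signal and the kernel share this fluence convention so contrast
ratios are well defined.  Contrasts of five measurands (attenuation in
early / total / late windows, mean time of flight, variance) and the
sensitivity factors MPP = dA/dmua, MTSF = dm1/dmua, VSF = dV/dmua follow.

A photon-packet Monte-Carlo oracle (absorption weighting, partial
pathlengths through the perturbation volume, annular detector band,
Fresnel internal reflection) provides an independent transport-level
cross-check at desk scale.

Geometry: source fiber at the origin, detector at (rho, 0, 0), medium in
z > 0; depth scans move the perturbation below the source-detector
midpoint, lateral scans move it along y at a fixed depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import C_CM_PS, OpticalProperties, boundary_mismatch_factor
from .metrics import (
    EARLY_WINDOW,
    LATE_WINDOW,
    ContrastRecord,
    TimeWindow,
)

__all__ = [
    "Perturbation",
    "SensitivityProfile",
    "ContrastScan",
    "fluence_tpsf",
    "perturbed_tpsf",
    "scan_contrasts",
    "sensitivity_factors",
    "mc_oracle",
    "MCResult",
]


def cylinder_volume_mm3(diameter_mm: float, length_mm: float) -> float:
    """Volume (mm^3) of a cylindrical inclusion, e.g. 5 mm x 5 mm -> ~98 mm^3."""
    if diameter_mm <= 0 or length_mm <= 0:
        raise ValueError("diameter and length must be positive")
    return np.pi * (diameter_mm / 2.0) ** 2 * length_mm


@dataclass(frozen=True)
class Perturbation:
    """Small absorbing inclusion: center (cm, z = depth below surface), volume (mm^3)."""

    center: tuple
    volume: float            # mm^3
    delta_mua: float         # 1/cm

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("volume must be > 0")

    @property
    def volume_cm3(self) -> float:
        return self.volume * 1e-3

    @property
    def equivalent_radius(self) -> float:
        """Radius (cm) of the sphere with the same volume."""
        return (3.0 * self.volume_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SensitivityProfile:
    positions: np.ndarray    # cm
    mpp: np.ndarray          # cm
    mtsf: np.ndarray         # ps cm
    vsf: np.ndarray          # ps^2 cm


@dataclass
class ContrastScan:
    positions: np.ndarray
    records: list
    mode: str                # 'depth' | 'lateral'

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(r, attr) for r in self.records])


def _g_infinite(dist, times, v, D, mua):
    t = np.asarray(times, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    k = 4.0 * D * v * tp
    out[pos] = v * (np.pi * k) ** -1.5 * np.exp(-dist**2 / k - mua * v * tp)
    return out


def _g_semi(p1, p2, times, props, zb):
    """Extrapolated-boundary fluence Green's function between two interior points."""
    v = C_CM_PS / props.n_medium
    D = 1.0 / (3.0 * props.musp)
    d = np.linalg.norm(np.subtract(p2, p1))
    p1m = (p1[0], p1[1], -p1[2] - 2.0 * zb)
    dm = np.linalg.norm(np.subtract(p2, p1m))
    return _g_infinite(d, times, v, D, props.mua) - _g_infinite(dm, times, v, D, props.mua)


def _geometry(rho, props, n_external):
    D = 1.0 / (3.0 * props.musp)
    zb = 2.0 * boundary_mismatch_factor(props.n_medium, n_external) * D
    z0 = 1.0 / props.musp
    src = (0.0, 0.0, z0)
    det = (rho, 0.0, 0.0)
    return src, det, zb


def fluence_tpsf(rho, times, props, n_external: float = 1.0) -> np.ndarray:
    """Unperturbed detected time curve in the fluence convention of this module."""
    src, det, zb = _geometry(rho, props, n_external)
    return _g_semi(src, det, times, props, zb)


def _submerged(center_z, radius):
    """Volume fraction of the equivalent sphere inside the medium and its centroid depth."""
    if center_z >= radius:
        return 1.0, center_z
    if center_z <= -radius:
        return 0.0, 0.0
    z = np.linspace(max(0.0, center_z - radius), center_z + radius, 129)
    area = np.pi * np.clip(radius**2 - (z - center_z) ** 2, 0.0, None)
    vol = np.trapezoid(area, z)
    frac = vol / (4.0 / 3.0 * np.pi * radius**3)
    centroid = np.trapezoid(z * area, z) / vol
    return float(frac), float(centroid)


def perturbed_tpsf(
    props: OpticalProperties,
    rho: float,
    pert: Perturbation,
    times,
    n_external: float = 1.0,
):
    """First-order Born perturbed curve.

    Returns (r0, r_pert, degraded) where ``degraded`` flags a perturbation
    closer than 2 mm to the source or detector (model accuracy degraded).
    The perturbation is treated as a point of strength delta_mua * V at its
    center; shallow centers use the submerged fraction of the equivalent
    sphere and its centroid.
    """
    t = np.asarray(times, dtype=float)
    src, det, zb = _geometry(rho, props, n_external)
    r0 = _g_semi(src, det, t, props, zb)
    x, y, z = pert.center
    frac, z_eff = _submerged(z, pert.equivalent_radius)
    if frac <= 0.0 or pert.delta_mua == 0.0:
        return r0, r0.copy(), False
    p = (x, y, max(z_eff, 1e-3))
    degraded = (
        np.linalg.norm(np.subtract(p, src)) < 0.2
        or np.linalg.norm(np.subtract(p, det)) < 0.2
    )
    g1 = _g_semi(src, p, t, props, zb)
    g2 = _g_semi(p, det, t, props, zb)
    dt = t[1] - t[0] if t.size > 1 else 1.0
    kernel = np.convolve(g1, g2)[: t.size] * dt
    r_pert = np.clip(r0 - pert.delta_mua * pert.volume_cm3 * frac * kernel, 0.0, None)
    return r0, r_pert, bool(degraded)


def scan_contrasts(
    props: OpticalProperties,
    rho: float,
    pert_template: Perturbation,
    positions,
    mode: str = "depth",
    *,
    lateral_depth: float = 1.5,
    times=None,
    early: TimeWindow = EARLY_WINDOW,
    late: TimeWindow = LATE_WINDOW,
    threshold_fraction: float = 0.001,
    n_external: float = 1.0,
) -> ContrastScan:
    """Noiseless Born contrasts versus perturbation position.

    ``mode='depth'`` moves the center to (rho/2, 0, pos); ``mode='lateral'``
    to (rho/2, pos, lateral_depth).  The reference is the unperturbed curve
    (perturbation at infinity).
    """
    from .forward import DTOF
    from .metrics import contrasts as _contrasts

    if mode not in ("depth", "lateral"):
        raise ValueError("mode must be 'depth' or 'lateral'")
    if times is None:
        times = (np.arange(1024) + 0.5) * 9.77
    times = np.asarray(times, dtype=float)
    bw = times[1] - times[0]
    positions = np.asarray(positions, dtype=float)

    r0 = fluence_tpsf(rho, times, props, n_external)
    scale = 1e9 / r0.max()  # common arbitrary scale; contrasts are scale-free
    ref = DTOF(counts=r0 * scale, bin_width=bw, rho=rho)
    records = []
    for pos in positions:
        center = (rho / 2.0, 0.0, pos) if mode == "depth" else (rho / 2.0, pos, lateral_depth)
        pert = Perturbation(center, pert_template.volume, pert_template.delta_mua)
        _, rp, _ = perturbed_tpsf(props, rho, pert, times, n_external)
        meas = DTOF(counts=rp * scale, bin_width=bw, rho=rho)
        rec = _contrasts(
            meas,
            ref,
            irf_max_time=0.0,
            early=early,
            late=late,
            threshold_fraction=threshold_fraction,
            inclusive=True,
            position=float(pos),
        )
        records.append(rec)
    return ContrastScan(positions=positions, records=records, mode=mode)


def sensitivity_factors(scan: ContrastScan, delta_mua: float) -> SensitivityProfile:
    """MPP, MTSF, VSF profiles: contrast per unit localized mua change."""
    if delta_mua == 0:
        raise ValueError("delta_mua must be nonzero")
    return SensitivityProfile(
        positions=scan.positions,
        mpp=scan.array("dA_total") / delta_mua,
        mtsf=scan.array("dm1") / delta_mua,
        vsf=scan.array("dV") / delta_mua,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _mc_walk(n_photons, musp, n_rel, cx, cy, cz, radius, det_x, det_radius, max_len, seed):
    """Scattering-only random walk in z > 0 (g = 0, step ~ Exp(musp)).

    Absorption is applied as exp(-mua * L) afterwards.  Detection is a disc
    of radius ``det_radius`` centered at (det_x, 0, 0): the detector must be
    a localized patch, not a full annulus, because the perturbation breaks
    the cylindrical symmetry and ring-averaging would dilute the contrast.
    Returns per-detected photon: total pathlength, partial pathlength in
    the perturbation sphere, plus escaped/truncated pathlength tallies for
    energy bookkeeping.
    """
    np.random.seed(seed)
    cap = max(16, n_photons // 4)
    det_len = np.empty(cap)
    det_lp = np.empty(cap)
    esc_len = np.empty(n_photons)
    n_esc = 0
    n_det = 0
    n_trunc = 0
    trunc_len = np.empty(n_photons)
    crit = 0.0
    if n_rel > 1.0:
        crit = np.sqrt(1.0 - 1.0 / (n_rel * n_rel))  # cos of critical angle
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        L = 0.0
        Lp = 0.0
        alive = True
        while alive:
            s = -np.log(np.random.random()) / musp
            hit = False
            if uz < 0.0 and z + uz * s < 0.0:
                s = -z / uz
                hit = True
            # chord of this segment inside the perturbation sphere
            if radius > 0.0:
                px = x - cx
                py = y - cy
                pz = z - cz
                b = px * ux + py * uy + pz * uz
                c = px * px + py * py + pz * pz - radius * radius
                disc = b * b - c
                if disc > 0.0:
                    rt = np.sqrt(disc)
                    u0 = -b - rt
                    u1 = -b + rt
                    if u0 < 0.0:
                        u0 = 0.0
                    if u1 > s:
                        u1 = s
                    if u1 > u0:
                        Lp += u1 - u0
            x += ux * s
            y += uy * s
            z += uz * s
            L += s
            if L > max_len:
                trunc_len[n_trunc] = L
                n_trunc += 1
                alive = False
            elif hit:
                z = 0.0
                cos_i = -uz
                refl = 1.0
                if n_rel <= 1.0 or cos_i > crit:
                    # Fresnel (unpolarized) at internal incidence
                    sin_t = n_rel * np.sqrt(max(0.0, 1.0 - cos_i * cos_i))
                    if sin_t < 1.0:
                        cos_t = np.sqrt(1.0 - sin_t * sin_t)
                        rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
                        rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
                        refl = 0.5 * (rs * rs + rp * rp)
                if np.random.random() < refl:
                    uz = -uz
                else:
                    dx = x - det_x
                    if dx * dx + y * y <= det_radius * det_radius:
                        if n_det < cap:
                            det_len[n_det] = L
                            det_lp[n_det] = Lp
                            n_det += 1
                    else:
                        esc_len[n_esc] = L
                        n_esc += 1
                    alive = False
            else:
                # isotropic scattering
                uz = 2.0 * np.random.random() - 1.0
                phi = 2.0 * np.pi * np.random.random()
                sin_th = np.sqrt(1.0 - uz * uz)
                ux = sin_th * np.cos(phi)
                uy = sin_th * np.sin(phi)
    return det_len[:n_det], det_lp[:n_det], esc_len[:n_esc], trunc_len[:n_trunc]


@dataclass(frozen=True)
class MCResult:
    """Monte-Carlo contrasts with bootstrap standard errors and energy tallies."""

    contrast: ContrastRecord
    stderr: ContrastRecord
    n_detected: int
    detected_weight: float
    escaped_weight: float
    absorbed_weight: float
    truncated_weight: float
    launched: int


def _mc_moments(t, w):
    n = w.sum()
    m1 = np.dot(t, w) / n
    var = np.dot(t * t, w) / n - m1 * m1
    return n, m1, var


def _mc_contrast(t, w0, w1, early, late):
    n0, m10, v0 = _mc_moments(t, w0)
    n1, m11, v1 = _mc_moments(t, w1)
    rec = {}
    for name, win in (("dA_early", early), ("dA_total", None), ("dA_late", late)):
        if win is None:
            rec[name] = -np.log(n1 / n0)
        else:
            sel = (t >= win.t_start) & (t < win.t_end)
            s0 = w0[sel].sum()
            s1 = w1[sel].sum()
            if s0 <= 0 or s1 <= 0:
                raise ValueError("no detected photons inside a time window")
            rec[name] = -np.log(s1 / s0)
    rec["dm1"] = m10 - m11
    rec["dV"] = v0 - v1
    return rec


def mc_oracle(
    props: OpticalProperties,
    rho: float,
    pert: Perturbation,
    n_photons: int,
    seed: int,
    *,
    det_radius: float = 0.25,
    early: TimeWindow = EARLY_WINDOW,
    late: TimeWindow = LATE_WINDOW,
    n_external: float = 1.0,
    t_max: float = 12500.0,
    n_bootstrap: int = 200,
) -> MCResult:
    """Photon-packet MC estimate of the five contrasts for one perturbation.

    Photons are launched at the origin into the medium; detection is a
    disc of radius ``det_radius`` (cm) around the detector position
    (rho, 0, 0), matching the point-detector geometry of the Born engine.
    The perturbation is the volume-equivalent sphere at the perturbation
    center; its effect is the exact extra attenuation
    exp(-delta_mua * L_pert) from the recorded partial pathlengths, so the
    same photon set yields the perturbed and unperturbed estimates
    (strongly correlated, low-variance contrast).
    """
    if n_photons > 10**7:
        raise ValueError("n_photons capped at 1e7 (desk scale)")
    v = C_CM_PS / props.n_medium
    cx, cy, cz = pert.center
    det_len, det_lp, esc_len, trunc_len = _mc_walk(
        int(n_photons),
        props.musp,
        props.n_medium / n_external,
        cx,
        cy,
        cz,
        pert.equivalent_radius,
        rho,
        det_radius,
        t_max * v,
        int(seed) & 0x7FFFFFFF,
    )
    if det_len.size == 0:
        raise ValueError("zero detected photons")
    t = det_len / v
    w0 = np.exp(-props.mua * det_len)
    w1 = w0 * np.exp(-pert.delta_mua * det_lp)

    point = _mc_contrast(t, w0, w1, early, late)

    rng = np.random.default_rng(seed)
    boot = {k: np.empty(n_bootstrap) for k in point}
    idx_n = t.size
    for b in range(n_bootstrap):
        idx = rng.integers(0, idx_n, idx_n)
        rb = _mc_contrast(t[idx], w0[idx], w1[idx], early, late)
        for k in boot:
            boot[k][b] = rb[k]
    se = {k: float(np.std(boot[k], ddof=1)) for k in boot}

    detected_w = float(w0.sum())
    escaped_w = float(np.exp(-props.mua * esc_len).sum())
    truncated_w = float(np.exp(-props.mua * trunc_len).sum())
    absorbed_w = float(
        (1.0 - np.exp(-props.mua * det_len)).sum()
        + (1.0 - np.exp(-props.mua * esc_len)).sum()
        + (1.0 - np.exp(-props.mua * trunc_len)).sum()
    )
    return MCResult(
        contrast=ContrastRecord(position=float(cz), **point),
        stderr=ContrastRecord(position=float("nan"), **se),
        n_detected=int(t.size),
        detected_weight=detected_w,
        escaped_weight=escaped_w,
        absorbed_weight=absorbed_w,
        truncated_weight=truncated_w,
        launched=int(n_photons),
    )
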