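"""Born-model perturbation sensitivity and its Monte-Carlo cross-checks."""

import numpy as np
import pytest

from tdnirs.forward import C_CM_PS, OpticalProperties
from tdnirs.sensitivity import (
    Perturbation,
    cylinder_volume_mm3,
    fluence_tpsf,
    mc_oracle,
    perturbed_tpsf,
    scan_contrasts,
    sensitivity_factors,
    _geometry,
)

SOLID = OpticalProperties(0.1, 8.0, 1.55)
LIQUID = OpticalProperties(0.026, 10.5, 1.33)
TIMES = (np.arange(1024) + 0.5) * 9.77


class TestPerturbedTPSF:
    def test_zero_strength_is_identity(self):
        pert = Perturbation((1.5, 0.0, 1.5), 98.0, 0.0)
        r0, rp, _ = perturbed_tpsf(SOLID, 3.0, pert, TIMES)
        assert np.array_equal(r0, rp)

    def test_very_deep_perturbation_has_no_effect(self):
        pert = Perturbation((1.5, 0.0, 10.0), 98.0, 0.017)
        r0, rp, _ = perturbed_tpsf(SOLID, 3.0, pert, TIMES)
        assert np.max(np.abs(r0 - rp)) < 1e-6 * r0.max()

    def test_reciprocity_for_midplane_perturbation(self):
        # mirroring the perturbation about the source-detector midplane is
        # equivalent to swapping source and detector
        pert_a = Perturbation((1.0, 0.4, 1.2), 98.0, 0.017)
        pert_b = Perturbation((2.0, 0.4, 1.2), 98.0, 0.017)
        _, rp_a, _ = perturbed_tpsf(SOLID, 3.0, pert_a, TIMES)
        _, rp_b, _ = perturbed_tpsf(SOLID, 3.0, pert_b, TIMES)
        assert np.allclose(rp_a, rp_b, rtol=1e-9)

    def test_near_fiber_perturbation_flagged(self):
        pert = Perturbation((0.05, 0.0, 0.15), 98.0, 0.017)
        _, _, degraded = perturbed_tpsf(SOLID, 3.0, pert, TIMES)
        assert degraded

    def test_above_surface_center_fully_clipped(self):
        pert = Perturbation((1.5, 0.0, -1.0), 98.0, 0.017)
        r0, rp, _ = perturbed_tpsf(SOLID, 3.0, pert, TIMES)
        assert np.array_equal(r0, rp)


class TestScans:
    @pytest.mark.parametrize("props,thr", [(SOLID, 0.001), (LIQUID, 0.02)])
    def test_depth_of_max_ordering(self, props, thr):
        # higher-order moments peak deeper: dA < dm1 < dV
        pert = Perturbation((0, 0, 0), 98.0, 0.017)
        scan = scan_contrasts(props, 3.0, pert, np.arange(0.2, 3.01, 0.1), "depth",
                              threshold_fraction=thr)
        pos = scan.positions
        # signed maxima: the deep positive sensitivity lobes
        d_a = pos[np.argmax(scan.array("dA_total"))]
        d_m1 = pos[np.argmax(scan.array("dm1"))]
        d_v = pos[np.argmax(scan.array("dV"))]
        assert d_a < d_m1 < d_v

    def test_shallow_vs_deep_moment_signs(self):
        pert = Perturbation((0, 0, 0), 98.0, 0.017)
        scan = scan_contrasts(SOLID, 3.0, pert, [0.5, 2.0], "depth")
        shallow, deep = scan.records
        assert shallow.dm1 < 0 and shallow.dV < 0
        assert deep.dm1 > 0 and deep.dV > 0

    def test_lateral_scan_symmetry(self):
        pert = Perturbation((0, 0, 0), 98.0, 0.017)
        xs = np.arange(-3.0, 3.01, 0.5)
        scan = scan_contrasts(SOLID, 3.0, pert, xs, "lateral", lateral_depth=1.5)
        da = scan.array("dA_total")
        assert np.allclose(da, da[::-1], rtol=1e-9, atol=1e-12)

    def test_liquid_preset_sees_deeper(self):
        # lower absorption -> larger contrast at 2 cm depth for every measurand
        pert_s = Perturbation((0, 0, 0), 98.0, 0.017)
        rec_s = scan_contrasts(SOLID, 3.0, pert_s, [2.0], "depth").records[0]
        rec_l = scan_contrasts(LIQUID, 3.0, pert_s, [2.0], "depth",
                               threshold_fraction=0.02).records[0]
        for name in ("dA_early", "dA_total", "dA_late", "dm1", "dV"):
            assert abs(getattr(rec_l, name)) > abs(getattr(rec_s, name))

    def test_first_order_linearity(self):
        pert = Perturbation((0, 0, 0), 98.0, 0.017)
        half = Perturbation((0, 0, 0), 49.0, 0.0085)
        full = scan_contrasts(SOLID, 3.0, pert, [1.0, 1.5, 2.0], "depth")
        quarter = scan_contrasts(SOLID, 3.0, half, [1.0, 1.5, 2.0], "depth")
        sf_full = sensitivity_factors(full, 0.017)
        sf_quarter = sensitivity_factors(quarter, 0.0085)
        # per unit dmua*V the profiles coincide within 2 %
        assert np.allclose(sf_full.mpp / 98.0, sf_quarter.mpp / 49.0, rtol=0.02)
        assert np.allclose(sf_full.vsf / 98.0, sf_quarter.vsf / 49.0, rtol=0.02)

    def test_profiles_vanish_beyond_four_cm(self):
        pert = Perturbation((0, 0, 0), 98.0, 0.017)
        scan = scan_contrasts(SOLID, 3.0, pert, [4.5, 5.0], "depth")
        sf = sensitivity_factors(scan, 0.017)
        assert np.all(np.abs(sf.mpp) < 1e-4)
        assert np.all(np.abs(sf.mtsf) < 0.05)

    def test_zero_delta_mua_rejected(self):
        pert = Perturbation((0, 0, 0), 98.0, 0.017)
        scan = scan_contrasts(SOLID, 3.0, pert, [1.0], "depth")
        with pytest.raises(ValueError):
            sensitivity_factors(scan, 0.0)


def test_mpp_sum_rule_conserves_total_pathlength():
    """Unit perturbations summed over the whole (extrapolated) domain must
    recover the total mean pathlength v*m1 of the unperturbed curve."""
    props = SOLID
    rho = 3.0
    src, det, zb = _geometry(rho, props, 1.0)
    D = 1.0 / (3.0 * props.musp)
    mueff = np.sqrt(3.0 * props.mua * props.musp)
    v = C_CM_PS / props.n_medium

    times = (np.arange(4096) + 0.5) * 9.77
    r0 = fluence_tpsf(rho, times, props)
    v_m1 = v * float((times * r0).sum() / r0.sum())

    # CW grid sum over the extended domain z > -zb (image solution's domain),
    # with a voxel-scale distance floor at the two singular points
    h = 0.05
    xs = np.arange(-3 + h / 2, 6, h)
    ys = np.arange(-4 + h / 2, 4, h)
    zs = np.arange(-zb + h / 2, 6, h)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    def gcw(p):
        d = np.maximum(
            np.sqrt((X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2), 0.62 * h
        )
        dm = np.sqrt((X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z + p[2] + 2 * zb) ** 2)
        return np.exp(-mueff * d) / (4 * np.pi * D * d) - np.exp(-mueff * dm) / (
            4 * np.pi * D * dm
        )

    d_sd = np.linalg.norm(np.subtract(det, src))
    dm_sd = np.linalg.norm(np.subtract(det, (src[0], src[1], -src[2] - 2 * zb)))
    g_sd = np.exp(-mueff * d_sd) / (4 * np.pi * D * d_sd) - np.exp(-mueff * dm_sd) / (
        4 * np.pi * D * dm_sd
    )
    total = float((gcw(src) * gcw(det)).sum()) * h**3 / g_sd
    assert total == pytest.approx(v_m1, rel=0.05)


class TestMCOracle:
    def test_zero_perturbation_gives_zero_contrasts(self):
        pert = Perturbation((1.5, 0.0, 1.5), 98.0, 0.0)
        res = mc_oracle(SOLID, 3.0, pert, 200_000, seed=1)
        assert res.contrast.dA_total == 0.0
        assert res.contrast.dm1 == 0.0
        assert res.contrast.dV == 0.0

    def test_energy_conservation(self):
        pert = Perturbation((1.5, 0.0, 1.5), 98.0, 0.017)
        res = mc_oracle(SOLID, 3.0, pert, 200_000, seed=2)
        total = (
            res.detected_weight
            + res.escaped_weight
            + res.absorbed_weight
            + res.truncated_weight
        )
        assert total == pytest.approx(res.launched, rel=1e-6)

    def test_seed_reproducibility(self):
        pert = Perturbation((1.5, 0.0, 1.5), 98.0, 0.017)
        a = mc_oracle(SOLID, 3.0, pert, 400_000, seed=3)
        b = mc_oracle(SOLID, 3.0, pert, 400_000, seed=3)
        assert a.contrast.dA_total == b.contrast.dA_total
        assert a.n_detected == b.n_detected

    def test_photon_cap_enforced(self):
        pert = Perturbation((1.5, 0.0, 1.5), 98.0, 0.017)
        with pytest.raises(ValueError):
            mc_oracle(SOLID, 3.0, pert, 10**7 + 1, seed=0)


def test_cylinder_volumes_match_printed_values():
    assert round(cylinder_volume_mm3(5.0, 5.0)) == 98
    assert round(cylinder_volume_mm3(4.0, 4.0)) == 50
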