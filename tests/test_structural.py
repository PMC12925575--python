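"""Structural parameters: analytic oracles and conservation laws.

Closed-form oracles: uniform cube (compartment stats), spherical shell
(cortical thickness/sBMD), digitized annulus (CSA/CSMI/Z against the exact
annulus formulas), cube projection (aBMD).
"""

import numpy as np
import pytest
import trimesh

from hipfe.phantom import (
    BACKGROUND, CORTICAL, TRABECULAR, REGION_NECK, REGION_SHAFT,
    AnatomicalFrame, FemurPhantom,
)
from hipfe.structural import (
    REFERENCE_CURVES, ReferenceCurve, compartment_stats,
    cortical_surface_measures, cross_section_props, project_abmd, t_score,
)


def make_phantom(image, spacing, compartment, region, frame=None, mesh=None,
                 mesh_regions=None):
    if mesh is None:
        mesh = trimesh.Trimesh(vertices=np.zeros((3, 3)),
                               faces=[[0, 1, 2]], process=False)
        mesh_regions = np.zeros(3, np.uint8)
    if frame is None:
        frame = AnatomicalFrame((0, 0, 50), 10.0, (1, 0, 0), (0, 0, 1),
                                (0, 0, 0), 50.0)
    return FemurPhantom(image=image.astype(np.float32), spacing=spacing,
                        origin=np.zeros(3), compartment_mask=compartment,
                        region_mask=region, mesh=mesh,
                        mesh_regions=mesh_regions, frame=frame)


# ---------------------------------------------------------------------------
# compartment stats


def test_uniform_cube_stats():
    """1 cm^3 cube at 300 mg/cm^3 labelled trabecular -> BMC 300 mg."""
    n = 10  # 10 x 10 x 10 voxels of 1 mm = 1 cm^3
    img = np.zeros((n + 2,) * 3)
    comp = np.zeros_like(img, np.uint8)
    reg = np.zeros_like(img, np.uint8)
    img[1:-1, 1:-1, 1:-1] = 300.0
    comp[1:-1, 1:-1, 1:-1] = TRABECULAR
    reg[1:-1, 1:-1, 1:-1] = REGION_NECK
    ph = make_phantom(img, 1.0, comp, reg)
    bmc, vbmd, vol = compartment_stats(ph, "trabecular", "neck")
    assert bmc == pytest.approx(300.0)
    assert vbmd == pytest.approx(300.0)
    assert vol == pytest.approx(1.0)


def test_partition_additivity(mean_phantom):
    """Integral BMC = cortical BMC + trabecular BMC, per region and for TH."""
    for region in ("neck", "trochanter", "shaft", "TH"):
        b_int, _, v_int = compartment_stats(mean_phantom, "integral", region)
        b_ct, _, v_ct = compartment_stats(mean_phantom, "cortical", region)
        b_tb, _, v_tb = compartment_stats(mean_phantom, "trabecular", region)
        assert b_int == pytest.approx(b_ct + b_tb, rel=1e-9)
        assert v_int == pytest.approx(v_ct + v_tb, rel=1e-9)
    # TH aggregates the three regions
    th = compartment_stats(mean_phantom, "integral", "TH")[0]
    parts = sum(compartment_stats(mean_phantom, "integral", r)[0]
                for r in ("neck", "trochanter", "shaft"))
    assert th == pytest.approx(parts, rel=1e-9)


def test_empty_mask_error(mean_phantom):
    img = np.zeros((4, 4, 4))
    ph = make_phantom(img, 1.0, np.zeros_like(img, np.uint8),
                      np.zeros_like(img, np.uint8))
    with pytest.raises(ValueError, match="trabecular.*neck|neck"):
        compartment_stats(ph, "trabecular", "neck")


def test_tb_vbmd_calibration(mean_phantom):
    """Mean phantom reproduces the TH trabecular vBMD target within 10 %."""
    _, vbmd, _ = compartment_stats(mean_phantom, "trabecular", "TH")
    assert vbmd == pytest.approx(162.0, rel=0.10)


# ---------------------------------------------------------------------------
# cortical surface measures


def _spherical_shell_phantom(r_out=15.0, thickness=2.0, density=800.0,
                             spacing=0.5):
    n = int(2 * (r_out + 4) / spacing)
    ax = (np.arange(n) - n / 2 + 0.5) * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z)
    comp = np.zeros(r.shape, np.uint8)
    comp[r < r_out] = TRABECULAR
    comp[(r < r_out) & (r >= r_out - thickness)] = CORTICAL
    img = np.where(comp == CORTICAL, density, 0.0)
    reg = np.where(comp > 0, REGION_NECK, 0).astype(np.uint8)
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=r_out)
    mesh = trimesh.Trimesh(vertices=sphere.vertices, faces=sphere.faces,
                           process=False)
    ph = make_phantom(img, spacing, comp, reg, mesh=mesh,
                      mesh_regions=np.full(len(mesh.vertices), REGION_NECK,
                                           np.uint8))
    ph.origin = np.array([ax[0], ax[0], ax[0]])
    return ph


def test_spherical_shell_oracle():
    """2 mm shell at 800 mg/cm^3: CTh ~2 mm, sBMD ~160 mg/cm^2 everywhere."""
    ph = _spherical_shell_phantom()
    cth, sbmd, ct_vbmd = cortical_surface_measures(ph)
    ok = ~np.isnan(cth)
    assert ok.mean() > 0.95
    assert np.nanmedian(cth) == pytest.approx(2.0, abs=0.3)
    assert np.nanmedian(sbmd) == pytest.approx(160.0, rel=0.15)
    # per-vertex identity sbmd = ct_vbmd * cth (unit-consistent)
    np.testing.assert_allclose(sbmd[ok], ct_vbmd[ok] * cth[ok] / 10.0,
                               rtol=1e-12)


def test_density_doubling_scales_sbmd_not_cth():
    ph1 = _spherical_shell_phantom(density=800.0)
    ph2 = _spherical_shell_phantom(density=1600.0)
    c1, s1, _ = cortical_surface_measures(ph1)
    c2, s2, _ = cortical_surface_measures(ph2)
    np.testing.assert_allclose(c1, c2, equal_nan=True)
    ok = ~np.isnan(s1)
    np.testing.assert_allclose(s2[ok], 2 * s1[ok], rtol=1e-9)


# ---------------------------------------------------------------------------
# cross sections


def _annulus_phantom(r_out=15.0, r_in=12.0, density=1000.0, spacing=0.5,
                     length=30.0, offset=(0.0, 0.0)):
    nz = int(length / spacing)
    nxy = int(2 * (r_out + 5) / spacing)
    ax = (np.arange(nxy) - nxy / 2 + 0.5) * spacing
    x, y = np.meshgrid(ax, ax, indexing="ij")
    r = np.sqrt((x - offset[0]) ** 2 + (y - offset[1]) ** 2)
    ring2d = (r < r_out) & (r >= r_in)
    img = np.zeros((nxy, nxy, nz))
    img[..., :] = np.where(ring2d, density, 0.0)[..., None]
    comp = np.where(img > 0, CORTICAL, 0).astype(np.uint8)
    reg = np.where(img > 0, REGION_SHAFT, 0).astype(np.uint8)
    # frame whose IT section plane is z = length/2, perpendicular to z
    frame = AnatomicalFrame(
        head_center=(offset[0], offset[1], length), head_radius=1.0,
        neck_axis=(0.17364818, 0.0, 0.98480775), shaft_axis=(0.0, 0.0, 1.0),
        gt_point=(offset[0] + r_out, offset[1], 0.0), head_gt_distance=30.0,
        neck_base=(offset[0], offset[1], length / 2.0))
    ph = make_phantom(img, spacing, comp, reg, frame=frame)
    ph.origin = np.array([ax[0], ax[0], 0.0])
    return ph


ANNULUS_SA = np.pi * (15.0 ** 2 - 12.0 ** 2)           # 254.469 mm^2
ANNULUS_CSMI = np.pi / 2 * (15.0 ** 4 - 12.0 ** 4)     # 46947.8 mm^4
ANNULUS_Z = ANNULUS_CSMI / 15.0                        # 3129.85 mm^3


def test_annulus_closed_form():
    """Digitized annulus at 0.5 mm spacing matches the closed forms < 2 %."""
    ph = _annulus_phantom()
    sa, csa, csmi, z = cross_section_props(ph, "IT")
    assert sa == pytest.approx(ANNULUS_SA, rel=0.02)
    assert csa == pytest.approx(ANNULUS_SA, rel=0.02)  # w = 1 at 1000 mg/cm^3
    assert csmi == pytest.approx(ANNULUS_CSMI, rel=0.02)
    assert z == pytest.approx(ANNULUS_Z, rel=0.02)


def test_annulus_density_linearity():
    ph1 = _annulus_phantom(density=500.0)
    ph2 = _annulus_phantom(density=1000.0)
    sa1, csa1, csmi1, z1 = cross_section_props(ph1, "IT")
    sa2, csa2, csmi2, z2 = cross_section_props(ph2, "IT")
    assert sa1 == pytest.approx(sa2)              # SA is density independent
    assert csa2 == pytest.approx(2 * csa1, rel=1e-9)
    assert csmi2 == pytest.approx(2 * csmi1, rel=1e-9)
    assert z2 == pytest.approx(2 * z1, rel=1e-9)


def test_annulus_translation_invariance():
    sa0, csa0, csmi0, z0 = cross_section_props(_annulus_phantom(), "IT")
    sa1, csa1, csmi1, z1 = cross_section_props(
        _annulus_phantom(offset=(2.0, -1.5)), "IT")
    assert sa1 == pytest.approx(sa0, rel=0.01)
    assert csa1 == pytest.approx(csa0, rel=0.01)
    assert csmi1 == pytest.approx(csmi0, rel=0.015)
    assert z1 == pytest.approx(z0, rel=0.015)


def test_section_modulus_identity(mean_phantom):
    """Z * d_max = CSMI by construction of the section modulus."""
    sa, csa, csmi, z = cross_section_props(mean_phantom, "FN")
    assert csmi / z > 0  # d_max
    assert sa > csa  # density weight < 1 on real phantoms


# ---------------------------------------------------------------------------
# projection and T-scores


def test_cube_projection():
    """1 cm cube at 500 mg/cm^3 viewed face-on -> 0.5 g/cm^2."""
    n = 10
    img = np.zeros((n + 2, n + 2, n + 2))
    comp = np.zeros_like(img, np.uint8)
    reg = np.zeros_like(img, np.uint8)
    img[1:-1, 1:-1, 1:-1] = 500.0
    comp[1:-1, 1:-1, 1:-1] = TRABECULAR
    reg[1:-1, 1:-1, 1:-1] = REGION_NECK
    ph = make_phantom(img, 1.0, comp, reg)
    assert project_abmd(ph, "FN") == pytest.approx(0.5)
    # rotating the cube a quarter turn about the projection axis: symmetric
    ph_rot = make_phantom(np.transpose(img, (2, 1, 0)),
                          1.0, np.transpose(comp, (2, 1, 0)),
                          np.transpose(reg, (2, 1, 0)))
    assert project_abmd(ph_rot, "FN") == pytest.approx(0.5)


def test_projection_conserves_bmc(mean_phantom):
    """aBMD x projected area returns the ROI BMC to < 0.1 %."""
    abmd, area = project_abmd(mean_phantom, "TH", return_area=True)
    bmc_g = compartment_stats(mean_phantom, "integral", "TH")[0] / 1000.0
    assert abmd * area == pytest.approx(bmc_g, rel=1e-3)


def test_t_score_reference_roundtrip():
    """Frozen young-adult references reproduce the population pairings."""
    assert t_score(0.849, REFERENCE_CURVES["TH"]) == pytest.approx(-0.76, abs=0.01)
    assert t_score(0.813, REFERENCE_CURVES["TH"]) == pytest.approx(-1.06, abs=0.01)
    assert t_score(0.713, REFERENCE_CURVES["FN"]) == pytest.approx(-1.23, abs=0.01)
    assert t_score(0.677, REFERENCE_CURVES["FN"]) == pytest.approx(-1.55, abs=0.01)
    # round-trip on independent rows
    assert t_score(0.800, REFERENCE_CURVES["TH"]) == pytest.approx(-1.16, abs=0.02)
    assert t_score(0.669, REFERENCE_CURVES["FN"]) == pytest.approx(-1.62, abs=0.02)


def test_t_score_identity_and_monotonicity():
    ref = ReferenceCurve("TH", 0.94, 0.12)
    assert t_score(0.94, ref) == 0.0
    assert t_score(0.95, ref) > t_score(0.93, ref)
    with pytest.raises(ValueError):
        ReferenceCurve("TH", 0.94, -1.0)
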