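"""Densitometric and structural parameters of the proximal femur.

Computes, from a :class:`~hipfe.phantom.FemurPhantom`, the standard set of
hip parameters: compartment BMC/vBMD/volume per region, vertex-wise cortical
thickness and surface BMD (sBMD = cortical vBMD x CTh), density-weighted
cross-sectional properties (SA, CSA, CSMI, section modulus Z) at the femoral
neck (FN) and intertrochanteric (IT) sections, projected areal BMD for the
total hip (TH) and FN regions, and DXA-style T-scores.

Unit conventions: images are mg/cm^3 and lengths mm internally; aBMD is
reported in g/cm^2 and sBMD in mg/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import (
    BACKGROUND, CORTICAL, TRABECULAR,
    REGION_NECK, REGION_TROCH, REGION_SHAFT,
    FemurPhantom,
)

#: reference density used to normalise the density weight w = vBMD / RHO_REF
#: in CSA/CSMI (hip-structural-analysis convention: fully mineralised
#: cortical bone ~1000 mg/cm^3).
RHO_REF = 1000.0

TH_REGIONS = (REGION_NECK, REGION_TROCH, REGION_SHAFT)

_REGION_SETS = {
    "neck": (REGION_NECK,),
    "trochanter": (REGION_TROCH,),
    "shaft": (REGION_SHAFT,),
    "TH": TH_REGIONS,
    "FN": (REGION_NECK,),
}

_COMPARTMENT_SETS = {
    "trabecular": (TRABECULAR,),
    "cortical": (CORTICAL,),
    "integral": (TRABECULAR, CORTICAL),
}


@dataclass(frozen=True)
class ReferenceCurve:
    """Young-adult reference used to convert aBMD to a T-score."""

    site: str
    young_adult_mean: float  # g/cm^2
    young_adult_sd: float    # g/cm^2

    def __post_init__(self):
        if self.young_adult_sd <= 0:
            raise ValueError("reference SD must be positive")


#: Young-adult reference curves recovered by inverting paired
#: (aBMD, T-score) population values at each site and frozen here.
REFERENCE_CURVES = {
    "TH": ReferenceCurve("TH", young_adult_mean=0.9402, young_adult_sd=0.1200),
    "FN": ReferenceCurve("FN", young_adult_mean=0.8514, young_adult_sd=0.1125),
}


@dataclass
class StructuralParams:
    """The 13 analysed densitometric/structural quantities plus aBMD/T-scores."""

    th_vbmd: float
    fn_vbmd: float
    th_tb_vbmd: float
    fn_tb_vbmd: float
    th_ct_vbmd: float
    fn_ct_vbmd: float
    th_ct_sbmd: float
    fn_ct_sbmd: float
    th_cth: float
    fn_cth: float
    fn_sa: float
    fn_csa: float
    fn_csmi: float
    fn_z: float
    th_abmd: float
    fn_abmd: float
    th_tscore: float
    fn_tscore: float


# ---------------------------------------------------------------------------
# compartment statistics


def compartment_stats(phantom: FemurPhantom, compartment: str, region: str):
    """BMC (mg), mean vBMD (mg/cm^3) and volume (cm^3) of a compartment/region.

    ``compartment`` is one of ``trabecular``, ``cortical``, ``integral``;
    ``region`` one of ``neck``, ``trochanter``, ``shaft``, ``TH``.
    """
    try:
        comp_labels = _COMPARTMENT_SETS[compartment]
        region_labels = _REGION_SETS[region]
    except KeyError as exc:
        raise ValueError(f"unknown compartment or region: {exc}") from None
    mask = np.isin(phantom.compartment_mask, comp_labels) & \
        np.isin(phantom.region_mask, region_labels)
    if not mask.any():
        raise ValueError(f"empty mask for compartment={compartment!r} region={region!r}")
    volume = float(mask.sum()) * phantom.voxel_volume_cm3
    bmc = float(phantom.image[mask].sum(dtype=np.float64)) * phantom.voxel_volume_cm3
    return bmc, bmc / volume, volume


# ---------------------------------------------------------------------------
# vertex-wise cortical measures


def cortical_surface_measures(phantom: FemurPhantom, max_depth_mm: float = 9.0,
                              entry_tol_mm: float = 3.0):
    """Per-vertex cortical thickness, surface BMD and cortical vBMD.

    For each mesh vertex a ray is cast along the inward normal with a step
    of a quarter voxel; the cortical thickness is the length of the
    contiguous cortical segment first crossed by the ray, the cortical vBMD
    the mean image value over that segment, and sBMD their (unit-consistent)
    product.  Rays that do not meet cortex within ``entry_tol_mm`` are
    flagged missing (NaN) and excluded from region averages.

    Returns ``(cth_mm, sbmd_mg_cm2, ct_vbmd_mg_cm3)`` arrays over vertices.
    """
    step = phantom.spacing / 4.0
    n_steps = int(np.ceil(max_depth_mm / step))
    verts = phantom.mesh.vertices
    normals = phantom.mesh.vertex_normals
    ts = step * np.arange(n_steps)
    pts = verts[:, None, :] - normals[:, None, :] * ts[None, :, None]
    idx = np.rint(phantom.world_to_index(pts.reshape(-1, 3))).astype(int)
    shape = phantom.compartment_mask.shape
    inside = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
    comp = np.zeros(len(idx), np.uint8)
    vals = np.zeros(len(idx), np.float32)
    ii = idx[inside]
    comp[inside] = phantom.compartment_mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    vals[inside] = phantom.image[ii[:, 0], ii[:, 1], ii[:, 2]]
    comp = comp.reshape(len(verts), n_steps)
    vals = vals.reshape(len(verts), n_steps)

    in_ct = comp == CORTICAL
    any_ct = in_ct.any(axis=1)
    first = np.argmax(in_ct, axis=1)
    # first non-cortical sample after entering the cortex
    after = (~in_ct) & (np.arange(n_steps)[None, :] > first[:, None])
    has_exit = after.any(axis=1)
    exit_i = np.where(has_exit, np.argmax(after, axis=1), n_steps)

    missing = (~any_ct) | (first * step > entry_tol_mm)
    cth = (exit_i - first) * step
    # mean vBMD over the cortical samples of the segment
    seg = in_ct & (np.arange(n_steps)[None, :] < exit_i[:, None])
    n_seg = seg.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ct_vbmd = np.where(n_seg > 0, (vals * seg).sum(axis=1) / np.maximum(n_seg, 1),
                           np.nan)
    cth = cth.astype(float)
    cth[missing] = np.nan
    ct_vbmd = ct_vbmd.astype(float)
    ct_vbmd[missing] = np.nan
    sbmd = ct_vbmd * cth / 10.0  # mg/cm^3 * cm -> mg/cm^2
    return cth, sbmd, ct_vbmd


# ---------------------------------------------------------------------------
# cross-sectional properties


def _section_plane(phantom: FemurPhantom, section: str):
    frame = phantom.frame
    head = np.asarray(frame.head_center)
    neck_axis = np.asarray(frame.neck_axis)
    base = np.asarray(frame.neck_base)
    if section == "FN":
        # mid-point of the free neck segment between head surface and base
        free_len = np.linalg.norm(head - base) - frame.head_radius
        center = head - neck_axis * (frame.head_radius + 0.5 * free_len)
        axis = neck_axis
    elif section == "IT":
        center = np.array([0.0, 0.0, base[2]])
        axis = np.asarray(frame.shaft_axis)
    else:
        raise ValueError(f"unknown section {section!r}")
    return center, axis / np.linalg.norm(axis)


def cross_section_props(phantom: FemurPhantom, section: str,
                        rho_ref: float = RHO_REF, half_extent_mm: float = 40.0):
    """Density-weighted cross-section properties at the FN or IT section.

    Returns ``(sa, csa, csmi, z)``: slice area (mm^2), density-weighted area
    (mm^2), density-weighted polar second moment about the weighted centroid
    (mm^4), and section modulus Z = CSMI / d_max (mm^3) where d_max is the
    largest centroid-to-periosteal-contour distance in the section plane.
    """
    center, axis = _section_plane(phantom, section)
    idx_c = phantom.world_to_index(center)
    if np.any(idx_c < 0) or np.any(idx_c > np.array(phantom.image.shape) - 1):
        raise ValueError(f"section plane center {center} lies outside the image")

    # in-plane orthonormal basis
    tmp = np.array([0.0, 1.0, 0.0])
    if abs(axis @ tmp) > 0.9:
        tmp = np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, tmp)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    px = phantom.spacing / 2.0
    # half-pixel stagger keeps sample points off exact voxel boundaries
    # (avoids systematic rounding bias of the nearest-neighbour mask lookup)
    coords_1d = np.arange(-half_extent_mm, half_extent_mm, px) + px / 2.0
    uu, vv = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    pts = center + uu[..., None] * u + vv[..., None] * v
    idx = phantom.world_to_index(pts.reshape(-1, 3)).T

    # nearest-neighbour density lookup: linear interpolation would smear the
    # periosteal edge toward background and bias the density weighting
    dens = ndimage.map_coordinates(phantom.image, idx, order=0, mode="constant",
                                   cval=0.0).reshape(uu.shape)
    bone = ndimage.map_coordinates((phantom.compartment_mask > 0).astype(np.float32),
                                   idx, order=0, mode="constant",
                                   cval=0.0).reshape(uu.shape) > 0.5

    # keep only the connected patch containing the section center: a plane
    # through the neck can also clip the trochanter or shaft
    labels, n = ndimage.label(bone)
    if n == 0:
        raise ValueError(f"no bone in the {section} section plane")
    ci = np.array(bone.shape) // 2
    lab = labels[ci[0], ci[1]]
    if lab == 0:
        # center pixel not bone (e.g. hollow artifacts): take largest patch
        lab = np.argmax(np.bincount(labels[labels > 0])) if (labels > 0).any() else 0
        if lab == 0:
            raise ValueError(f"no bone in the {section} section plane")
    bone = labels == lab

    area = px * px
    w = dens / rho_ref
    sa = float(bone.sum()) * area
    csa = float(w[bone].sum()) * area
    wsum = w[bone].sum()
    cu = (w[bone] * uu[bone]).sum() / wsum
    cv = (w[bone] * vv[bone]).sum() / wsum
    r2 = (uu - cu) ** 2 + (vv - cv) ** 2
    csmi = float((w[bone] * r2[bone]).sum()) * area
    d_max = float(np.sqrt(r2[bone].max()))
    return sa, csa, csmi, csmi / d_max


# ---------------------------------------------------------------------------
# projected aBMD and T-scores


def project_abmd(phantom: FemurPhantom, roi: str = "TH", return_area: bool = False):
    """Projected areal BMD of a region of interest, g/cm^2.

    Emulates a posterior-anterior DXA measurement: the projection direction
    is the normal of the neck/shaft plane (the y axis of the canonical
    frame).  BMC is conserved: aBMD x projected area = BMC of the ROI.
    """
    region_labels = _REGION_SETS.get(roi)
    if region_labels is None:
        raise ValueError(f"unknown ROI {roi!r}")
    roi_mask = np.isin(phantom.region_mask, region_labels) & \
        (phantom.compartment_mask > 0)
    if not roi_mask.any():
        raise ValueError(f"empty ROI {roi!r}")
    bmc_g = float(phantom.image[roi_mask].sum(dtype=np.float64)) * \
        phantom.voxel_volume_cm3 / 1000.0
    silhouette = roi_mask.any(axis=1)  # project along y
    area_cm2 = float(silhouette.sum()) * (phantom.spacing / 10.0) ** 2
    abmd = bmc_g / area_cm2
    if return_area:
        return abmd, area_cm2
    return abmd


def t_score(abmd: float, reference: ReferenceCurve) -> float:
    """DXA T-score: (aBMD - young-adult mean) / young-adult SD."""
    return (abmd - reference.young_adult_mean) / reference.young_adult_sd


# ---------------------------------------------------------------------------
# full parameter set


def structural_params(phantom: FemurPhantom) -> StructuralParams:
    """Compute the full analysed parameter set for one phantom."""
    _, th_vbmd, _ = compartment_stats(phantom, "integral", "TH")
    _, fn_vbmd, _ = compartment_stats(phantom, "integral", "neck")
    _, th_tb, _ = compartment_stats(phantom, "trabecular", "TH")
    _, fn_tb, _ = compartment_stats(phantom, "trabecular", "neck")
    _, th_ct, _ = compartment_stats(phantom, "cortical", "TH")
    _, fn_ct, _ = compartment_stats(phantom, "cortical", "neck")

    cth, sbmd, _ = cortical_surface_measures(phantom)
    ok = ~np.isnan(cth)
    th_vert = ok  # all regions: canonical mesh covers the proximal femur
    fn_vert = ok & (phantom.mesh_regions == REGION_NECK)
    th_cth = float(np.nanmean(cth[th_vert]))
    fn_cth = float(np.nanmean(cth[fn_vert]))
    th_sbmd = float(np.nanmean(sbmd[th_vert]))
    fn_sbmd = float(np.nanmean(sbmd[fn_vert]))

    fn_sa, fn_csa, fn_csmi, fn_z = cross_section_props(phantom, "FN")

    th_abmd = project_abmd(phantom, "TH")
    fn_abmd = project_abmd(phantom, "FN")
    return StructuralParams(
        th_vbmd=th_vbmd, fn_vbmd=fn_vbmd,
        th_tb_vbmd=th_tb, fn_tb_vbmd=fn_tb,
        th_ct_vbmd=th_ct, fn_ct_vbmd=fn_ct,
        th_ct_sbmd=th_sbmd, fn_ct_sbmd=fn_sbmd,
        th_cth=th_cth, fn_cth=fn_cth,
        fn_sa=fn_sa, fn_csa=fn_csa, fn_csmi=fn_csmi, fn_z=fn_z,
        th_abmd=th_abmd, fn_abmd=fn_abmd,
        th_tscore=t_score(th_abmd, REFERENCE_CURVES["TH"]),
        fn_tscore=t_score(fn_abmd, REFERENCE_CURVES["FN"]),
    )
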