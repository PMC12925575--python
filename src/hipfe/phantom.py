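"""Synthetic proximal-femur phantoms.

A phantom emulates the output of a 3D densitometric reconstruction of the
proximal femur: a voxel image whose values are local volumetric BMD
(mg/cm^3), compartment masks separating the cortical shell from the
trabecular interior, anatomical region labels (femoral neck, trochanter,
proximal shaft), a canonical periosteal surface mesh with fixed vertex
correspondence across subjects, and an anatomical coordinate frame
(neck/shaft axes, head center, greater-trochanter landmark).

The geometry is an analytic union of simple solids -- a sphere for the
femoral head, a frustum for the neck, a cylinder for the shaft and an
ellipsoid for the greater trochanter.  A single scalar ``latent_quality``
(in population SD units, 0 = population mean) scales cortical density,
cortical thickness and trabecular density monotonically, so that one factor
drives coherent variation of every downstream densitometric, structural and
mechanical parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

# compartment labels
BACKGROUND = 0
TRABECULAR = 1
CORTICAL = 2

# region labels ("none" covers the femoral head, which is outside the
# standard densitometric regions of interest)
REGION_NONE = 0
REGION_NECK = 1
REGION_TROCH = 2
REGION_SHAFT = 3

REGION_CODES = {"neck": REGION_NECK, "trochanter": REGION_TROCH, "shaft": REGION_SHAFT}


@dataclass(frozen=True)
class AnatomicalFrame:
    """Internal coordinate system of a proximal femur (mm)."""

    head_center: tuple[float, float, float]
    head_radius: float
    neck_axis: tuple[float, float, float]   # unit vector, points toward the head
    shaft_axis: tuple[float, float, float]  # unit vector, points proximally
    gt_point: tuple[float, float, float]    # lateral apex of the greater trochanter
    head_gt_distance: float
    neck_base: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shaft_top_z: float = 0.0
    distal_point: tuple[float, float, float] = (0.0, 0.0, 0.0)  # distal shaft center

    def __post_init__(self):
        n = np.asarray(self.neck_axis, float)
        s = np.asarray(self.shaft_axis, float)
        if abs(abs(float(n @ s)) - 1.0) < 1e-6:
            raise ValueError("neck and shaft axes must not be parallel")
        if self.head_gt_distance <= 0:
            raise ValueError("head-GT distance must be positive")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, density and calibration defaults for phantom generation.

    Lengths are mm, densities mg/cm^3.  The defaults are calibrated so that
    the population-mean phantom (latent_quality = 0) reproduces the control
    marginals of the emulated cohort: total-hip projected aBMD ~0.85 g/cm^2,
    total-hip trabecular vBMD ~162 mg/cm^3, and a fall-configuration
    finite-element strength near 3.56 kN with the default material law.
    """

    spacing: float = 0.75         # voxel size of the vBMD image
    mesh_spacing: float = 2.0     # grid used to extract the canonical mesh
    margin: float = 4.0

    # geometry
    head_radius: float = 23.5
    neck_radius_base: float = 16.5
    neck_radius_head: float = 14.5
    neck_shaft_angle_deg: float = 125.0
    neck_base_z: float = 46.0
    neck_length: float = 52.0     # neck_base -> head center distance
    shaft_radius: float = 15.0
    shaft_top_z: float = 52.0
    troch_center: tuple[float, float, float] = (-7.0, 0.0, 60.0)
    troch_semiaxes: tuple[float, float, float] = (15.5, 14.0, 17.5)

    # cortical shell thickness per structure at latent_quality 0 (mm)
    cth_head: float = 1.6
    cth_neck: float = 1.8
    cth_troch: float = 2.2
    cth_shaft: float = 2.9
    # azimuthal asymmetry of the neck cortex: thick inferior-medial calcar,
    # thin superior cortex (cth_neck * (1 + asym * cos(phi)))
    cth_neck_asym: float = 0.7

    # densities at latent_quality 0 (mg/cm^3)
    ct_vbmd: float = 855.0
    tb_vbmd_head: float = 250.0
    tb_vbmd_neck: float = 205.0
    tb_vbmd_troch: float = 110.0
    tb_vbmd_shaft: float = 160.0

    # per-SD sensitivities of the latent quality factor (log scale)
    sens_ct_vbmd: float = 0.08
    sens_tb_vbmd: float = 0.21
    sens_cth: float = 0.08

    # smooth multiplicative density noise
    noise_frac: float = 0.04
    noise_smooth_mm: float = 4.0

    density_scale: float = 1.0    # global calibration factor (phantom-type cross-calibration)

    def min_cth(self) -> float:
        return min(self.cth_head, self.cth_neck, self.cth_troch, self.cth_shaft)


@dataclass
class FemurPhantom:
    """Voxel vBMD image plus masks, canonical mesh and anatomical frame."""

    image: np.ndarray             # (nx, ny, nz) float32, mg/cm^3
    spacing: float                # isotropic, mm
    origin: np.ndarray            # (3,) mm, position of voxel (0,0,0) center
    compartment_mask: np.ndarray  # uint8, {BACKGROUND, TRABECULAR, CORTICAL}
    region_mask: np.ndarray       # uint8, {REGION_NONE, NECK, TROCH, SHAFT}
    mesh: trimesh.Trimesh         # canonical periosteal surface
    mesh_regions: np.ndarray      # per-vertex region label
    frame: AnatomicalFrame
    latent_quality: float = 0.0
    config: PhantomConfig | None = None
    # provenance of a rigidly-moved phantom: (source, rotation, pivot).
    # Successive rigid moves are composed so the source image is only ever
    # resampled once (repeated interpolation dissipates the cortical shell).
    source: tuple | None = None

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.spacing / 10.0) ** 3

    def grid_coords(self):
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[i] + self.spacing * np.arange(self.image.shape[i])
            for i in range(3)
        )

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) / self.spacing


# ---------------------------------------------------------------------------
# analytic geometry


def _frame_from_config(cfg: PhantomConfig) -> AnatomicalFrame:
    ang = np.deg2rad(180.0 - cfg.neck_shaft_angle_deg)
    # neck axis in the x-z plane, tilted from the (vertical) shaft axis
    neck_axis = np.array([np.sin(ang), 0.0, np.cos(ang)])
    neck_axis /= np.linalg.norm(neck_axis)
    neck_base = np.array([0.0, 0.0, cfg.neck_base_z])
    head_center = neck_base + cfg.neck_length * neck_axis
    cx, cy, cz = cfg.troch_center
    gt_point = np.array([cx - cfg.troch_semiaxes[0], cy, cz])
    d = float(np.linalg.norm(head_center - gt_point))
    return AnatomicalFrame(
        head_center=tuple(head_center),
        head_radius=cfg.head_radius,
        neck_axis=tuple(neck_axis),
        shaft_axis=(0.0, 0.0, 1.0),
        gt_point=tuple(gt_point),
        head_gt_distance=d,
        neck_base=tuple(neck_base),
        shaft_top_z=cfg.shaft_top_z,
    )


def _structure_distances(pts: np.ndarray, cfg: PhantomConfig, frame: AnatomicalFrame):
    """Approximate signed distances (negative inside) to the four solids.

    Returns an array (n_structures, n_points) in the order
    head, neck, trochanter, shaft.
    """
    head_center = np.asarray(frame.head_center)
    neck_base = np.asarray(frame.neck_base)
    neck_axis = np.asarray(frame.neck_axis)

    d_head = np.linalg.norm(pts - head_center, axis=-1) - cfg.head_radius

    # neck: frustum along the neck axis between neck_base and head center
    rel = pts - neck_base
    t = rel @ neck_axis
    tc = np.clip(t, 0.0, cfg.neck_length)
    radial = np.linalg.norm(rel - tc[..., None] * neck_axis, axis=-1)
    frac = tc / cfg.neck_length
    r_t = cfg.neck_radius_base + (cfg.neck_radius_head - cfg.neck_radius_base) * frac
    d_side = radial - r_t
    d_cap = np.maximum(-t, t - cfg.neck_length)
    d_neck = np.maximum(d_side, d_cap)

    # trochanter ellipsoid (approximate signed distance)
    c = np.asarray(cfg.troch_center)
    a = np.asarray(cfg.troch_semiaxes)
    k = np.linalg.norm((pts - c) / a, axis=-1)
    d_troch = (k - 1.0) * a.min()

    # shaft cylinder with caps, axis z from 0 to shaft_top_z
    radial = np.linalg.norm(pts[..., :2], axis=-1)
    d_side = radial - cfg.shaft_radius
    d_cap = np.maximum(-pts[..., 2], pts[..., 2] - cfg.shaft_top_z)
    d_shaft = np.maximum(d_side, d_cap)

    return np.stack([d_head, d_neck, d_troch, d_shaft])


# structure index -> region label
_STRUCT_REGION = np.array([REGION_NONE, REGION_NECK, REGION_TROCH, REGION_SHAFT], np.uint8)


def _evaluate_geometry(cfg: PhantomConfig, spacing: float):
    """Sample the analytic solid on a regular grid.

    Returns (phi, structure, origin) where phi is the union signed distance
    and structure the index of the closest/most-interior solid.
    """
    frame = _frame_from_config(cfg)
    head_center = np.asarray(frame.head_center)
    m = cfg.margin
    lo = np.array([
        min(cfg.troch_center[0] - cfg.troch_semiaxes[0], -cfg.shaft_radius) - m,
        -max(cfg.head_radius + abs(head_center[1]), cfg.shaft_radius,
             cfg.troch_semiaxes[1] + abs(cfg.troch_center[1])) - m,
        -m,
    ])
    hi = np.array([
        head_center[0] + cfg.head_radius + m,
        -lo[1],
        head_center[2] + cfg.head_radius + m,
    ])
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[i] + spacing * np.arange(shape[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    d = _structure_distances(grid.reshape(-1, 3), cfg, frame)
    phi = d.min(axis=0).reshape(shape)
    structure = d.argmin(axis=0).reshape(shape).astype(np.uint8)
    return phi, structure, lo, frame


@lru_cache(maxsize=8)
def _template_mesh(cfg: PhantomConfig):
    """Canonical periosteal mesh shared by every phantom built from ``cfg``.

    Extracted once by marching cubes on the analytic union; vertex count and
    ordering are therefore identical across subjects, giving free canonical
    correspondence.
    """
    phi, structure, origin, frame = _evaluate_geometry(cfg, cfg.mesh_spacing)
    verts, faces, normals, _ = measure.marching_cubes(phi, level=0.0)
    verts = verts * cfg.mesh_spacing + origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    # orient vertex normals outward (positive side of the union surface)
    norms = np.asarray(mesh.vertex_normals, float).copy()
    probe = _structure_distances(verts + norms, cfg, frame).min(axis=0)
    if (probe < 0).mean() > 0.5:  # majority of +normal probes inside: flip
        norms = -norms
        mesh.faces = mesh.faces[:, ::-1]
    mesh.vertex_normals = norms
    d = _structure_distances(verts, cfg, frame)
    regions = _STRUCT_REGION[d.argmin(axis=0)]
    return mesh, regions


def generate_phantom(config: PhantomConfig, latent_quality: float = 0.0,
                     seed: int = 0) -> FemurPhantom:
    """Generate a femur phantom for one subject.

    Deterministic given ``(config, latent_quality, seed)``.  The latent
    quality factor (population SD units) scales trabecular density,
    cortical density and cortical thickness via ``exp(sensitivity * q)``,
    so every densitometric quantity is strictly monotone in ``q``.
    """
    if not (0.5 < config.spacing <= 3.0):
        raise ValueError("voxel spacing must lie in (0.5, 3] mm")
    if not np.isfinite(latent_quality):
        raise ValueError("latent_quality must be finite")
    q = float(latent_quality)
    cth_scale = float(np.exp(config.sens_cth * q))
    if config.spacing > config.min_cth() * cth_scale:
        raise ValueError(
            f"spacing {config.spacing} mm too coarse to resolve a cortical "
            f"shell >= 1 voxel thick (min thickness "
            f"{config.min_cth() * cth_scale:.2f} mm)")

    phi, structure, origin, frame = _evaluate_geometry(config, config.spacing)
    bone = phi < 0.0

    # distance from each bone voxel to the periosteal surface
    dist = ndimage.distance_transform_edt(bone, sampling=config.spacing)

    cth_by_struct = np.array([config.cth_head, config.cth_neck,
                              config.cth_troch, config.cth_shaft]) * cth_scale
    cth_local = cth_by_struct[structure]
    if config.cth_neck_asym:
        # calcar asymmetry: the inferior-medial neck cortex is thick, the
        # superior cortex thin (drives the stance/fall strength contrast)
        shape = bone.shape
        axes = [origin[i] + config.spacing * np.arange(shape[i]) for i in range(3)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        n_ax = np.asarray(frame.neck_axis)
        base = np.asarray(frame.neck_base)
        d_inf = np.cross([0.0, 1.0, 0.0], n_ax)
        d_inf /= np.linalg.norm(d_inf)  # in-plane, points inferior-medial
        rel = pts - base
        t = rel @ n_ax
        radial = rel - t[..., None] * n_ax
        rnorm = np.linalg.norm(radial, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_phi = np.where(rnorm > 1e-9, (radial @ d_inf) / rnorm, 0.0)
        neck_sel = structure == 1
        cth_local = np.where(
            neck_sel,
            cth_local * (1.0 + config.cth_neck_asym * cos_phi),
            cth_local)
    # a shell thinner than one voxel diagonal cannot separate the interior
    # from background on the grid; clamp so the shell is always closed
    cth_local = np.maximum(cth_local, np.sqrt(3.0) * config.spacing * 1.001)
    compartment = np.zeros(bone.shape, np.uint8)
    compartment[bone] = np.where(dist[bone] <= cth_local[bone], CORTICAL, TRABECULAR)

    region = np.zeros(bone.shape, np.uint8)
    region[bone] = _STRUCT_REGION[structure[bone]]

    tb_by_struct = np.array([config.tb_vbmd_head, config.tb_vbmd_neck,
                             config.tb_vbmd_troch, config.tb_vbmd_shaft])
    tb_local = tb_by_struct[structure] * np.exp(config.sens_tb_vbmd * q)
    ct_local = config.ct_vbmd * np.exp(config.sens_ct_vbmd * q)

    image = np.zeros(bone.shape, np.float32)
    image[compartment == TRABECULAR] = tb_local[compartment == TRABECULAR]
    image[compartment == CORTICAL] = ct_local

    if config.noise_frac > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
        white = rng.standard_normal(bone.shape)
        smooth = ndimage.gaussian_filter(white, config.noise_smooth_mm / config.spacing)
        smooth /= max(smooth.std(), 1e-12)
        image *= (1.0 + config.noise_frac * smooth).astype(np.float32)

    image *= config.density_scale
    np.clip(image, 0.0, None, out=image)
    image[~bone] = 0.0

    mesh, mesh_regions = _template_mesh(config)
    return FemurPhantom(
        image=image.astype(np.float32),
        spacing=config.spacing,
        origin=np.asarray(origin, float),
        compartment_mask=compartment,
        region_mask=region,
        mesh=mesh,
        mesh_regions=mesh_regions,
        frame=frame,
        latent_quality=q,
        config=config,
    )


def total_bmc_mg(phantom: FemurPhantom) -> float:
    """Direct voxel sum of bone mineral content over the whole phantom (mg)."""
    return float(phantom.image.sum() * phantom.voxel_volume_cm3)
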