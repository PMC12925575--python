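"""Voxel finite-element femoral strength.

Builds a hexahedral finite-element model from a femur phantom (voxels
downsampled to 3 mm become trilinear 8-node bricks), assigns an
elastic-perfectly-plastic material from the local volumetric BMD through a
bone-volume-fraction power law, and runs a displacement-controlled
quasi-static solve for two load cases:

* ``fall``: impact on the greater trochanter.  The bone is reposed so the
  shaft axis is inclined 10 degrees to the horizontal with the neck/shaft
  plane vertical; the GT rests on a padded rigid support, the distal shaft
  end is fully constrained, and a vertical displacement is driven through a
  padding cap on the femoral head.
* ``stance``: one-legged stance.  Upright pose, distal end fixed, vertical
  displacement driven through the head cap.

Strength is the reaction force at a head displacement of 4 % of the
head-center-to-greater-trochanter distance.

The solver uses small-strain J2 (von Mises) perfect plasticity with a
radial-return stress update and consistent algorithmic tangent, full Newton
iterations per displacement increment and a sparse direct factorisation.
An optional isotropic damage variable (exponential stiffness reduction with
accumulated plastic strain) is available and off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import splu

from .phantom import FemurPhantom, AnatomicalFrame

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# material law


@dataclass(frozen=True)
class MaterialLaw:
    """Density-elasticity-yield law for voxel elements.

    vBMD (mg/cm^3 hydroxyapatite-equivalent) is converted to a bone volume
    fraction BV/TV = min(1, vBMD / rho_tissue); the elastic modulus follows
    a power law E = e0 * (BV/TV)**k and the yield stress a fixed yield
    strain, sigma_y = eps_y * E.  Defaults are representative of published
    density-modulus laws for human proximal femur at the millimetre scale.
    """

    rho_tissue: float = 1200.0   # mg/cm^3 at full mineralisation
    e0: float = 7840.0           # MPa; calibrated so the population-mean
    #                              phantom reproduces the control-group mean
    #                              fall strength under the 4 % criterion
    k: float = 1.6
    eps_y: float = 0.007
    nu: float = 0.3
    e_floor: float = 0.1         # MPa; weaker elements are removed
    pad_e: float = 40.0          # polyurethane padding modulus, MPa
    damage: bool = False
    damage_scale: float = 0.05   # plastic strain for 1/e stiffness loss


def material_from_vbmd(vbmd, law: MaterialLaw):
    """Map vBMD (mg/cm^3) to (E [MPa], sigma_y [MPa]); monotone in vBMD."""
    vbmd = np.asarray(vbmd, float)
    if np.any(vbmd < 0):
        raise ValueError("vBMD must be non-negative")
    bvtv = np.clip(vbmd / law.rho_tissue, 0.0, 1.0)
    e = law.e0 * bvtv ** law.k
    return e, law.eps_y * e


# ---------------------------------------------------------------------------
# trilinear hexahedron (cube of edge h)

_NODE_OFFSETS = np.array([
    (0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
    (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1),
])


def _hex_b_matrices(h: float):
    """B matrices (8 Gauss points x 6 x 24) and Gauss weight volume."""
    xi_nodes = 2.0 * _NODE_OFFSETS - 1.0
    g = 1.0 / np.sqrt(3.0)
    gauss = np.array([(gx, gy, gz) for gz in (-g, g) for gy in (-g, g) for gx in (-g, g)])
    B = np.zeros((8, 6, 24))
    for gi, (x, y, z) in enumerate(gauss):
        for a, (ax, ay, az) in enumerate(xi_nodes):
            dndx = ax * (1 + ay * y) * (1 + az * z) / 8.0 * (2.0 / h)
            dndy = ay * (1 + ax * x) * (1 + az * z) / 8.0 * (2.0 / h)
            dndz = az * (1 + ax * x) * (1 + ay * y) / 8.0 * (2.0 / h)
            c = 3 * a
            B[gi, 0, c + 0] = dndx
            B[gi, 1, c + 1] = dndy
            B[gi, 2, c + 2] = dndz
            B[gi, 3, c + 0] = dndy  # gamma_xy
            B[gi, 3, c + 1] = dndx
            B[gi, 4, c + 1] = dndz  # gamma_yz
            B[gi, 4, c + 2] = dndy
            B[gi, 5, c + 0] = dndz  # gamma_zx
            B[gi, 5, c + 2] = dndx
    detj_w = (h / 2.0) ** 3  # unit Gauss weights
    return B, detj_w


def _elastic_d(nu: float):
    """Unit-modulus isotropic stiffness in Voigt [xx,yy,zz,xy,yz,zx]."""
    lam = nu / ((1 + nu) * (1 - 2 * nu))
    mu = 1.0 / (2 * (1 + nu))
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.arange(3), np.arange(3)] = lam + 2 * mu
    d[np.arange(3, 6), np.arange(3, 6)] = mu
    return d


# ---------------------------------------------------------------------------
# model container


@dataclass
class FEModel:
    nodes: np.ndarray          # (n_nodes, 3) mm
    elements: np.ndarray       # (n_el, 8) node indices
    e_modulus: np.ndarray      # (n_el,) MPa
    yield_stress: np.ndarray   # (n_el,) MPa (np.inf = elastic)
    is_padding: np.ndarray     # (n_el,) bool
    h: float                   # element edge, mm
    fixed_nodes: np.ndarray    # node indices, all DOF constrained
    driven_nodes: np.ndarray   # node indices, z prescribed (reference coupling)
    load_case: str
    target_displacement: float
    nu: float = 0.3
    fixed_z_nodes: np.ndarray | None = None   # z-only supports (e.g. oracles)
    pinned: tuple = ()          # extra (node, axis) zero constraints

    def __post_init__(self):
        if self.fixed_z_nodes is None:
            self.fixed_z_nodes = np.empty(0, np.int64)
        if (len(self.fixed_nodes) == 0 and len(self.fixed_z_nodes) == 0) \
                or len(self.driven_nodes) == 0:
            raise ValueError("constrained and driven node sets must be non-empty")
        if np.intersect1d(self.fixed_nodes, self.driven_nodes).size:
            raise ValueError("constrained and driven node sets must be disjoint")
        if np.any(self.e_modulus <= 0):
            raise ValueError("all elements must have positive modulus")

    @property
    def n_dof(self) -> int:
        return 3 * len(self.nodes)


@dataclass
class StrengthResult:
    load_case: str
    displacement_steps: np.ndarray  # mm, starts at 0
    reaction_force: np.ndarray      # N per step, starts at 0
    strength: float                 # N at the target displacement
    target_displacement: float      # mm


# ---------------------------------------------------------------------------
# J2 perfect plasticity, vectorised radial return

_SHEAR = slice(3, 6)


def _return_map(strain, eps_p, e, nu, sig_y):
    """Radial-return stress update for an array of Gauss points.

    ``strain`` and ``eps_p`` are (m, 6) Voigt with engineering shear; ``e``
    and ``sig_y`` are (m,).  Returns stress, updated plastic strain,
    increment of equivalent plastic strain, plastic mask and the trial
    deviatoric direction (for the consistent tangent).
    """
    g = e / (2 * (1 + nu))
    kb = e / (3 * (1 - 2 * nu))
    ee = strain - eps_p
    tr = ee[:, 0] + ee[:, 1] + ee[:, 2]
    # trial stress
    sig = np.empty_like(ee)
    sig[:, :3] = 2 * g[:, None] * (ee[:, :3] - tr[:, None] / 3.0) + kb[:, None] * tr[:, None]
    sig[:, _SHEAR] = g[:, None] * ee[:, _SHEAR]
    p = (sig[:, 0] + sig[:, 1] + sig[:, 2]) / 3.0
    s = sig.copy()
    s[:, :3] -= p[:, None]
    q = np.sqrt(1.5 * (np.einsum("ij,ij->i", s[:, :3], s[:, :3])
                       + 2.0 * np.einsum("ij,ij->i", s[:, _SHEAR], s[:, _SHEAR])))
    plastic = q > sig_y
    dgam = np.zeros(len(ee))
    n_dir = np.zeros_like(s)
    if plastic.any():
        qp = q[plastic]
        sy = sig_y[plastic]
        gp = g[plastic]
        dgam[plastic] = (qp - sy) / (3 * gp)
        beta = sy / qp
        sp = s[plastic]
        # plastic strain increment (engineering shear doubles)
        dep = np.empty_like(sp)
        dep[:, :3] = dgam[plastic, None] * 1.5 * sp[:, :3] / qp[:, None]
        dep[:, _SHEAR] = dgam[plastic, None] * 3.0 * sp[:, _SHEAR] / qp[:, None]
        eps_p = eps_p.copy()
        eps_p[plastic] += dep
        s[plastic] = beta[:, None] * sp
        sig[plastic] = s[plastic]
        sig[plastic, :3] += p[plastic, None]
        norm = np.sqrt(np.einsum("ij,ij->i", sp[:, :3], sp[:, :3])
                       + 2.0 * np.einsum("ij,ij->i", sp[:, _SHEAR], sp[:, _SHEAR]))
        n_dir[plastic] = sp / norm[:, None]
    return sig, eps_p, dgam, plastic, n_dir, q


def _consistent_tangent(e, nu, sig_y, q_trial, n_dir):
    """Algorithmic tangent for plastic Gauss points, (m, 6, 6) Voigt."""
    g = e / (2 * (1 + nu))
    kb = e / (3 * (1 - 2 * nu))
    beta = sig_y / q_trial
    m = len(e)
    d = np.zeros((m, 6, 6))
    # bulk part
    d[:, :3, :3] = kb[:, None, None]
    # deviatoric identity (engineering-strain form) scaled by 2*G*beta
    i_dev = np.zeros((6, 6))
    i_dev[:3, :3] = -1.0 / 3.0
    i_dev[np.arange(3), np.arange(3)] += 1.0
    i_dev[np.arange(3, 6), np.arange(3, 6)] = 0.5
    d += (2 * g * beta)[:, None, None] * i_dev[None]
    # rank-one reduction along the trial deviatoric direction
    d -= (2 * g * beta)[:, None, None] * np.einsum("mi,mj->mij", n_dir, n_dir)
    return d


# ---------------------------------------------------------------------------
# solver


def solve_strength(model: FEModel, n_increments: int = 20, tol: float = 1e-6,
                   max_iter: int = 40, law: MaterialLaw | None = None,
                   elastic_only: bool = False) -> StrengthResult:
    """Displacement-controlled quasi-static solve; strength at the 4 % target.

    The driven nodes move together along -z (kinematic coupling to the head
    reference point); ``strength`` is the total reaction at the driven set
    when the target displacement is reached (equal increments end exactly on
    the target; intermediate crossings are linearly interpolated).
    """
    if n_increments < 5:
        raise ValueError("need at least 5 increments")
    damage = bool(law.damage) if law is not None else False
    damage_scale = law.damage_scale if law is not None else 0.05

    nel = len(model.elements)
    B, detj_w = _hex_b_matrices(model.h)
    d_unit = _elastic_d(model.nu)
    k_unit = np.einsum("gai,ab,gbj->ij", B, d_unit, B) * detj_w

    dof = (3 * model.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(nel, 24)
    rows = np.repeat(dof, 24, axis=1).ravel()
    cols = np.tile(dof, (1, 24)).ravel()

    ndof = model.n_dof
    prescribed = np.zeros(ndof, bool)
    if len(model.fixed_nodes):
        prescribed[(3 * model.fixed_nodes[:, None] + np.arange(3)).ravel()] = True
    if len(model.fixed_z_nodes):
        prescribed[3 * model.fixed_z_nodes + 2] = True
    for node, axis in model.pinned:
        prescribed[3 * node + axis] = True
    driven_z = 3 * model.driven_nodes + 2
    prescribed[driven_z] = True
    free = ~prescribed
    free_index = -np.ones(ndof, np.int64)
    free_index[free] = np.arange(free.sum())

    rmap = free_index[rows]
    cmap = free_index[cols]
    keep = (rmap >= 0) & (cmap >= 0)
    rkeep, ckeep = rmap[keep], cmap[keep]
    nfree = int(free.sum())

    e_el = model.e_modulus
    sy_el = np.where(np.isfinite(model.yield_stress), model.yield_stress, 1e30)
    if elastic_only:
        sy_el = np.full(nel, 1e30)
    # Gauss-point arrays (flattened element x gauss)
    e_gp = np.repeat(e_el, 8)
    sy_gp = np.repeat(sy_el, 8)
    eps_p = np.zeros((nel * 8, 6))
    alpha = np.zeros(nel * 8)

    u = np.zeros(ndof)
    steps = np.linspace(0.0, model.target_displacement, n_increments + 1)
    reactions = [0.0]

    def internal_forces(u_vec, eps_p_committed, alpha_committed):
        ue = u_vec[dof]                                   # (nel, 24)
        strain = np.einsum("gci,ei->egc", B, ue).reshape(nel * 8, 6)
        e_eff = e_gp
        if damage:
            d_fac = np.exp(-alpha_committed / damage_scale)
            e_eff = e_gp * np.maximum(d_fac, 0.05)
        sig, eps_p_new, dgam, plastic, n_dir, q = _return_map(
            strain, eps_p_committed, e_eff, model.nu, sy_gp)
        fe = np.einsum("gci,egc->ei", B, sig.reshape(nel, 8, 6)) * detj_w
        f = np.zeros(ndof)
        np.add.at(f, dof.ravel(), fe.ravel())
        return f, sig, eps_p_new, dgam, plastic, n_dir, q, e_eff

    def factorize(plastic, n_dir, q, e_eff):
        """Assemble the tangent (elastic baseline + plastic correction)."""
        vals = e_eff.reshape(nel, 8).mean(axis=1)[:, None, None] * k_unit[None]
        if plastic.any():
            pl = np.where(plastic)[0]
            d_ep = _consistent_tangent(e_eff[pl], model.nu, sy_gp[pl],
                                       q[pl], n_dir[pl])
            el_idx = pl // 8
            g_idx = pl % 8
            d_el = e_eff[pl][:, None, None] * d_unit[None]
            delta = d_ep - d_el
            for gi in range(8):
                m = g_idx == gi
                if not m.any():
                    continue
                bg = B[gi]
                corr = np.einsum("ci,mcd,dj->mij", bg, delta[m], bg) * detj_w
                np.add.at(vals, el_idx[m], corr)
        kmat = sparse.coo_matrix(
            (vals.ravel()[keep], (rkeep, ckeep)), shape=(nfree, nfree)).tocsc()
        return splu(kmat)

    lu = None  # factorization reused across iterations/increments while
    #            Newton keeps contracting; refreshed on slow progress
    for inc in range(1, n_increments + 1):
        u[driven_z] = -steps[inc]
        converged = False
        state = internal_forces(u, eps_p, alpha)
        f_int, sig, eps_p_new, dgam, plastic, n_dir, q, e_eff = state
        rnorm = np.linalg.norm(f_int[free])
        res0 = max(rnorm, 1e-12)
        need_factor = lu is None
        for it in range(max_iter):
            scale = max(np.linalg.norm(f_int[prescribed]), 1.0)
            if rnorm <= tol * max(res0, scale):
                converged = True
                break
            if need_factor:
                lu = factorize(plastic, n_dir, q, e_eff)
                need_factor = False
            du = lu.solve(-f_int[free])
            # backtracking line search on the residual norm: perfect
            # plasticity can chatter under full Newton steps
            best = None
            for a in (1.0, 0.5, 0.25, 0.125, 1 / 16, 1 / 32):
                u_try = u.copy()
                u_try[free] += a * du
                s_try = internal_forces(u_try, eps_p, alpha)
                rn = np.linalg.norm(s_try[0][free])
                if best is None or rn < best[0]:
                    best = (rn, a, u_try, s_try)
                if rn <= (1.0 - 1e-4 * a) * rnorm:
                    break
            rn, a_used, u, state = best
            f_int, sig, eps_p_new, dgam, plastic, n_dir, q, e_eff = state
            # refresh the tangent only on slow contraction: stale-Jacobian
            # iterations are much cheaper than a new factorization
            need_factor = rn > 0.7 * rnorm
            rnorm = rn
        if not converged:
            raise RuntimeError(
                f"increment {inc} did not converge (residual {rnorm:.3e} "
                f"after {max_iter} iterations)")
        eps_p = eps_p_new
        alpha = alpha + dgam
        reactions.append(abs(float(f_int[driven_z].sum())))

    reactions = np.asarray(reactions)
    # equal increments end exactly on the target; interpolate for safety
    strength = float(np.interp(model.target_displacement, steps, reactions))
    return StrengthResult(
        load_case=model.load_case,
        displacement_steps=steps,
        reaction_force=reactions,
        strength=strength,
        target_displacement=model.target_displacement,
    )


# ---------------------------------------------------------------------------
# repositioning


def _fall_rotation(frame: AnatomicalFrame, shaft_tilt_deg: float = 10.0) -> np.ndarray:
    """Rotation taking the frame to the sideways-fall pose.

    After the rotation the shaft axis makes ``shaft_tilt_deg`` with the
    horizontal plane, the neck/shaft plane is vertical (its normal
    horizontal), and the head lies above the greater trochanter so that a
    vertical load mimics an impact on the GT.
    """
    s = np.asarray(frame.shaft_axis, float)
    n = np.asarray(frame.neck_axis, float)
    m = np.cross(s, n)
    nm = np.linalg.norm(m)
    if nm < 1e-8:
        raise ValueError("degenerate frame: neck and shaft axes are parallel")
    m /= nm
    p = n - (n @ s) * s
    p /= np.linalg.norm(p)          # in-plane, perpendicular to shaft
    src = np.stack([s, p, m])       # orthonormal source basis (rows)
    t = np.deg2rad(shaft_tilt_deg)
    # target: shaft in the x-z plane tilted t above horizontal, pointing so
    # that the neck component p maps upward (+z) -> head above GT
    s_t = np.array([np.cos(t), 0.0, np.sin(t)])
    p_t = np.array([-np.sin(t), 0.0, np.cos(t)])
    m_t = np.cross(s_t, p_t)  # horizontal (-y): right-handed target basis
    dst = np.stack([s_t, p_t, m_t])
    return dst.T @ src


def rotate_phantom(phantom: FemurPhantom, rot: np.ndarray,
                   pivot: np.ndarray | None = None) -> FemurPhantom:
    """Rigidly rotate a phantom: image resampled with trilinear
    interpolation, masks nearest-neighbour, frame and mesh exactly.

    Successive rotations are composed onto the original image (a phantom
    that was itself produced by a rigid move carries its source), so a
    chain of poses costs exactly one resampling pass.
    """
    if phantom.source is not None:
        src, prev_rot, prev_pivot = phantom.source
        return rotate_phantom(src, np.asarray(rot) @ prev_rot, prev_pivot)
    if pivot is None:
        pivot = np.asarray(phantom.frame.gt_point, float)

    # bounding box of the rotated volume
    shape = np.array(phantom.image.shape)
    corners = np.array([[i, j, k] for i in (0, shape[0] - 1)
                        for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)])
    world = phantom.origin + phantom.spacing * corners
    rot_w = (world - pivot) @ rot.T + pivot
    lo = rot_w.min(axis=0)
    hi = rot_w.max(axis=0)
    # snap the output origin to the FE downsampling pitch so 3 mm element
    # boundaries land at the same world positions regardless of how many
    # rigid transforms preceded (keeps strength frame-indifferent)
    snap = 3.0
    new_origin = np.floor(lo / snap) * snap
    new_shape = np.ceil((hi - new_origin) / phantom.spacing).astype(int) + 1

    # output index -> input index affine map (pull-back uses the inverse)
    # world_out = new_origin + s*i_out ; world_in = R^-1 (world_out - pivot) + pivot
    rinv = rot.T
    a = rinv
    offset_world = pivot - rinv @ pivot
    # input_index = (a @ world_out + offset_world - origin_in) / s
    matrix = a
    offset = (matrix @ new_origin + offset_world - phantom.origin) / phantom.spacing
    scaled = matrix  # spacing cancels (isotropic, same in and out)

    image = ndimage.affine_transform(
        phantom.image, scaled, offset=offset, output_shape=tuple(new_shape),
        order=1, mode="constant", cval=0.0)
    comp = ndimage.affine_transform(
        phantom.compartment_mask, scaled, offset=offset,
        output_shape=tuple(new_shape), order=0, mode="constant", cval=0)
    regm = ndimage.affine_transform(
        phantom.region_mask, scaled, offset=offset,
        output_shape=tuple(new_shape), order=0, mode="constant", cval=0)

    def rot_pt(p):
        return tuple((rot @ (np.asarray(p, float) - pivot)) + pivot)

    def rot_vec(v):
        return tuple(rot @ np.asarray(v, float))

    frame = AnatomicalFrame(
        head_center=rot_pt(phantom.frame.head_center),
        head_radius=phantom.frame.head_radius,
        neck_axis=rot_vec(phantom.frame.neck_axis),
        shaft_axis=rot_vec(phantom.frame.shaft_axis),
        gt_point=rot_pt(phantom.frame.gt_point),
        head_gt_distance=phantom.frame.head_gt_distance,
        neck_base=rot_pt(phantom.frame.neck_base),
        shaft_top_z=phantom.frame.shaft_top_z,
        distal_point=rot_pt(phantom.frame.distal_point),
    )
    mesh = phantom.mesh.copy()
    mesh.vertices = (mesh.vertices - pivot) @ rot.T + pivot
    return FemurPhantom(
        image=image.astype(np.float32), spacing=phantom.spacing,
        origin=np.asarray(new_origin, float), compartment_mask=comp,
        region_mask=regm, mesh=mesh, mesh_regions=phantom.mesh_regions,
        frame=frame, latent_quality=phantom.latent_quality,
        config=phantom.config,
        source=(phantom, np.asarray(rot, float).copy(), np.asarray(pivot, float)))


def reposition_stance(phantom: FemurPhantom):
    """Pose for the one-legged stance load case.

    The joint load of single-leg stance acts along the mechanical axis of
    the femur (femoral head center toward the distal end), so the bone is
    rotated in the neck/shaft plane until the head center sits vertically
    above the distal shaft center; the vertical driven displacement then
    mimics the physiologic gait load direction.  Returns ``(phantom, rot)``.
    """
    frame = phantom.frame
    head = np.asarray(frame.head_center, float)
    distal = np.asarray(frame.distal_point, float)
    v = head - distal
    v /= np.linalg.norm(v)
    s = np.asarray(frame.shaft_axis, float)
    n = np.asarray(frame.neck_axis, float)
    m = np.cross(s, n)
    m /= np.linalg.norm(m)          # neck/shaft plane normal; v lies in-plane
    u = np.cross(m, v)
    src = np.stack([v, u, m])
    dst = np.stack([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    rot = dst.T @ src
    if np.allclose(rot, np.eye(3), atol=1e-9):
        return phantom, np.eye(3)
    return rotate_phantom(phantom, rot), rot


def reposition_fall(phantom: FemurPhantom, shaft_tilt_deg: float = 10.0):
    """Resample a phantom into the sideways-fall pose.

    Returns ``(posed_phantom, rotation)``.  Applying the repositioning to an
    already-posed phantom yields (numerically) the identity rotation, so the
    operation is idempotent on the pose.
    """
    rot = _fall_rotation(phantom.frame, shaft_tilt_deg)
    if np.allclose(rot, np.eye(3), atol=1e-9):
        return phantom, rot
    return rotate_phantom(phantom, rot), rot


# ---------------------------------------------------------------------------
# model construction


def _downsample(image: np.ndarray, spacing: float, origin: np.ndarray,
                voxel_mm: float):
    factor = int(round(voxel_mm / spacing))
    if abs(factor * spacing - voxel_mm) > 1e-9 or factor < 1:
        raise ValueError("FE voxel size must be an integer multiple of the image spacing")
    if factor == 1:
        return image.astype(float), origin.copy()
    shape = np.array(image.shape)
    pad = (-shape) % factor
    padded = np.pad(image, [(0, p) for p in pad])
    s = padded.shape
    coarse = padded.reshape(s[0] // factor, factor, s[1] // factor, factor,
                            s[2] // factor, factor).mean(axis=(1, 3, 5))
    return coarse, origin.copy()


def build_fe_model(phantom: FemurPhantom, load_case: str,
                   law: MaterialLaw | None = None, voxel_mm: float = 3.0,
                   pad_layers: int = 1, cap_depth_mm: float = 9.0,
                   min_elements: int = 50) -> FEModel:
    """Build the voxel FE model for a (posed, for the fall case) phantom.

    The vBMD image is block-averaged to ``voxel_mm`` isotropic voxels, each
    bone voxel becomes a linear hexahedral element with properties from the
    material law, void elements (E below the removal floor) are dropped and
    only the largest connected component is kept.  Polyurethane padding caps
    are added above the femoral head (both cases) and below the greater
    trochanter (fall case, resting on a rigid support).
    """
    law = law or MaterialLaw()
    if load_case not in ("fall", "stance"):
        raise ValueError(f"unknown load case {load_case!r}")

    coarse, origin = _downsample(phantom.image, phantom.spacing,
                                 phantom.origin, voxel_mm)
    e_vox, sy_vox = material_from_vbmd(coarse, law)
    solid = e_vox >= law.e_floor
    labels, n = ndimage.label(solid, structure=np.ones((3, 3, 3), int))
    if n == 0:
        raise ValueError("no load-bearing elements after downsampling")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    solid = labels == counts.argmax()
    if solid.sum() < min_elements:
        raise ValueError(
            f"only {int(solid.sum())} elements after downsampling "
            f"(minimum {min_elements})")

    frame = phantom.frame
    head = np.asarray(frame.head_center)
    gt = np.asarray(frame.gt_point)
    nx, ny, nz = solid.shape
    # voxel center world coordinate helper
    def centers(axis, n):
        return origin[axis] + voxel_mm * np.arange(n)

    cx, cy, cz = (centers(0, nx), centers(1, ny), centers(2, nz))
    gx, gy, gz = np.meshgrid(cx, cy, cz, indexing="ij")
    head_vox = solid & (((gx - head[0]) ** 2 + (gy - head[1]) ** 2 +
                         (gz - head[2]) ** 2) <= frame.head_radius ** 2)
    if not head_vox.any():
        raise ValueError("no femoral-head elements found")

    npad = pad_layers
    ext_shape = (nx, ny, nz + 2 * npad)
    solid_e = np.zeros(ext_shape, bool)
    solid_e[:, :, npad:npad + nz] = solid
    e_e = np.zeros(ext_shape)
    e_e[:, :, npad:npad + nz] = np.where(solid, e_vox, 0.0)
    sy_e = np.zeros(ext_shape)
    sy_e[:, :, npad:npad + nz] = np.where(solid, sy_vox, 0.0)
    pad_head = np.zeros(ext_shape, bool)
    pad_gt = np.zeros(ext_shape, bool)

    # head cap: padding columns above the upper head surface
    head_e = np.zeros(ext_shape, bool)
    head_e[:, :, npad:npad + nz] = head_vox
    zidx = np.arange(ext_shape[2])[None, None, :]
    head_top = np.where(head_e.any(axis=2),
                        np.max(np.where(head_e, zidx, -1), axis=2), -1)
    top_z = head_top.max()
    cap_depth = max(1, int(round(cap_depth_mm / voxel_mm)))
    cap_cols = head_top >= top_z - cap_depth
    for (i, j) in zip(*np.nonzero(cap_cols)):
        z0 = head_top[i, j] + 1
        pad_head[i, j, z0:z0 + npad] = True

    if load_case == "fall":
        gt_r = 16.0
        gt_vox = solid & (((gx - gt[0]) ** 2 + (gy - gt[1]) ** 2 +
                           (gz - gt[2]) ** 2) <= gt_r ** 2)
        if not gt_vox.any():
            raise ValueError("no greater-trochanter elements found for the fall case")
        gt_e = np.zeros(ext_shape, bool)
        gt_e[:, :, npad:npad + nz] = gt_vox
        gt_bot = np.where(gt_e.any(axis=2),
                          np.min(np.where(gt_e, zidx, ext_shape[2]), axis=2),
                          ext_shape[2])
        bot_z = gt_bot.min()
        sup_cols = gt_bot <= bot_z + cap_depth
        for (i, j) in zip(*np.nonzero(sup_cols)):
            z0 = gt_bot[i, j]
            pad_gt[i, j, z0 - npad:z0] = True

    pad_head &= ~solid_e
    pad_gt &= ~(solid_e | pad_head)
    pad_mask = pad_head | pad_gt
    e_e[pad_mask] = law.pad_e
    sy_e[pad_mask] = np.inf
    all_el = solid_e | pad_mask

    # nodes and elements
    el_idx = np.array(np.nonzero(all_el)).T
    node_grid_shape = np.array(all_el.shape) + 1
    def node_id(ijk):
        return (ijk[:, 0] * node_grid_shape[1] + ijk[:, 1]) * node_grid_shape[2] + ijk[:, 2]

    conn = np.empty((len(el_idx), 8), np.int64)
    for a, off in enumerate(_NODE_OFFSETS):
        conn[:, a] = node_id(el_idx + off)
    used, inv = np.unique(conn, return_inverse=True)
    conn = inv.reshape(conn.shape)
    ug = np.empty((len(used), 3), np.int64)
    ug[:, 2] = used % node_grid_shape[2]
    rem = used // node_grid_shape[2]
    ug[:, 1] = rem % node_grid_shape[1]
    ug[:, 0] = rem // node_grid_shape[1]
    nodes = origin[None, :] + voxel_mm * ug.astype(float)
    nodes[:, 2] -= voxel_mm * npad  # account for the padded z origin

    ei = e_e[all_el]
    syi = sy_e[all_el]
    is_pad = pad_mask[all_el]
    el_is_pad_head = pad_head[all_el]
    el_is_pad_gt = pad_gt[all_el]

    # driven node set: the top face of every head-padding column (rigid-cup
    # kinematic coupling to the head reference point)
    driven = set()
    pad_cells = el_idx[el_is_pad_head]
    if len(pad_cells):
        col_top = {}
        for (i, j, k) in pad_cells:
            col_top[(i, j)] = max(col_top.get((i, j), -1), k)
        for row, cell in zip(conn[el_is_pad_head], pad_cells):
            if cell[2] == col_top[(cell[0], cell[1])]:
                driven.update(row[4:])  # the four upper-face nodes
    driven = np.array(sorted(driven), np.int64)

    fixed = set()
    # distal end: extreme elements along the distal direction of the shaft
    shaft_dir = -np.asarray(frame.shaft_axis, float)
    el_centers = origin[None, :] + voxel_mm * (el_idx.astype(float) + 0.5)
    el_centers[:, 2] -= voxel_mm * npad
    proj = el_centers @ shaft_dir
    bone_sel = ~is_pad
    distal_cut = proj[bone_sel].max() - 1.2 * voxel_mm
    distal_el = bone_sel & (proj >= distal_cut)
    for row in conn[distal_el]:
        fixed.update(row)
    if load_case == "fall":
        # the bottom face of every GT-padding column: rigid support cup
        cells = el_idx[el_is_pad_gt]
        if len(cells):
            col_bot = {}
            for (i, j, k) in cells:
                col_bot[(i, j)] = min(col_bot.get((i, j), 10 ** 9), k)
            for row, cell in zip(conn[el_is_pad_gt], cells):
                if cell[2] == col_bot[(cell[0], cell[1])]:
                    fixed.update(row[:4])  # four lower-face nodes

    fixed = np.array(sorted(fixed - set(driven.tolist())), np.int64)

    return FEModel(
        nodes=nodes, elements=conn, e_modulus=ei, yield_stress=syi,
        is_padding=is_pad, h=voxel_mm, fixed_nodes=fixed, driven_nodes=driven,
        load_case=load_case,
        target_displacement=0.04 * frame.head_gt_distance, nu=law.nu)


def strength_pair(phantom: FemurPhantom, law: MaterialLaw | None = None,
                  n_increments: int = 20, voxel_mm: float = 3.0):
    """Femoral strength in the fall and stance configurations (N)."""
    posed_fall, _ = reposition_fall(phantom)
    fall = solve_strength(build_fe_model(posed_fall, "fall", law, voxel_mm),
                          n_increments, law=law)
    posed_stance, _ = reposition_stance(phantom)
    stance = solve_strength(build_fe_model(posed_stance, "stance", law, voxel_mm),
                            n_increments, law=law)
    return fall.strength, stance.strength


# ---------------------------------------------------------------------------
# debugging dump


def dump_model(model: FEModel, path):
    """Write a plain-text nodes/elements/materials dump for inspection."""
    with open(path, "w") as fh:
        fh.write(f"# hipfe FE model, load_case={model.load_case}, "
                 f"h={model.h} mm, target={model.target_displacement:.4f} mm\n")
        fh.write("NODES\n")
        for i, p in enumerate(model.nodes):
            fh.write(f"{i} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")
        fh.write("ELEMENTS\n")
        for i, (row, e, sy, pad) in enumerate(
                zip(model.elements, model.e_modulus, model.yield_stress,
                    model.is_padding)):
            fh.write(f"{i} " + " ".join(map(str, row)) +
                     f" E={e:.3f} SY={sy:.4f} PAD={int(pad)}\n")
        fh.write("FIXED " + " ".join(map(str, model.fixed_nodes)) + "\n")
        fh.write("DRIVEN " + " ".join(map(str, model.driven_nodes)) + "\n")
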