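"""Peri-cyst trabecular microarchitecture (the 8-parameter micro-CT panel).

The region of interest is the Cys-Tb shell: trabecular bone extending
0.5 mm outward from the cyst surface.  On bone within an ROI the panel is

* BV/TV (%)        bone volume fraction (voxel counting)
* BS/BV (1/mm)     triangulated isosurface area over bone volume
* Tb.Th (μm)       volume-weighted mean largest-inscribed-sphere diameter
                   of the bone phase (distance-ridge local thickness)
* Tb.Sp (μm)       the same for the void phase
* Tb.N (1/mm)      1 / (Tb.Th + Tb.Sp)
* SMI              6·V·S′/S², S′ estimated by dilating the surface
* DA               longest / shortest principal mean-intercept-length axis
* Conn.D (1/mm³)   (1 − χ)/TV with χ the Euler characteristic
                   (foreground 26 / background 6 connectivity)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .cystdetect import ball_structuring_element
from .volio import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "RoiMask",
    "MicroarchParams",
    "MilResult",
    "cys_tb_shell",
    "bv_tv",
    "bone_surface",
    "local_thickness",
    "local_thickness_nd",
    "thickness_map",
    "tb_n",
    "smi",
    "mil_anisotropy",
    "conn_density",
    "euler_characteristic",
    "compute_panel",
]


@dataclass
class RoiMask:
    """A measurement region: the mask plus its provenance."""

    mask: Volume
    kind: str = "custom"  # "cys_tb" or "custom"
    shell_width: float | None = None  # mm, for cys_tb


@dataclass
class MicroarchParams:
    """The eight-parameter trabecular panel (units in the field names)."""

    bv_tv: float  # %
    bs_bv: float | None  # 1/mm
    tb_th: float | None  # μm
    tb_sp: float | None  # μm
    tb_n: float | None  # 1/mm
    smi: float | None
    da: float | None
    conn_d: float  # 1/mm^3

    def as_dict(self) -> dict:
        return {
            "bv_tv": self.bv_tv, "bs_bv": self.bs_bv, "tb_th": self.tb_th,
            "tb_sp": self.tb_sp, "tb_n": self.tb_n, "smi": self.smi,
            "da": self.da, "conn_d": self.conn_d,
        }


def _roi_mask(roi: RoiMask | Volume) -> Volume:
    return roi.mask if isinstance(roi, RoiMask) else roi


def cys_tb_shell(
    cyst: Volume, width: float = 0.5, total: Volume | None = None
) -> RoiMask:
    """The Cys-Tb ROI: a shell extending ``width`` mm out from the cyst surface.

    Computed as dilate(cyst, ball(width)) \\ cyst, clipped to the total head
    region when given.  The shell is disjoint from the cyst by construction.
    """
    mask = np.asarray(cyst.values, dtype=bool)
    if not mask.any():
        raise ValueError("empty cyst mask")
    if width <= 0:
        raise ValueError("shell width must be positive")
    if width < min(cyst.spacing):
        raise ValueError(
            f"shell width {width} mm is below one voxel ({min(cyst.spacing)} mm); "
            "use a finer voxel size"
        )
    se = ball_structuring_element(width, cyst.spacing)
    shell = ndimage.binary_dilation(mask, structure=se) & ~mask
    if total is not None:
        cyst.check_same_grid(total, "cys_tb_shell")
        shell &= np.asarray(total.values, dtype=bool)
    return RoiMask(cyst.like(shell), kind="cys_tb", shell_width=width)


def bv_tv(bone: Volume, roi: RoiMask | Volume) -> float:
    """Bone volume fraction in percent: 100 x |bone ∩ roi| / |roi|."""
    roi_v = _roi_mask(roi)
    bone.check_same_grid(roi_v, "bv_tv")
    r = np.asarray(roi_v.values, dtype=bool)
    if not r.any():
        raise ValueError("empty ROI")
    b = np.asarray(bone.values, dtype=bool)
    return 100.0 * float((b & r).sum()) / float(r.sum())


def _isosurface(
    bone: Volume, roi: RoiMask | Volume, pad: bool, smooth_vox: float = 1.0
):
    """Triangulated bone surface in the ROI.

    Marching cubes at the 0.5 level of the Gaussian-smoothed (sigma one
    voxel) binary mask — smoothing removes most of the staircase area bias
    of a raw binary isosurface.  ``pad=False`` treats structure at the
    array border as continuing (open surfaces).  Returns (verts, faces,
    outward unit normals) in mm.
    """
    roi_v = _roi_mask(roi)
    bone.check_same_grid(roi_v, "bone_surface")
    mask = np.asarray(bone.values, dtype=bool) & np.asarray(roi_v.values, dtype=bool)
    if not mask.any():
        raise ValueError("no bone inside the ROI")
    if pad:
        k = int(np.ceil(3 * smooth_vox)) + 1
        mask = np.pad(mask, k, mode="constant")
    f = ndimage.gaussian_filter(mask.astype(np.float32), sigma=smooth_vox,
                                mode="reflect")
    if f.min() >= 0.5 or f.max() <= 0.5:
        return None
    verts, faces, normals, _ = skmeasure.marching_cubes(
        f, level=0.5, spacing=bone.spacing
    )
    # marching-cubes normals point down the field gradient, i.e. from the
    # high (inside) values toward the outside: already outward here
    norms = normals / np.maximum(np.linalg.norm(normals, axis=1, keepdims=True),
                                 1e-12)
    return verts, faces, norms


def _mesh_area(verts: np.ndarray, faces: np.ndarray) -> float:
    return float(skmeasure.mesh_surface_area(verts, faces))


def bone_surface(
    bone: Volume, roi: RoiMask | Volume, *, pad: bool = True
) -> tuple[float, float | None]:
    """Bone surface area (mm²) and BS/BV (1/mm) in the ROI."""
    mesh = _isosurface(bone, roi, pad=pad)
    area = _mesh_area(mesh[0], mesh[1]) if mesh else 0.0
    roi_v = _roi_mask(roi)
    b = np.asarray(bone.values, dtype=bool) & np.asarray(roi_v.values, dtype=bool)
    bv = float(b.sum()) * bone.voxel_volume
    return area, (area / bv if bv > 0 else None)


def local_thickness_nd(mask: np.ndarray, spacing) -> np.ndarray:
    """Local thickness map (mm) in any dimension: per element, the diameter
    of the largest inscribed sphere (disc in 2D) of the mask containing it
    — the distance-ridge / sphere-stamping algorithm of Hildebrand &
    Rüegsegger.

    Distance-ridge radii are processed exactly, in descending order; each
    radius group stamps its ball via a distance transform restricted to the
    group's bounding box, so the map equals the per-voxel inscribed-sphere
    definition.  Structure touching the array border is treated as
    continuing.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    if not mask.any():
        return np.zeros(mask.shape, dtype=float)
    edt = np.round(ndimage.distance_transform_edt(mask, sampling=spacing), 9)
    return _stamp_thickness(mask, edt, mask, spacing)


def _stamp_thickness(
    mask: np.ndarray, edt: np.ndarray, target: np.ndarray, spacing: np.ndarray
) -> np.ndarray:
    """Sphere-stamping core: fill ``target`` voxels (⊆ mask) with the
    diameter of the largest covering inscribed sphere, radii descending."""
    out = np.zeros(mask.shape, dtype=float)
    unassigned = target & mask
    if not unassigned.any():
        return out
    # only centres within max-radius reach of the target can matter
    r_max = float(edt[mask].max())
    idx = np.argwhere(unassigned)
    margin = np.ceil(r_max / spacing).astype(int) + 1
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    outer = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub_mask, sub_edt = mask[outer], edt[outer]
    sub_un = unassigned[outer]
    sub_out = out[outer]
    for r in np.unique(sub_edt[sub_mask])[::-1]:
        r = float(r)
        pts = (sub_edt == r) & sub_mask
        p_idx = np.argwhere(pts)
        m = np.ceil(r / spacing).astype(int) + 1
        b_lo = np.maximum(p_idx.min(axis=0) - m, 0)
        b_hi = np.minimum(p_idx.max(axis=0) + m + 1, sub_mask.shape)
        box = tuple(slice(l, h) for l, h in zip(b_lo, b_hi))
        dist = ndimage.distance_transform_edt(~pts[box], sampling=spacing)
        covered = (dist <= r + 1e-9) & sub_un[box]
        sub_out[box][covered] = 2.0 * r
        sub_un[box][covered] = False
        if not sub_un.any():
            break
    return out


def thickness_map(mask_vol: Volume) -> np.ndarray:
    """Local thickness map of a 3D mask volume (mm); see
    :func:`local_thickness_nd`."""
    return local_thickness_nd(np.asarray(mask_vol.values, dtype=bool),
                              mask_vol.spacing)


def local_thickness(mask_vol: Volume, roi: RoiMask | Volume) -> float | None:
    """Volume-weighted mean local thickness over mask ∩ roi, in μm.

    Tb.Th when the mask is the bone phase, Tb.Sp when it is the void phase
    within the total region.  Returns None (with a warning) when the
    intersection is empty.
    """
    roi_v = _roi_mask(roi)
    mask_vol.check_same_grid(roi_v, "local_thickness")
    mask = np.asarray(mask_vol.values, dtype=bool)
    sel = mask & np.asarray(roi_v.values, dtype=bool)
    if not sel.any():
        logger.warning("local_thickness: empty mask ∩ roi")
        return None
    spacing = np.asarray(mask_vol.spacing, dtype=float)
    edt = np.round(ndimage.distance_transform_edt(mask, sampling=spacing), 9)
    th = _stamp_thickness(mask, edt, sel, spacing)
    return float(th[sel].mean()) * 1000.0


def tb_n(tb_th_um: float, tb_sp_um: float) -> float:
    """Trabecular number, 1/mm: 1 / (Tb.Th + Tb.Sp)."""
    if tb_th_um <= 0 or tb_sp_um <= 0:
        raise ValueError("Tb.Th and Tb.Sp must be positive")
    return 1000.0 / (tb_th_um + tb_sp_um)


def smi(
    bone: Volume,
    roi: RoiMask | Volume,
    epsilon: float | None = None,
    *,
    pad: bool = False,
) -> float | None:
    """Structure model index: 6·V·S′/S² (0 plate, 3 rod, 4 sphere).

    S′ = (S(ε) − S)/ε with the dilated surface obtained by moving every
    mesh vertex by ε (default half a voxel) along its outward normal —
    the surface-dilation construction on the triangulated isosurface.
    Structure at the array border is treated as continuing (open
    surfaces), so ideal slabs and cylinders spanning the ROI behave as
    infinite.  Concave structures can legitimately go negative.  Returns
    None on a degenerate (zero-area) surface.
    """
    roi_v = _roi_mask(roi)
    if epsilon is None:
        epsilon = 0.5 * min(bone.spacing)
    mesh = _isosurface(bone, roi, pad=pad)
    if mesh is None:
        logger.warning("smi: degenerate surface")
        return None
    verts, faces, normals = mesh
    s0 = _mesh_area(verts, faces)
    if s0 <= 0:
        logger.warning("smi: degenerate surface")
        return None
    s1 = _mesh_area(verts + epsilon * normals, faces)
    sel = np.asarray(bone.values, dtype=bool) & np.asarray(roi_v.values, dtype=bool)
    v = float(sel.sum()) * bone.voxel_volume
    s_prime = (s1 - s0) / epsilon
    return 6.0 * v * s_prime / (s0 * s0)


@dataclass
class MilResult:
    """Mean-intercept-length fabric: tensor fit, principal MILs and DA."""

    tensor: np.ndarray  # the 3x3 ellipsoid tensor A in 1/MIL² = ω·A·ω
    mil_principal: np.ndarray  # principal MILs, descending (mm)
    principal_axis: np.ndarray  # unit direction of the longest MIL
    da: float  # longest / shortest principal MIL (>= 1)
    n_intercepts: int


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform directions on the upper hemisphere (antipodes folded)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = (i + 0.5) / n  # upper hemisphere only
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def mil_anisotropy(
    bone: Volume,
    roi: RoiMask | Volume,
    n_directions: int = 512,
    n_lines: int = 128,
    seed: int = 0,
    step_factor: float = 0.5,
) -> MilResult:
    """Mean-intercept-length fabric tensor and degree of anisotropy.

    Test lines through random points of the ROI bounding box are marched in
    quasi-uniform sphere directions; MIL(ω) is the bone length per
    bone-entry intercept.  An ellipsoid 1/MIL² = ω·A·ω is least-squares
    fitted; DA is the longest-to-shortest principal MIL ratio (>= 1), and
    the principal axis the direction of the longest MIL (trabecular
    alignment).
    """
    roi_v = _roi_mask(roi)
    bone.check_same_grid(roi_v, "mil_anisotropy")
    r = np.asarray(roi_v.values, dtype=bool)
    b = np.asarray(bone.values, dtype=bool) & r
    if not b.any() or not (r & ~b).any():
        raise ValueError("MIL needs both bone and void inside the ROI")
    rng = np.random.default_rng(seed)
    spacing = np.asarray(bone.spacing)
    idx = np.argwhere(r)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    extent_mm = (hi - lo + 1) * spacing
    diag = float(np.linalg.norm(extent_mm))
    step = step_factor * float(spacing.min())
    n_steps = int(np.ceil(diag / step)) + 1
    t = (np.arange(n_steps) - n_steps / 2) * step

    dirs = _fibonacci_hemisphere(n_directions)
    mils = np.empty(n_directions)
    total_intercepts = 0
    centre_mm = (lo + (hi - lo) / 2) * spacing
    for d_i, w in enumerate(dirs):
        origins = (lo + rng.random((n_lines, 3)) * (hi - lo)) * spacing
        # line points in mm, then nearest voxel index
        pts = origins[None, :, :] + t[:, None, None] * w[None, None, :]
        ijk = np.round(pts / spacing).astype(np.int64)
        inb = np.all((ijk >= 0) & (ijk < np.array(bone.shape)), axis=2)
        ijk_c = np.clip(ijk, 0, np.array(bone.shape) - 1)
        flat = np.ravel_multi_index(
            (ijk_c[..., 0], ijk_c[..., 1], ijk_c[..., 2]), bone.shape
        )
        valid = r.ravel()[flat] & inb
        in_bone = b.ravel()[flat] & valid
        bone_len = float(in_bone.sum()) * step
        # entries into bone from valid void along each line
        prev_void = valid[:-1] & ~in_bone[:-1]
        entries = int(np.sum(prev_void & in_bone[1:]))
        total_intercepts += entries
        mils[d_i] = bone_len / max(entries, 1)
    if total_intercepts < 100:
        logger.warning(
            "mil_anisotropy: only %d intercepts; estimates may be unstable — "
            "increase n_lines or the ROI", total_intercepts,
        )

    # least-squares ellipsoid fit to y = 1/MIL² = ω·A·ω
    y = 1.0 / np.maximum(mils, 1e-12) ** 2
    wx, wy, wz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    design = np.stack(
        [wx * wx, wy * wy, wz * wz, 2 * wx * wy, 2 * wx * wz, 2 * wy * wz], axis=1
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a = np.array([
        [coef[0], coef[3], coef[4]],
        [coef[3], coef[1], coef[5]],
        [coef[4], coef[5], coef[2]],
    ])
    evals, evecs = np.linalg.eigh(a)
    evals = np.maximum(evals, 1e-12)
    mil_axes = 1.0 / np.sqrt(evals)  # descending MIL = ascending eigenvalue
    order = np.argsort(mil_axes)[::-1]
    mil_axes = mil_axes[order]
    axes = evecs[:, order]
    return MilResult(
        tensor=a,
        mil_principal=mil_axes,
        principal_axis=axes[:, 0] / np.linalg.norm(axes[:, 0]),
        da=float(mil_axes[0] / mil_axes[-1]),
        n_intercepts=total_intercepts,
    )


def euler_characteristic(mask: np.ndarray) -> int:
    """3D Euler characteristic with foreground 26-connectivity.

    The mask is zero-padded first, so structure touching the array border
    is capped rather than mirrored.
    """
    padded = np.pad(np.asarray(mask, dtype=bool), 1, mode="constant")
    return int(skmeasure.euler_number(padded, connectivity=3))


def conn_density(bone: Volume, roi: RoiMask | Volume) -> float:
    """Connectivity density, 1/mm³: (1 − χ)/TV over bone ∩ roi."""
    roi_v = _roi_mask(roi)
    bone.check_same_grid(roi_v, "conn_density")
    r = np.asarray(roi_v.values, dtype=bool)
    if not r.any():
        raise ValueError("empty ROI")
    sel = np.asarray(bone.values, dtype=bool) & r
    tv = float(r.sum()) * bone.voxel_volume
    chi = euler_characteristic(sel)
    return (1.0 - chi) / tv


def compute_panel(
    bone: Volume,
    roi: RoiMask | Volume,
    *,
    total: Volume | None = None,
    n_directions: int = 512,
    n_lines: int = 128,
    seed: int = 0,
    da_convention: str = "max_over_min",
) -> MicroarchParams:
    """The full 8-parameter panel on one ROI.

    The void phase for Tb.Sp is the complement of bone, clipped to the
    total region when given.  ``da_convention``: ``max_over_min`` (>= 1,
    default) or ``one_minus_min_over_max`` (in [0, 1)).
    """
    roi_v = _roi_mask(roi)
    void_vals = ~np.asarray(bone.values, dtype=bool)
    if total is not None:
        void_vals &= np.asarray(total.values, dtype=bool)
    void = bone.like(void_vals)

    p_bvtv = bv_tv(bone, roi_v)
    _, p_bsbv = bone_surface(bone, roi_v, pad=False)
    p_th = local_thickness(bone, roi_v)
    p_sp = local_thickness(void, roi_v)
    p_tbn = tb_n(p_th, p_sp) if (p_th and p_sp) else None
    p_smi = smi(bone, roi_v)
    try:
        mil = mil_anisotropy(bone, roi_v, n_directions, n_lines, seed)
        p_da = mil.da
        if da_convention == "one_minus_min_over_max":
            p_da = 1.0 - 1.0 / mil.da
    except ValueError:
        p_da = None
    p_connd = conn_density(bone, roi_v)
    return MicroarchParams(
        bv_tv=p_bvtv, bs_bv=p_bsbv, tb_th=p_th, tb_sp=p_sp,
        tb_n=p_tbn, smi=p_smi, da=p_da, conn_d=p_connd,
    )
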