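"""Synthetic femoral-head phantoms with known ground truth.

The phantom stands in for surgical femoral-head specimens: a spherical
head of trabecular bone (a thresholded Gaussian random field, giving a
controllable porous structure), a cortical shell, and quasi-spherical
cystic voids carved at specified positions.  Each cyst is enclosed by a
thin sclerotic rim of bone so that it is a sealed interior void, the way
the detection pipeline defines a cyst, rather than an open pocket of the
marrow network.  A matching 2D histology-section generator and a cohort
generator provide ground truth for the histomorphometry and statistics
stages.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .histo2d import BONE as HISTO_BONE
from .histo2d import ERODED as HISTO_ERODED
from .histo2d import MARROW as HISTO_MARROW
from .histo2d import OSTEOID as HISTO_OSTEOID
from .histo2d import HistoSection2D
from .volio import LandmarkSet, Volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CystSpec",
    "HistoSection2D",
    "CohortSpec",
    "generate_head",
    "generate_trabecular_block",
    "generate_histo_section",
    "generate_cohort",
    "MARROW_INTENSITY",
    "BONE_INTENSITY",
]

# Intensity conventions: marrow well below and bone well above the 90-255
# mineralized-tissue window, so the window separates the classes before noise.
MARROW_INTENSITY = 40.0
BONE_INTENSITY = 160.0


@dataclass(frozen=True)
class CystSpec:
    """One spherical cystic void: centre in mm (head centre = origin), diameter in mm."""

    centre: tuple[float, float, float]
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"cyst diameter must be positive, got {self.diameter}")


@dataclass
class PhantomSpec:
    """Parameters of the synthetic femoral head.

    Parameters
    ----------
    head_radius
        Radius of the spherical head, mm.
    voxel_size
        Isotropic voxel edge, mm.  0.0736 mm mirrors a high-resolution
        specimen micro-CT scan; coarser grids are fine for tests.
    bone_fraction_target
        Target BV/TV of the trabecular compartment, in (0, 1).
    strut_scale
        Autocorrelation length of the trabecular texture, mm; sets the
        strut thickness / separation scale.
    anisotropy_stretch
        >= 1; stretches the texture autocorrelation along the main
        trabeculae direction (z), making struts preferentially aligned.
    cortical_thickness
        Thickness of the solid cortical shell, mm.
    cyst_specs
        Spherical voids to carve, as :class:`CystSpec` or (centre, diameter).
    rim_thickness
        Thickness of the sclerotic bone rim sealing each cyst, mm.  The
        realized rim is at least two voxels thick so the discrete shell is
        watertight.
    max_pore_diameter
        Cap on the inscribed diameter of marrow pores, mm.  A raw
        thresholded random field has a heavy pore-size tail; real
        trabecular separation in the femoral head is far more uniform and
        stays well below the 1 mm cyst rule, so oversized pore cores are
        patched with bone.
    noise_sd
        SD of additive Gaussian intensity noise.
    blur_sigma
        Gaussian blur applied before noise, mm (partial-volume surrogate).
    """

    head_radius: float = 12.0
    voxel_size: float = 0.0736
    bone_fraction_target: float = 0.30
    strut_scale: float = 0.25
    anisotropy_stretch: float = 1.3
    cortical_thickness: float = 0.6
    cyst_specs: Sequence[CystSpec] = field(default_factory=list)
    rim_thickness: float = 0.3
    max_pore_diameter: float = 0.7
    noise_sd: float = 8.0
    blur_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.cyst_specs = [
            c if isinstance(c, CystSpec) else CystSpec(tuple(c[0]), float(c[1]))
            for c in self.cyst_specs
        ]
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.head_radius < 10 * self.voxel_size:
            raise ValueError(
                f"head_radius {self.head_radius} mm must be at least 10 voxels "
                f"({10 * self.voxel_size} mm)"
            )
        if not 0 < self.bone_fraction_target < 1:
            raise ValueError("bone_fraction_target must be in (0, 1)")
        if self.anisotropy_stretch < 1:
            raise ValueError("anisotropy_stretch must be >= 1")
        # cysts must lie fully inside the head (rim included)
        rim = self.effective_rim
        for i, c in enumerate(self.cyst_specs):
            reach = np.linalg.norm(c.centre) + c.diameter / 2 + rim
            if reach > self.head_radius - self.cortical_thickness:
                raise ValueError(
                    f"cyst {i} (centre {c.centre}, diameter {c.diameter}) extends "
                    "outside the trabecular compartment of the head"
                )
        # pairwise overlap check, rims included
        colliding = []
        for i in range(len(self.cyst_specs)):
            for j in range(i + 1, len(self.cyst_specs)):
                a, b = self.cyst_specs[i], self.cyst_specs[j]
                gap = np.linalg.norm(np.subtract(a.centre, b.centre))
                if gap < a.diameter / 2 + b.diameter / 2 + 2 * rim:
                    colliding.append((i, j))
        if colliding:
            raise ValueError(f"overlapping cyst specs at index pairs {colliding}")

    @property
    def effective_rim(self) -> float:
        """Realized rim thickness: at least two voxels, so the shell seals."""
        return max(self.rim_thickness, 2.0 * self.voxel_size)


@dataclass
class PhantomTruth:
    """Ground truth emitted with a phantom."""

    cyst_label_truth: Volume
    cyst_diameters: list[float]
    cyst_volumes_analytic: list[float]
    cyst_volumes_voxel: list[float]
    bone_mask_truth: Volume
    head_mask_truth: Volume
    landmarks: LandmarkSet


def _gaussian_random_field(
    shape: tuple[int, ...],
    sigma_vox: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Smoothed white noise, standardized to zero mean / unit variance."""
    field = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(field, sigma=sigma_vox, mode="reflect")
    field -= field.mean()
    sd = field.std()
    if sd > 0:
        field /= sd
    return field


def generate_head(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Generate the phantom volume plus its ground truth.

    The trabecular texture is a Gaussian random field with anisotropic
    autocorrelation (``strut_scale``, stretched along z by
    ``anisotropy_stretch``), thresholded at the quantile that hits
    ``bone_fraction_target`` inside the trabecular compartment.  Cyst voids
    (and their sealing rims) are carved afterwards, then the volume is
    blurred, noised, and quantized to 8 bits.
    """
    rng = np.random.default_rng(spec.seed)
    vx = spec.voxel_size
    margin = max(2 * vx, spec.blur_sigma * 3, 0.3)
    half = spec.head_radius + margin
    n = int(np.ceil(2 * half / vx))
    # head centre at world origin, voxel-centre convention
    origin = tuple(-(n - 1) / 2 * vx for _ in range(3))
    grid = Volume(np.zeros((n, n, n), dtype=np.uint8), (vx, vx, vx), origin)
    cx, cy, cz = grid.index_grid_world()
    r2 = cx**2 + cy**2 + cz**2
    head = r2 <= spec.head_radius**2
    trabecular = r2 <= (spec.head_radius - spec.cortical_thickness) ** 2
    cortex = head & ~trabecular

    # anisotropic GRF: correlation length strut_scale, stretched along z (MTD)
    sigma_vox = np.array([1.0, 1.0, spec.anisotropy_stretch]) * (spec.strut_scale / vx)
    field = _gaussian_random_field((n, n, n), sigma_vox, rng)
    vals = field[trabecular]
    thr = np.quantile(vals, 1.0 - spec.bone_fraction_target)
    bone = np.zeros((n, n, n), dtype=bool)
    bone[trabecular] = field[trabecular] >= thr
    bone |= cortex

    # cap marrow pore size: patch the cores of oversized pores with bone
    if spec.max_pore_diameter > 0:
        pore = trabecular & ~bone
        pore_edt = ndimage.distance_transform_edt(pore, sampling=(vx,) * 3)
        bone |= pore_edt > spec.max_pore_diameter / 2.0

    # carve cysts: void sphere + sclerotic rim of bone
    labels = np.zeros((n, n, n), dtype=np.int32)
    vol_voxel = []
    rim_t = spec.effective_rim
    for i, c in enumerate(spec.cyst_specs):
        d2 = (cx - c.centre[0]) ** 2 + (cy - c.centre[1]) ** 2 + (cz - c.centre[2]) ** 2
        void = d2 <= (c.diameter / 2) ** 2
        rim = (d2 <= (c.diameter / 2 + rim_t) ** 2) & ~void
        bone[rim] = True
        bone[void] = False
        labels[void] = i + 1
        vol_voxel.append(float(void.sum()) * grid.voxel_volume)

    intensity = np.full((n, n, n), 0.0)
    intensity[head] = MARROW_INTENSITY
    intensity[bone] = BONE_INTENSITY
    if spec.blur_sigma > 0:
        intensity = ndimage.gaussian_filter(intensity, sigma=spec.blur_sigma / vx)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    volume = grid.like(np.clip(np.round(intensity), 0, 255).astype(np.uint8))

    landmarks = LandmarkSet(
        head_centre=(0.0, 0.0, 0.0),
        # fovea sits on the medial (+x) surface, neck/calcar centre inferior
        fovea_centre=(spec.head_radius, 0.0, 0.0),
        neck_centre=(0.0, 0.0, -spec.head_radius),
        mtd=(0.0, 0.0, 1.0),
        side="left",
    )
    truth = PhantomTruth(
        cyst_label_truth=grid.like(labels),
        cyst_diameters=[c.diameter for c in spec.cyst_specs],
        cyst_volumes_analytic=[
            4.0 / 3.0 * np.pi * (c.diameter / 2) ** 3 for c in spec.cyst_specs
        ],
        cyst_volumes_voxel=vol_voxel,
        bone_mask_truth=grid.like(bone),
        head_mask_truth=grid.like(head),
        landmarks=landmarks,
    )
    return volume, truth


# Peri-cyst shell condition presets for generate_trabecular_block.
# Sclerotic bone (degenerative compensation) is dense and near-isotropic;
# lytic bone (necrotic remodelling) keeps the architectural scale but has
# thinned struts, wider spacing and more pronounced alignment of the
# remnant trabeculae.
SCLEROTIC_SHELL = {
    "bone_fraction": 0.40, "strut_scale": 0.30, "anisotropy_stretch": 1.1,
}
LYTIC_SHELL = {
    "bone_fraction": 0.15, "strut_scale": 0.30, "anisotropy_stretch": 1.8,
}


def generate_trabecular_block(
    shape: tuple[int, int, int],
    voxel_size: float,
    bone_fraction: float,
    strut_scale: float,
    anisotropy_stretch: float = 1.0,
    seed: int = 0,
) -> Volume:
    """A bare trabecular bone mask on a block grid (no head, no cortex).

    Convenience substrate for morphometry experiments, e.g. contrasting a
    sclerotic peri-cyst shell (dense, thick, fine-spaced struts) with a
    lytic one (sparse, thin, coarse, more aligned struts).
    """
    rng = np.random.default_rng(seed)
    sigma_vox = np.array([1.0, 1.0, anisotropy_stretch]) * (strut_scale / voxel_size)
    f = _gaussian_random_field(shape, sigma_vox, rng)
    thr = np.quantile(f, 1.0 - bone_fraction)
    return Volume(f >= thr, (voxel_size,) * 3, (0.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# 2D histology sections
# ---------------------------------------------------------------------------



def _boundary_edge_counts(solid: np.ndarray) -> np.ndarray:
    """Per-pixel count of 4-adjacent (solid, marrow) edges."""
    counts = np.zeros(solid.shape, dtype=np.int32)
    for axis in (0, 1):
        for shift in (1, -1):
            neigh = np.roll(~solid, shift, axis=axis)
            # rolled-in border wraps; treat out-of-image as marrow
            edge = np.zeros(solid.shape, dtype=bool)
            sl = [slice(None), slice(None)]
            sl[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
            edge[tuple(sl)] = True
            counts += (solid & (neigh | edge)).astype(np.int32)
    return counts


def generate_histo_section(
    width: int,
    height: int,
    osteoid_fraction: float,
    eroded_surface_fraction: float,
    seed: int = 0,
    *,
    pixel_size_um: float = 5.0,
    bone_area_fraction: float = 0.45,
    texture_scale_px: float = 12.0,
) -> HistoSection2D:
    """Generate a labelled section with programmed osteoid and erosion.

    ``osteoid_fraction`` is the target OV/BV (osteoid area over total solid
    area); ``eroded_surface_fraction`` the target ES/BS (fraction of the
    bone-marrow boundary carrying the eroded-surface marker).  Osteoid is
    laid down as seams along the bone surface (shallowest bone pixels
    first), erosion as marker pixels on the boundary itself.  Realized
    fractions are recorded in ``truth``.
    """
    if not (0 <= osteoid_fraction < 1 and 0 <= eroded_surface_fraction < 1):
        raise ValueError("fractions must lie in [0, 1)")
    if osteoid_fraction + eroded_surface_fraction >= 1:
        raise ValueError("osteoid + eroded fractions must sum to < 1")
    rng = np.random.default_rng(seed)

    f = rng.standard_normal((width, height))
    f = ndimage.gaussian_filter(f, sigma=texture_scale_px, mode="reflect")
    thr = np.quantile(f, 1.0 - bone_area_fraction)
    solid = f >= thr
    labels = np.where(solid, HISTO_BONE, HISTO_MARROW).astype(np.uint8)
    total_solid = int(solid.sum())
    if total_solid == 0:
        raise ValueError("degenerate section: no bone generated")

    edge_counts = _boundary_edge_counts(solid)
    total_edges = int(edge_counts.sum())

    # eroded-surface marker: convert boundary pixels until the edge quota
    target_edges = eroded_surface_fraction * total_edges
    boundary_idx = np.flatnonzero((edge_counts > 0).ravel() & solid.ravel())
    rng.shuffle(boundary_idx)
    flat_counts = edge_counts.ravel()
    got, chosen = 0, []
    for idx in boundary_idx:
        if got >= target_edges:
            break
        chosen.append(idx)
        got += int(flat_counts[idx])
    flat = labels.ravel()
    flat[np.array(chosen, dtype=np.intp)] = HISTO_ERODED if chosen else flat[:0]
    realized_es_bs = got / total_edges if total_edges else 0.0

    # osteoid seams: shallowest remaining bone pixels, random tie-break
    k = int(round(osteoid_fraction * total_solid))
    if k > 0:
        depth = ndimage.distance_transform_edt(solid)
        candidates = np.flatnonzero((labels == HISTO_BONE).ravel())
        keys = depth.ravel()[candidates] + rng.uniform(0, 0.5, size=candidates.size)
        order = candidates[np.argsort(keys)]
        flat[order[:k]] = HISTO_OSTEOID
    realized_ov_bv = k / total_solid

    return HistoSection2D(
        labels=labels,
        pixel_size_um=pixel_size_um,
        truth={
            "ov_bv": realized_ov_bv,
            "es_bs": realized_es_bs,
            "bone_area_fraction": total_solid / solid.size,
        },
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Two-group cohort generator specification.

    ``continuous`` maps a variable name to per-group ``(family, loc, scale)``
    tuples, e.g. ``{"age": (("normal", 63.2, 10.6), ("normal", 49.6, 13.4))}``;
    families: normal, lognormal (loc/scale on the log scale), uniform
    (loc=low, scale=width).  ``categorical`` maps a name to per-group event
    probabilities ``(p_a, p_b)``.
    """

    n_group_a: int
    n_group_b: int
    continuous: dict = field(default_factory=dict)
    categorical: dict = field(default_factory=dict)
    group_names: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("both group sizes must be >= 2")
        for name, (pa, pb) in self.categorical.items():
            if not (0 <= pa <= 1 and 0 <= pb <= 1):
                raise ValueError(f"{name}: event probabilities must lie in [0, 1]")


def _draw(rng: np.random.Generator, family: str, loc: float, scale: float, n: int):
    if family == "normal":
        return rng.normal(loc, scale, n)
    if family == "lognormal":
        return rng.lognormal(loc, scale, n)
    if family == "uniform":
        return rng.uniform(loc, loc + scale, n)
    raise ValueError(f"unknown distribution family {family!r}")


def generate_cohort(spec: CohortSpec):
    """Draw a two-group subject table per the spec; deterministic per seed."""
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    na, nb = spec.n_group_a, spec.n_group_b
    data = {
        "subject_id": [f"S{i:04d}" for i in range(na + nb)],
        "group": [spec.group_names[0]] * na + [spec.group_names[1]] * nb,
    }
    for name, (gen_a, gen_b) in spec.continuous.items():
        a = _draw(rng, *gen_a, na)
        b = _draw(rng, *gen_b, nb)
        data[name] = np.concatenate([a, b])
    for name, (pa, pb) in spec.categorical.items():
        a = rng.random(na) < pa
        b = rng.random(nb) < pb
        data[name] = np.concatenate([a, b]).astype(int)
    return pd.DataFrame(data)
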