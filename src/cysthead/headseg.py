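"""Six-region / three-pillar segmentation of the femoral head.

Geometry: a reference plane through the head, fovea and neck/calcar
centres splits the head into anterior and posterior hemispheres; two
cutting planes parallel to the main trabeculae direction (MTD) and
perpendicular to the reference plane split it into lateral / central /
medial pillars covering 30% / 40% / 30% of the head width.  Regions are
numbered I-III (anterior lateral/central/medial) and IV-VI (posterior).

Anterior-normal orientation truth table (n0 = normalize((fovea-head) x
(neck-head))): left hip -> anterior normal = +n0; right hip -> -n0.  The
lateral side is the width-axis end farther from the fovea, which is
anatomically medial — no hidden handedness parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cystdetect import CystRecord
from .volio import LandmarkSet, Volume

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationGeometry",
    "reference_plane",
    "estimate_mtd",
    "segment_regions",
    "assign_cyst_region",
    "apply_region_assignment",
    "pillar_counts",
    "REGION_PILLAR",
    "REGION_HEMISPHERE",
]

REGION_NAMES = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI"}
REGION_PILLAR = {
    "I": "lateral", "II": "central", "III": "medial",
    "IV": "lateral", "V": "central", "VI": "medial",
}
REGION_HEMISPHERE = {
    "I": "anterior", "II": "anterior", "III": "anterior",
    "IV": "posterior", "V": "posterior", "VI": "posterior",
}


@dataclass
class SegmentationGeometry:
    """World-space geometry of the six-region segmentation."""

    reference_point: np.ndarray  # a point on the reference plane (head centre)
    reference_normal: np.ndarray  # unit normal, oriented anterior
    mtd: np.ndarray  # unit main-trabeculae direction
    w_axis: np.ndarray  # unit width axis (perp. to MTD, in the reference plane)
    head_width: float  # mm, extent of the head projection on w_axis
    w_min: float  # mm, lowest head w-coordinate (relative to reference point)
    cut_1: float  # mm, first cut plane w-coordinate (lateral|central)
    cut_2: float  # mm, second cut plane w-coordinate (central|medial)
    medial_is_positive_w: bool

    @property
    def cut_planes(self):
        """The two cutting planes as (point, normal) pairs in world space."""
        return [
            (self.reference_point + c * self.w_axis, self.w_axis)
            for c in (self.cut_1, self.cut_2)
        ]


def reference_plane(lm: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    """Plane through the head, fovea and neck centres.

    Returns (point, unit normal), the normal oriented toward the anterior
    side per the ``side`` convention in the module docstring.  Collinear
    landmarks raise (the LandmarkSet constructor already enforces this).
    """
    u = lm.fovea_centre - lm.head_centre
    v = lm.neck_centre - lm.head_centre
    n = np.cross(u, v)
    norm = np.linalg.norm(n)
    if norm <= 1e-12:
        raise ValueError("landmarks are collinear: reference plane undefined")
    n = n / norm
    if lm.side == "right":
        n = -n
    return lm.head_centre.copy(), n


def estimate_mtd(
    bone: Volume,
    n_directions: int = 256,
    n_lines: int = 200,
    seed: int = 0,
    isotropy_ratio: float = 1.05,
) -> np.ndarray:
    """Estimate the main trabeculae direction from the bone mask.

    A stand-in for manual MTD placement: the principal (longest) axis of
    the mean-intercept-length fabric tensor, i.e. the direction along which
    bone intercepts are longest.  Near-isotropic structure (MIL axis ratio
    below ``isotropy_ratio``) falls back to the superoinferior (z) axis
    with a warning.  The sign is chosen with a non-negative z component.
    """
    from .microarch import mil_anisotropy

    roi = bone.like(np.ones(bone.shape, dtype=bool))
    result = mil_anisotropy(bone, roi, n_directions=n_directions,
                            n_lines=n_lines, seed=seed)
    if result.da < isotropy_ratio:
        logger.warning(
            "estimate_mtd: near-isotropic structure (DA=%.3f < %.2f); "
            "defaulting to the z axis", result.da, isotropy_ratio,
        )
        return np.array([0.0, 0.0, 1.0])
    mtd = result.principal_axis
    if mtd[2] < 0 or (mtd[2] == 0 and (mtd[0] < 0 or (mtd[0] == 0 and mtd[1] < 0))):
        mtd = -mtd
    return mtd


def segment_regions(
    head: Volume,
    lm: LandmarkSet,
    fractions: tuple[float, float, float] = (0.30, 0.40, 0.30),
) -> tuple[Volume, SegmentationGeometry]:
    """Label every head voxel with its region (1-6 = I-VI).

    The width axis w is the unit vector perpendicular to the MTD lying in
    the reference plane; the head width is the extent of the head-mask
    projection onto w, and the cutting planes sit at the cumulative
    lateral / lateral+central width fractions.  Voxels are classified by
    the signed distance of their centres to the true world-space planes.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"pillar fractions must sum to 1, got {fractions}")
    if lm.mtd is None:
        raise ValueError("landmarks carry no MTD; run estimate_mtd first")
    mask = np.asarray(head.values, dtype=bool)
    if not mask.any():
        raise ValueError("empty head mask")

    point, normal = reference_plane(lm)
    mtd = np.asarray(lm.mtd, dtype=float)
    w = np.cross(normal, mtd)
    wnorm = np.linalg.norm(w)
    if wnorm < 1e-9:
        raise ValueError("MTD is parallel to the reference-plane normal; "
                         "width axis undefined")
    w = w / wnorm

    cx, cy, cz = head.index_grid_world()
    # signed coordinates relative to the reference point
    wc = (cx - point[0]) * w[0] + (cy - point[1]) * w[1] + (cz - point[2]) * w[2]
    sc = ((cx - point[0]) * normal[0] + (cy - point[1]) * normal[1]
          + (cz - point[2]) * normal[2])

    w_vals = wc[mask]
    # head width = physical extent of the voxel footprints projected on w
    # (centre extent plus one voxel footprint), so a digitized sphere of
    # radius R measures 2R rather than 2R minus a voxel
    w_half = 0.5 * float(np.sum(np.abs(w) * np.asarray(head.spacing)))
    w_min = float(w_vals.min()) - w_half
    w_max = float(w_vals.max()) + w_half
    head_width = w_max - w_min
    cut_1 = w_min + fractions[0] * head_width
    cut_2 = w_min + (fractions[0] + fractions[1]) * head_width

    fovea_w = float(np.dot(lm.fovea_centre - point, w))
    centre_w = float(np.dot(lm.head_centre - point, w))
    if abs(fovea_w - centre_w) < 1e-9:
        raise ValueError(
            "fovea projects onto the head-centre width coordinate; "
            "medial side undefined"
        )
    medial_is_positive_w = fovea_w > centre_w

    # normalized width coordinate with the lateral end at 0
    u = (wc - w_min) / head_width if head_width > 0 else np.zeros_like(wc)
    if not medial_is_positive_w:
        u = 1.0 - u
    pillar = np.full(mask.shape, 0, dtype=np.uint8)  # 0 lat, 1 cen, 2 med
    pillar[u >= fractions[0]] = 1
    pillar[u >= fractions[0] + fractions[1]] = 2
    anterior = sc >= 0

    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[mask] = (pillar[mask] + 1) + np.where(anterior[mask], 0, 3)

    geometry = SegmentationGeometry(
        reference_point=point,
        reference_normal=normal,
        mtd=mtd,
        w_axis=w,
        head_width=head_width,
        w_min=w_min,
        cut_1=cut_1,
        cut_2=cut_2,
        medial_is_positive_w=medial_is_positive_w,
    )
    return head.like(labels), geometry


def assign_cyst_region(cyst_labels: Volume, regions: Volume) -> dict[int, dict]:
    """Assign each cyst to its distribution area.

    A cyst may span several regions; the region holding the highest voxel
    fraction of the cyst wins (exact ties go to the lower region index and
    are flagged).  Cysts with zero overlap with the head mask come back
    ``unassigned`` with a warning.  Returns, per cyst label, the region
    name, pillar, hemisphere, the full six-region overlap-fraction vector,
    and the tie flag.
    """
    cyst_labels.check_same_grid(regions, "assign_cyst_region")
    cl = np.asarray(cyst_labels.values)
    rg = np.asarray(regions.values)
    out: dict[int, dict] = {}
    for lab in np.unique(cl[cl > 0]):
        sel = cl == lab
        total = int(sel.sum())
        counts = np.bincount(rg[sel].ravel(), minlength=7)
        overlap = {REGION_NAMES[r]: counts[r] / total for r in range(1, 7)}
        inside = counts[1:7].sum()
        if inside == 0:
            logger.warning("cyst %d has no overlap with the head mask", int(lab))
            out[int(lab)] = {
                "region": "unassigned", "pillar": "unassigned",
                "hemisphere": "unassigned", "overlap": overlap, "tie": False,
            }
            continue
        best = int(np.argmax(counts[1:7])) + 1
        tie = int(np.sum(counts[1:7] == counts[best])) > 1
        name = REGION_NAMES[best]
        out[int(lab)] = {
            "region": name,
            "pillar": REGION_PILLAR[name],
            "hemisphere": REGION_HEMISPHERE[name],
            "overlap": overlap,
            "tie": tie,
        }
    return out


def apply_region_assignment(
    records: list[CystRecord], assignment: dict[int, dict]
) -> list[CystRecord]:
    """Copy an assign_cyst_region result onto the matching cyst records."""
    for r in records:
        if r.id in assignment:
            a = assignment[r.id]
            r.region = a["region"]
            r.pillar = a["pillar"]
            r.hemisphere = a["hemisphere"]
            r.region_overlap = a["overlap"]
            r.tie = a["tie"]
    return records


def pillar_counts(records: list[CystRecord]):
    """Cyst counts by pillar x hemisphere, with marginals.

    Unassigned records are excluded; the grand total therefore equals the
    number of assigned cysts.
    """
    import pandas as pd

    pillars = ["lateral", "central", "medial"]
    hemis = ["anterior", "posterior"]
    table = pd.DataFrame(0, index=pillars, columns=hemis, dtype=int)
    for r in records:
        if r.pillar in pillars and r.hemisphere in hemis:
            table.loc[r.pillar, r.hemisphere] += 1
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table
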