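"""2D histomorphometry of labelled undecalcified sections.

The module consumes already-labelled sections (class segmentation of
stained RGB images is out of scope): 0 marrow/void, 1 mineralized bone,
2 osteoid, 3 eroded-surface marker.  Osteoid parameters index bone
formation, eroded-surface parameters bone resorption; microvessel density
follows the Weidner counting rule (any isolated endothelial cluster is one
vessel).

Surface densities are reported as raw 2D length/area (mm/mm²) by default;
``stereology=True`` applies the standard 4/π section-to-volume correction,
after which the units read mm²/mm³.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "HistoSection2D",
    "HistoParams",
    "VesselFieldSet",
    "measure_osteoid",
    "measure_erosion",
    "compute_histo_panel",
    "microvessel_density",
    "MARROW",
    "BONE",
    "OSTEOID",
    "ERODED",
]

MARROW, BONE, OSTEOID, ERODED = 0, 1, 2, 3

STEREOLOGY_FACTOR = 4.0 / np.pi  # perimeter density -> surface density


@dataclass
class HistoSection2D:
    """Labelled 2D section: 0 marrow, 1 mineralized bone, 2 osteoid,
    3 eroded-surface marker; pixel size in μm.  ``truth`` records realized
    generator fractions (empty for externally annotated sections)."""

    labels: np.ndarray
    pixel_size_um: float
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("section labels must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class HistoParams:
    """The seven-parameter osteoid/erosion panel."""

    o_th: float | None  # μm
    ov_bv: float  # %
    os_bs: float  # %
    os_bv: float  # mm/mm² (x 4/π -> mm²/mm³ with stereology)
    es_bs: float  # %
    es_bv: float
    es_tv: float
    stereology: bool = False


def _boundary_edges_by_class(labels: np.ndarray) -> dict[int, int]:
    """Count 4-adjacent (solid, marrow) edges, keyed by the solid pixel's
    class.  Out-of-image neighbours count as marrow."""
    solid = labels > 0
    counts: dict[int, int] = {BONE: 0, OSTEOID: 0, ERODED: 0}
    padded_marrow = np.pad(~solid, 1, mode="constant", constant_values=True)
    for axis in (0, 1):
        for shift in (1, -1):
            sl = [slice(1, -1), slice(1, -1)]
            sl[axis] = slice(2, None) if shift == 1 else slice(None, -2)
            neigh_marrow = padded_marrow[tuple(sl)]
            edge_pix = solid & neigh_marrow
            for cls in counts:
                counts[cls] += int(np.sum(edge_pix & (labels == cls)))
    return counts


def measure_osteoid(
    section: HistoSection2D, stereology: bool = False
) -> tuple[float | None, float, float, float]:
    """(O.Th μm, OV/BV %, OS/BS %, OS/BV) on one section.

    OV/BV is osteoid area over total solid (bone + osteoid + eroded-marker)
    area; BS is the solid-marrow boundary; OS/BS the fraction of it whose
    solid pixel is osteoid; OS/BV the osteoid-covered boundary length per
    solid area.  O.Th is the mean 2D local thickness (inscribed-disc
    diameter) of the osteoid seams, None when no osteoid is present.
    """
    labels = section.labels
    a_solid = int(np.sum(labels > 0))
    if a_solid == 0:
        logger.warning("measure_osteoid: no bone in section")
        return None, float("nan"), float("nan"), float("nan")
    px_mm = section.pixel_size_um / 1000.0
    a_osteoid = int(np.sum(labels == OSTEOID))
    ov_bv = 100.0 * a_osteoid / a_solid

    edges = _boundary_edges_by_class(labels)
    bs_edges = sum(edges.values())
    os_bs = 100.0 * edges[OSTEOID] / bs_edges if bs_edges else 0.0
    os_len = edges[OSTEOID] * px_mm
    solid_area = a_solid * px_mm**2
    os_bv = os_len / solid_area
    if stereology:
        os_bv *= STEREOLOGY_FACTOR

    o_th: float | None = None
    if a_osteoid:
        from .microarch import local_thickness_nd

        th = local_thickness_nd(labels == OSTEOID, (px_mm, px_mm))
        o_th = float(th[labels == OSTEOID].mean()) * 1000.0
    return o_th, ov_bv, os_bs, os_bv


def measure_erosion(
    section: HistoSection2D, stereology: bool = False
) -> tuple[float, float, float]:
    """(ES/BS %, ES/BV, ES/TV): eroded boundary length over the bone
    surface, per solid area, and per total section area."""
    labels = section.labels
    a_solid = int(np.sum(labels > 0))
    if a_solid == 0:
        logger.warning("measure_erosion: no bone in section")
        return float("nan"), float("nan"), float("nan")
    px_mm = section.pixel_size_um / 1000.0
    edges = _boundary_edges_by_class(labels)
    bs_edges = sum(edges.values())
    es_bs = 100.0 * edges[ERODED] / bs_edges if bs_edges else 0.0
    es_len = edges[ERODED] * px_mm
    es_bv = es_len / (a_solid * px_mm**2)
    es_tv = es_len / (labels.size * px_mm**2)
    if stereology:
        es_bv *= STEREOLOGY_FACTOR
        es_tv *= STEREOLOGY_FACTOR
    return es_bs, es_bv, es_tv


def compute_histo_panel(
    section: HistoSection2D, stereology: bool = False
) -> HistoParams:
    """The full seven-parameter formation/resorption panel."""
    o_th, ov_bv, os_bs, os_bv = measure_osteoid(section, stereology)
    es_bs, es_bv, es_tv = measure_erosion(section, stereology)
    return HistoParams(o_th, ov_bv, os_bs, os_bv, es_bs, es_bv, es_tv,
                       stereology=stereology)


@dataclass
class VesselFieldSet:
    """Binary microvessel masks for high-power fields (default ten, 200x)."""

    fields: list
    magnification: str = "200x"

    def __post_init__(self) -> None:
        self.fields = [np.asarray(f, dtype=bool) for f in self.fields]
        if not self.fields:
            raise ValueError("at least one field is required")
        for f in self.fields:
            if f.ndim != 2:
                raise ValueError("vessel fields must be 2D")


def microvessel_density(fields: VesselFieldSet | list) -> tuple[float, list[int]]:
    """Weidner microvessel density: per-field connected-component counts
    (8-connectivity — touching endothelial clusters count once) and their
    mean across fields."""
    if not isinstance(fields, VesselFieldSet):
        fields = VesselFieldSet(fields)
    structure = np.ones((3, 3), dtype=bool)
    counts = [int(ndimage.label(f, structure=structure)[1]) for f in fields.fields]
    return float(np.mean(counts)), counts
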