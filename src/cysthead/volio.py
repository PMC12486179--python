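"""Volume I/O and the shared grid/coordinate contract.

Every image in the pipeline lives on a regular voxel grid with physical
spacing (mm per axis) and an origin (mm position of the centre of voxel
(0, 0, 0)).  Axes are ordered (x, y, z) = (mediolateral, anteroposterior,
superoinferior).  World position of index (i, j, k) is
``origin + index * spacing`` (voxel-centre convention).

Derived masks and label maps carry the grid of the volume they came from;
any grid mismatch downstream is an error, never a silent resample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "LandmarkSet",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "write_report",
    "read_cyst_csv",
]


class GridMismatchError(ValueError):
    """Two images that must share a grid (shape, spacing, origin) do not."""


@dataclass
class Volume:
    """A 3D scalar grid with physical spacing.

    ``values`` may be 8-bit grayscale (a VoxelVolume), boolean (a binary
    mask) or non-negative integer labels (0 = background); the grid
    contract is identical in all three cases.

    Parameters
    ----------
    values
        Array of shape (nx, ny, nz).
    spacing
        mm per axis; isotropic unless explicitly allowed otherwise.
    origin
        mm world position of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive on all axes, got {self.spacing}")

    # -- grid helpers ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def like(self, values: np.ndarray) -> "Volume":
        """A new Volume with these values on this grid."""
        values = np.asarray(values)
        if values.shape != self.values.shape:
            raise GridMismatchError(
                f"shape {values.shape} does not match grid {self.values.shape}"
            )
        return Volume(values, self.spacing, self.origin)

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def check_same_grid(self, other: "Volume", what: str = "operand") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what}: grid mismatch "
                f"(shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing}, "
                f"origin {self.origin} vs {other.origin}); "
                "resampling must be explicit, never silent"
            )

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World (mm) positions of index triples, shape (..., 3)."""
        return np.asarray(self.origin) + np.asarray(indices) * np.asarray(self.spacing)

    def index_grid_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates broadcastable over the grid."""
        axes = []
        for ax in range(3):
            c = self.origin[ax] + np.arange(self.shape[ax]) * self.spacing[ax]
            shape = [1, 1, 1]
            shape[ax] = -1
            axes.append(c.reshape(shape))
        return tuple(axes)  # type: ignore[return-value]


@dataclass
class LandmarkSet:
    """Anatomical landmarks defining the segmentation geometry.

    The three centres (femoral head, fovea capitis femoris, femoral neck /
    calcar) span the reference plane; ``mtd`` is the unit main-trabeculae
    direction.  ``side`` records which hip (left/right) so the anterior
    normal can be oriented consistently.
    """

    head_centre: np.ndarray
    fovea_centre: np.ndarray
    neck_centre: np.ndarray
    mtd: np.ndarray | None = None
    side: Literal["left", "right"] = "left"

    def __post_init__(self) -> None:
        self.head_centre = np.asarray(self.head_centre, dtype=float)
        self.fovea_centre = np.asarray(self.fovea_centre, dtype=float)
        self.neck_centre = np.asarray(self.neck_centre, dtype=float)
        for name in ("head_centre", "fovea_centre", "neck_centre"):
            v = getattr(self, name)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        u = self.fovea_centre - self.head_centre
        v = self.neck_centre - self.head_centre
        n = np.cross(u, v)
        if np.linalg.norm(n) <= 1e-9 * max(np.linalg.norm(u) * np.linalg.norm(v), 1e-30):
            raise ValueError(
                "landmarks are collinear: reference plane undefined"
            )
        if self.mtd is not None:
            m = np.asarray(self.mtd, dtype=float)
            norm = np.linalg.norm(m)
            if norm <= 0:
                raise ValueError("mtd must be a non-zero vector")
            self.mtd = m / norm

    @property
    def needs_mtd_estimate(self) -> bool:
        return self.mtd is None


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

Format = Literal["tiff_stack", "nifti", "metaimage"]

_SUFFIX_FORMAT: dict[str, str] = {
    ".nii": "nifti",
    ".nii.gz": "nifti",
    ".tif": "tiff_stack",
    ".tiff": "tiff_stack",
    ".mhd": "metaimage",
    ".mha": "metaimage",
}


def _sniff_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return "nifti"
    fmt = _SUFFIX_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(
            f"cannot infer volume format from {path.name!r}; pass format= explicitly"
        )
    return fmt


def _clamp_to_uint8(data: np.ndarray, path: Path) -> np.ndarray:
    if data.dtype == np.uint8:
        return data
    lo, hi = float(np.min(data)), float(np.max(data))
    if lo < 0 or hi > 255:
        logger.warning(
            "%s: intensities [%g, %g] exceed the 8-bit range; clamping to 0-255",
            path.name, lo, hi,
        )
        data = np.clip(data, 0, 255)
    return np.round(data).astype(np.uint8)


def read_volume(
    path: str | Path,
    format: Format | None = None,
    *,
    spacing: Sequence[float] | None = None,
    allow_anisotropic: bool = False,
    dtype: str = "uint8",
) -> Volume:
    """Read a volume from NIfTI, TIFF stack or MetaImage.

    Intensities are clamped to the 0-255 8-bit range with a logged warning
    when the source exceeds it (``dtype='preserve'`` keeps the raw values,
    used for label volumes).  Missing spacing metadata is an error unless an
    explicit ``spacing`` is supplied; anisotropic spacing is an error unless
    ``allow_anisotropic`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _sniff_format(path)

    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        sp = tuple(float(z) for z in zooms)
        origin = tuple(float(x) for x in img.affine[:3, 3])
    elif fmt == "tiff_stack":
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            sp_meta = _tiff_spacing(tf)
        # TIFF pages are (z, y, x); pipeline convention is (x, y, z)
        data = np.transpose(data, (2, 1, 0))
        sp = sp_meta
        origin = (0.0, 0.0, 0.0)
        if sp is None:
            if spacing is None:
                raise ValueError(
                    f"{path.name}: no voxel-spacing metadata; pass spacing= explicitly"
                )
            sp = tuple(float(s) for s in spacing)
    elif fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        sp = tuple(float(s) for s in img.GetSpacing())
        origin = tuple(float(o) for o in img.GetOrigin())
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if spacing is not None:
        sp = tuple(float(s) for s in spacing)
    if sp is None or any(s <= 0 for s in sp):
        raise ValueError(f"{path.name}: invalid or missing voxel spacing {sp}")
    if not allow_anisotropic and (max(sp) - min(sp)) > 1e-6 * max(sp):
        raise ValueError(
            f"{path.name}: anisotropic spacing {sp}; pass allow_anisotropic=True "
            "to accept it"
        )
    if dtype == "uint8":
        data = _clamp_to_uint8(data, path)
    elif dtype == "preserve":
        pass
    else:
        data = data.astype(dtype)
    return Volume(data, sp, origin)


def _tiff_spacing(tf) -> tuple[float, float, float] | None:
    """Pull isotropic spacing from ImageJ TIFF metadata if present."""
    meta = tf.imagej_metadata
    if meta and "spacing" in meta:
        z = float(meta["spacing"])
        # x/y resolution from the first page
        page = tf.pages[0]
        try:
            xres = page.tags["XResolution"].value
            xr = xres[1] / xres[0]
        except (KeyError, ZeroDivisionError):
            xr = z
        return (xr, xr, z)
    return None


def write_volume(vol: Volume, path: str | Path, format: Format | None = None) -> Path:
    """Write a volume as NIfTI (.nii/.nii.gz), TIFF stack or MetaImage."""
    path = Path(path)
    fmt = format or _sniff_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        img = nib.Nifti1Image(np.asarray(vol.values), affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
    elif fmt == "tiff_stack":
        import tifffile

        data = np.transpose(np.asarray(vol.values), (2, 1, 0))
        if data.dtype == bool:
            data = data.astype(np.uint8)
        sx = vol.spacing[0]
        tifffile.imwrite(
            str(path),
            data,
            imagej=True,
            resolution=(1.0 / sx, 1.0 / vol.spacing[1]),
            metadata={"spacing": vol.spacing[2], "unit": "mm", "axes": "ZYX"},
        )
    elif fmt == "metaimage":
        import SimpleITK as sitk

        arr = np.asarray(vol.values)
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        img = sitk.GetImageFromArray(np.transpose(arr, (2, 1, 0)))
        img.SetSpacing(vol.spacing)
        img.SetOrigin(vol.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark JSON file.

    Schema: ``{"head_centre": [x,y,z], "fovea_centre": [...],
    "neck_centre": [...], "mtd": [...] (optional), "side": "left"|"right"}``.
    ``mtd`` is normalized; if absent the set is flagged for estimation.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    missing = {"head_centre", "fovea_centre", "neck_centre"} - set(data)
    if missing:
        raise ValueError(f"{path.name}: missing landmark fields {sorted(missing)}")
    return LandmarkSet(
        head_centre=data["head_centre"],
        fovea_centre=data["fovea_centre"],
        neck_centre=data["neck_centre"],
        mtd=data.get("mtd"),
        side=data.get("side", "left"),
    )


def write_landmarks(lm: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {
        "head_centre": list(lm.head_centre),
        "fovea_centre": list(lm.fovea_centre),
        "neck_centre": list(lm.neck_centre),
        "side": lm.side,
    }
    if lm.mtd is not None:
        data["mtd"] = list(np.asarray(lm.mtd, dtype=float))
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
    return path


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

CYST_CSV_COLUMNS = [
    "id", "volume_mm3", "centroid_x_mm", "centroid_y_mm", "centroid_z_mm",
    "max_inscribed_diameter_mm", "touches_exterior", "region", "pillar",
    "hemisphere",
]


def write_report(
    records: Iterable,
    summary,
    out_dir: str | Path,
    *,
    morphometry=None,
    params: dict | None = None,
) -> dict[str, Path]:
    """Write per-cyst CSV, summary JSON and (optionally) a morphometry CSV.

    ``records`` are CystRecord-like objects; ``summary`` a CystSummary-like
    object; ``morphometry`` an optional pandas DataFrame with one row per
    cyst ROI.  Returns the paths written, keyed by artifact name.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "volume_mm3": r.volume,
            "centroid_x_mm": r.centroid[0],
            "centroid_y_mm": r.centroid[1],
            "centroid_z_mm": r.centroid[2],
            "max_inscribed_diameter_mm": r.max_inscribed_diameter,
            "touches_exterior": bool(r.touches_exterior),
            "region": r.region,
            "pillar": r.pillar,
            "hemisphere": r.hemisphere,
        })
    df = pd.DataFrame(rows, columns=CYST_CSV_COLUMNS)
    paths["cysts_csv"] = out_dir / "cysts.csv"
    df.to_csv(paths["cysts_csv"], index=False)

    summary_dict = {
        "cyst_n": summary.cyst_n,
        "cyst_v_mm3": summary.cyst_v,
        "cystv_ave_mm3": summary.cystv_ave,
        "cystv_min_mm3": summary.cystv_min,
        "cystv_max_mm3": summary.cystv_max,
    }
    if params:
        summary_dict["parameters"] = params
    paths["summary_json"] = out_dir / "summary.json"
    with open(paths["summary_json"], "w") as fh:
        json.dump(summary_dict, fh, indent=2, sort_keys=True)

    if morphometry is not None:
        paths["morphometry_csv"] = out_dir / "morphometry.csv"
        morphometry.to_csv(paths["morphometry_csv"], index=False)
    return paths


def read_cyst_csv(path: str | Path):
    """Round-trip reader for the per-cyst CSV written by :func:`write_report`."""
    import pandas as pd

    return pd.read_csv(path)
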