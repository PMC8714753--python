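"""Hernia morphometry from paired rest/Valsalva 3D segmentation label volumes.

Inputs are finished integer label volumes (the output of a segmentation step,
which is outside this package): abdominal-wall regions such as the hernia sac,
rectus muscles and the unstable zone, on a voxel grid with physical spacing in
mm.  The module measures region areas by two methods, estimates the surface
displacement between rest and strained (Valsalva) states by a closest-surface-
point approximation, and buckets displacement magnitudes into isodistance
bands for plotting.  Full non-rigid registration is deliberately not used:
the closest-point estimator is deterministic, dependency-light, and accurate
at phantom scale; the method name is recorded in every output.

Coordinate convention: voxel centers, zero origin, grid axis order (i, j, k)
scaled by ``spacing`` mm per axis.  Internal math is in mm; areas are
reported in cm² and displacement summaries in cm.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import (
    INDETERMINATE_REST_AREA_CM2,
    IndeterminateDistension,
    distension_pct,
)

__all__ = [
    "LabelVolume",
    "DisplacementMap",
    "MorphometryResult",
    "AreaMeasurement",
    "read_volume",
    "write_volume",
    "region_area",
    "displacement_field",
    "isodistance_contours",
    "percent_deviation",
    "analyze_pair",
]

MM2_PER_CM2 = 100.0
MM_PER_CM = 10.0


@dataclass
class LabelVolume:
    """A 3D integer label grid with physical spacing and region names."""

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    label_map: Dict[int, str]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError(f"label volume must be integer-valued, got {self.voxels.dtype}")
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("label volume must be a non-empty 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive mm values")
        present = set(np.unique(self.voxels).tolist())
        unknown = present - set(self.label_map) - {0}
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from label_map")

    def label_of(self, region: str) -> int:
        for lbl, name in self.label_map.items():
            if name == region:
                return lbl
        raise KeyError(f"region {region!r} not in label map {sorted(self.label_map.values())}")

    def mask(self, region: str) -> np.ndarray:
        return self.voxels == self.label_of(region)


@dataclass
class DisplacementMap:
    """Per-point displacement magnitudes (mm) on the rest-state surface."""

    points: np.ndarray  # (n, 3) mm coordinates on the rest surface
    magnitude: np.ndarray  # (n,) mm, >= 0
    method: str = "closest_surface_point"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if np.any(self.magnitude < 0) or not np.all(np.isfinite(self.magnitude)):
            raise ValueError("magnitudes must be finite and >= 0")

    @property
    def max_mm(self) -> float:
        return float(self.magnitude.max()) if self.magnitude.size else 0.0


@dataclass
class AreaMeasurement:
    """A region area in cm² with the method that produced it."""

    area_cm2: float
    method: str
    warnings: Tuple[str, ...] = ()

    def __float__(self) -> float:
        return self.area_cm2


@dataclass
class MorphometryResult:
    """Summary of one rest/Valsalva pair for one region."""

    area_rest: float  # cm²
    area_load: float  # cm²
    distension: Optional[float]  # percent; None when indeterminate
    indeterminate: bool
    max_displacement: float  # cm
    displacement_map: DisplacementMap
    method: str


# -- volume I/O --------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".labels.json")


def write_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a label volume to NIfTI (.nii/.nii.gz) or NRRD (.nrrd).

    The label map travels in a JSON sidecar ``<file>.labels.json`` (neither
    format has a portable slot for a label dictionary).
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels))
        # SimpleITK axis order is (z, y, x) relative to the numpy array
        img.SetSpacing(tuple(reversed(vol.spacing)))
        sitk.WriteImage(img, str(path))
    elif suffixes.endswith(".nii") or suffixes.endswith(".nii.gz"):
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        nib.save(nib.Nifti1Image(vol.voxels.astype(np.int16), affine), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name} (use .nii, .nii.gz, .nrrd)")
    _sidecar_path(path).write_text(
        json.dumps({str(k): v for k, v in vol.label_map.items()}, indent=1)
    )


def read_volume(path: str | Path) -> LabelVolume:
    """Read a label volume written by :func:`write_volume`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)
        spacing = tuple(reversed(img.GetSpacing()))
    elif suffixes.endswith(".nii") or suffixes.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if not np.issubdtype(data.dtype, np.integer):
        if np.allclose(data, np.round(data)):
            data = np.round(data).astype(np.int32)
        else:
            raise ValueError(f"{path.name}: label volume contains non-integer values")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        label_map = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    else:
        label_map = {int(l): f"label_{l}" for l in np.unique(data) if l != 0}
    return LabelVolume(voxels=data.astype(np.int32), spacing=spacing, label_map=label_map)


# -- measurements ------------------------------------------------------------

def _voxel_coords_mm(mask: np.ndarray, spacing: Tuple[float, float, float]) -> np.ndarray:
    return np.argwhere(mask) * np.asarray(spacing)


def _sheet_height_grid(
    mask: np.ndarray, spacing: Tuple[float, float, float]
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Rasterize a sheet-like region onto its best-fit plane.

    The voxel cloud is rotated into the plane frame (normal from PCA,
    in-plane axes snapped deterministically toward the voxel axes so that
    axis-aligned sheets rasterize without aliasing), the top height per
    in-plane pixel is taken, and small aliasing holes inside the footprint
    are filled by nearest neighbor.  Returns (heights, footprint, pixel_mm).
    """
    coords = np.argwhere(mask) * np.asarray(spacing)
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    axis = np.eye(3)[np.argmin(np.abs(normal))]
    u = np.cross(normal, axis)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    uvw = centered @ np.stack([u, v, normal]).T
    px = min(spacing)
    iu = np.floor(uvw[:, 0] / px + 0.5).astype(np.int64)
    iv = np.floor(uvw[:, 1] / px + 0.5).astype(np.int64)
    iu -= iu.min()
    iv -= iv.min()
    heights = np.full((iu.max() + 1, iv.max() + 1), -np.inf)
    np.maximum.at(heights, (iu, iv), uvw[:, 2])
    occupied = np.isfinite(heights)
    footprint = ndimage.binary_closing(occupied, structure=np.ones((3, 3)))
    holes = footprint & ~occupied
    if holes.any():
        _, (ii, jj) = ndimage.distance_transform_edt(~occupied, return_indices=True)
        heights[holes] = heights[ii[holes], jj[holes]]
    return heights, footprint, px


def _projected_plane_area(mask: np.ndarray, spacing: Tuple[float, float, float]) -> float:
    """Footprint area (mm²) of the region projected onto its best-fit plane."""
    _, footprint, px = _sheet_height_grid(mask, spacing)
    return float(footprint.sum()) * px**2


def _surface_mesh_area(mask: np.ndarray, spacing: Tuple[float, float, float]) -> float:
    """Triangulated sheet surface area (mm²) of the region's upper envelope.

    Unlike half-the-boundary of a marching-cubes mesh, the height-field
    triangulation does not inflate steeply sloped sheets with voxel
    staircase facets and carries no rim contribution from sheet thickness.
    """
    heights, footprint, px = _sheet_height_grid(mask, spacing)
    quads = (
        footprint[:-1, :-1] & footprint[1:, :-1] & footprint[:-1, 1:] & footprint[1:, 1:]
    )
    h00, h10 = heights[:-1, :-1], heights[1:, :-1]
    h01, h11 = heights[:-1, 1:], heights[1:, 1:]
    with np.errstate(invalid="ignore"):
        t1 = 0.5 * np.sqrt((px * (h01 - h00)) ** 2 + (px * (h10 - h00)) ** 2 + px**4)
        t2 = 0.5 * np.sqrt((px * (h01 - h11)) ** 2 + (px * (h10 - h11)) ** 2 + px**4)
        return float(np.nansum(np.where(quads, t1 + t2, 0.0)))


def region_area(
    vol: LabelVolume, region: str, method: str = "projected_plane"
) -> AreaMeasurement:
    """Area of a sheet-like region in cm² by one of two methods.

    ``projected_plane`` projects the region's voxel cloud onto its best-fit
    plane and counts the occupied footprint — exact for flat regions, an
    underestimate for strongly curved ones.  ``surface_mesh`` triangulates
    the sheet's upper-envelope height field over the same plane —
    appropriate for bulged (curved) regions.

    A region named in the label map but absent from the grid yields a
    zero-area result with a warning, not an error.
    """
    if method not in ("projected_plane", "surface_mesh"):
        raise ValueError(f"unknown method {method!r}")
    mask = vol.mask(region)
    if not mask.any():
        msg = f"region {region!r} has no voxels in this volume"
        _warnings.warn(msg)
        return AreaMeasurement(0.0, method, (msg,))
    if method == "projected_plane":
        area_mm2 = _projected_plane_area(mask, vol.spacing)
    else:
        area_mm2 = _surface_mesh_area(mask, vol.spacing)
    return AreaMeasurement(area_mm2 / MM2_PER_CM2, method)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    return mask & ~eroded


def displacement_field(
    rest: LabelVolume, load: LabelVolume, region: str
) -> DisplacementMap:
    """Closest-surface-point displacement of a region between two states.

    For each surface voxel of the rest-state region the magnitude is the
    distance (mm) to the nearest surface voxel of the same region in the
    load state.  Deterministic; an approximation to a true point
    correspondence that is exact for pure normal motion of a smooth surface.
    """
    if rest.voxels.shape != load.voxels.shape:
        raise ValueError("rest and load grids must have the same shape")
    if rest.spacing != load.spacing:
        raise ValueError("rest and load grids must have the same spacing")
    rest_surface = _voxel_coords_mm(_surface_voxels(rest.mask(region)), rest.spacing)
    load_surface = _voxel_coords_mm(_surface_voxels(load.mask(region)), load.spacing)
    if rest_surface.size == 0 or load_surface.size == 0:
        raise ValueError(f"region {region!r} has no surface voxels in one of the states")
    dist, _ = cKDTree(load_surface).query(rest_surface)
    return DisplacementMap(points=rest_surface, magnitude=dist)


@dataclass
class IsodistanceBand:
    """Points whose displacement magnitude falls in [lower, upper) mm."""

    lower: float
    upper: float
    points: np.ndarray
    count: int = field(init=False)

    def __post_init__(self) -> None:
        self.count = len(self.points)


def isodistance_contours(dmap: DisplacementMap, step: float) -> List[IsodistanceBand]:
    """Bucket displacement magnitudes into bands of width ``step`` mm.

    Closely spaced bands on a map indicate high displacement gradients and
    thus main stress zones.  Band count is ``ceil(max/step)`` (one band for
    an all-zero map); a magnitude exactly at the top edge joins the last band.
    """
    if step <= 0:
        raise ValueError("step must be > 0 mm")
    n_bands = max(1, int(np.ceil(dmap.max_mm / step)))
    idx = np.minimum((dmap.magnitude // step).astype(int), n_bands - 1)
    return [
        IsodistanceBand(lower=b * step, upper=(b + 1) * step, points=dmap.points[idx == b])
        for b in range(n_bands)
    ]


def percent_deviation(measured_cm2: float, reference_cm2: float) -> float:
    """Absolute percent deviation of a measured area from a reference area."""
    if reference_cm2 <= 0:
        raise ValueError("reference area must be > 0")
    return 100.0 * abs(measured_cm2 - reference_cm2) / reference_cm2


def analyze_pair(
    rest: LabelVolume,
    load: LabelVolume,
    region: str,
    method: str = "surface_mesh",
    *,
    indeterminate_below: float = INDETERMINATE_REST_AREA_CM2,
) -> MorphometryResult:
    """Full morphometry of one region: areas, distension, displacement.

    Distension of a near-zero resting orifice (below ``indeterminate_below``
    cm²) is reported as indeterminate rather than as an explosive percentage.
    """
    a_rest = region_area(rest, region, method)
    a_load = region_area(load, region, method)
    try:
        dist: Optional[float] = distension_pct(
            a_rest.area_cm2, a_load.area_cm2, indeterminate_below=indeterminate_below
        )
        indeterminate = False
    except IndeterminateDistension:
        dist = None
        indeterminate = True
    dmap = displacement_field(rest, load, region)
    return MorphometryResult(
        area_rest=a_rest.area_cm2,
        area_load=a_load.area_cm2,
        distension=dist,
        indeterminate=indeterminate,
        max_displacement=dmap.max_mm / MM_PER_CM,
        displacement_map=dmap,
        method=method,
    )
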