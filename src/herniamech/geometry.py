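"""Mesh and defect geometry: areas, overlap, mesh-defect area ratio, distension.

All areas are in cm² and mesh dimensions in cm; the minimal mesh overlap is in
mm, matching clinical usage.  Internal computation is at full precision;
reporting helpers round MDAR to one decimal and distension to whole percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .coefficients import MeshDevice

__all__ = [
    "MeshSpec",
    "DefectGeometry",
    "OverlapSpec",
    "mesh_area",
    "effective_defect_area",
    "mdar",
    "distension_pct",
    "check_overlap",
    "circular_defect",
    "MIN_OVERLAP_MM",
    "INDETERMINATE_REST_AREA_CM2",
    "IndeterminateDistension",
]

#: Empirical minimal mesh overlap beyond the unstable-area border.
MIN_OVERLAP_MM: float = 50.0

#: Resting orifice areas below this threshold make a relative distension
#: meaningless (the worked example has a rest area < 1 cm²).
INDETERMINATE_REST_AREA_CM2: float = 1.0


@dataclass(frozen=True)
class MeshSpec:
    """A planar mesh: device, shape and principal dimensions in cm.

    By convention ``width <= height``: meshes are oriented longitudinally
    along the axis of highest elasticity, so the longer principal axis is
    stored second.  For an ellipse, width and height are the full axes.
    """

    device: MeshDevice
    shape: str  # "rectangle" | "ellipse"
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "ellipse"):
            raise ValueError(f"shape must be 'rectangle' or 'ellipse', got {self.shape!r}")
        if not (self.width > 0 and self.height > 0):
            raise ValueError("mesh dimensions must be positive")
        if self.width > self.height:
            raise ValueError(
                "convention: width <= height (orient the mesh along its most elastic axis)"
            )

    @property
    def area(self) -> float:
        return mesh_area(self)


@dataclass(frozen=True)
class DefectGeometry:
    """Defect / unstable-area geometry in cm².

    The effective area to be augmented is the maximum of the resting,
    Valsalva and (when measured) intraoperative areas: the larger value is
    taken as the area of instability.
    """

    area_rest: Optional[float] = None
    area_load: Optional[float] = None
    area_intraop: Optional[float] = None

    def __post_init__(self) -> None:
        for v in (self.area_rest, self.area_load, self.area_intraop):
            if v is not None and v < 0:
                raise ValueError("areas must be >= 0")

    @property
    def equivalent_diameter(self) -> float:
        """Diameter (cm) of the circle with the effective defect area."""
        return 2.0 * math.sqrt(effective_defect_area(self) / math.pi)


@dataclass(frozen=True)
class OverlapSpec:
    """Minimal mesh overlap beyond the unstable-area border, in mm."""

    minimal_overlap: float

    def __post_init__(self) -> None:
        if self.minimal_overlap < 0:
            raise ValueError("overlap must be >= 0 mm")


class IndeterminateDistension(ValueError):
    """Distension is undefined for a (near-)zero resting orifice."""


def mesh_area(spec: MeshSpec) -> float:
    """Planar mesh area in cm²: w*h for a rectangle, (π/4)*w*h for an ellipse."""
    if spec.shape == "rectangle":
        return spec.width * spec.height
    return math.pi / 4.0 * spec.width * spec.height


def effective_defect_area(geom: DefectGeometry) -> float:
    """Largest supplied area (rest / Valsalva / intraoperative), in cm²."""
    supplied = [a for a in (geom.area_rest, geom.area_load, geom.area_intraop) if a is not None]
    if not supplied:
        raise ValueError("no defect area supplied")
    area = max(supplied)
    if area <= 0:
        raise ValueError("effective defect area must be > 0 for a plannable defect")
    return area


def mdar(mesh_area_cm2: float, defect_area_cm2: float) -> float:
    """Mesh-defect area ratio: reinforcement area over effective defect area."""
    if defect_area_cm2 <= 0:
        raise ValueError("defect area must be > 0")
    if mesh_area_cm2 < 0:
        raise ValueError("mesh area must be >= 0")
    return mesh_area_cm2 / defect_area_cm2


def distension_pct(
    area_rest: float,
    area_load: float,
    *,
    indeterminate_below: float = INDETERMINATE_REST_AREA_CM2,
) -> float:
    """Percent increase of the orifice area from rest to Valsalva.

    Raises :class:`IndeterminateDistension` when the resting area is below
    ``indeterminate_below`` (default 1 cm²): a relative measure on a
    near-zero orifice is explosive and clinically meaningless.
    """
    if area_rest < indeterminate_below:
        raise IndeterminateDistension(
            f"indeterminate (near-zero resting orifice: {area_rest} cm² "
            f"< {indeterminate_below} cm²)"
        )
    return 100.0 * (area_load - area_rest) / area_rest


def check_overlap(overlap: OverlapSpec, minimum_mm: float = MIN_OVERLAP_MM) -> str:
    """Return ``"pass"`` when the overlap reaches the minimum, else ``"warn"``."""
    return "pass" if overlap.minimal_overlap >= minimum_mm else "warn"


def circular_defect(diameter_cm: float) -> DefectGeometry:
    """Convenience constructor: a round defect of the given diameter (cm)."""
    if diameter_cm <= 0:
        raise ValueError("diameter must be > 0")
    area = math.pi * diameter_cm**2 / 4.0
    return DefectGeometry(area_rest=area)
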