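"""GRIP scoring: fixation factor, GRIP, CRIP, safety margin, option explorer.

GRIP (gained resistance to impacts related to pressure) scores a completed or
planned hernia repair's resistance to cyclic pressure loads; CRIP (critical
resistance to impacts related to pressure) is the threshold the repair must
surpass to count as durable.  The combination rule adopted here is

    GRIP = MDAR * c_mesh * c_pos * FF

with MDAR the mesh-defect area ratio, ``c_mesh`` the mesh dynamic-stiction
coefficient, ``c_pos`` the position coefficient, and FF the fixation factor
(sum of element counts weighted per unit, 0.5 per suture bite so that 100
suture points give FF = 50).  The rule is multiplicative because each
coefficient scales the retention the mesh-tissue compound can build, and it
reproduces the published worked example within rounding.  It is a named,
swappable strategy: reports record which rule produced a number.

CRIP is primarily a user-supplied input, computed preoperatively from the
individual hernia's geometry and distension by methods outside this package.
An optional single-point-calibrated model (``k * area * (1 + distension/100)``)
is provided for exploration only and is flagged as non-normative wherever it
is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from . import geometry
from .coefficients import (
    FIXATION_COEFFICIENTS,
    GLUE_SPOTS_PER_CM2,
    FixationElementType,
    lookup_position,
)
from .geometry import DefectGeometry, MeshSpec, OverlapSpec

__all__ = [
    "FixationPlan",
    "RepairPlan",
    "PlanReport",
    "CripInput",
    "fixation_factor",
    "grip",
    "resolve_crip",
    "safety_margin",
    "classify_durable",
    "evaluate_plan",
    "explore_options",
    "GRIP_RULES",
    "DEFAULT_RULE",
    "DEFAULT_CRIP_CALIBRATION",
    "DEFAULT_DISTENSION_PCT",
    "DURABILITY_THRESHOLD",
]

#: Durability requires GRIP to surpass CRIP; margin exactly at the threshold
#: counts as durable (closed boundary).
DURABILITY_THRESHOLD: float = 1.0

#: Assumed orifice distension when no Valsalva measurement exists (the
#: cohort-wide median distension).
DEFAULT_DISTENSION_PCT: float = 20.0


@dataclass(frozen=True)
class FixationPlan:
    """Fixation elements of a repair: (kind, count) pairs plus glued flat area.

    An empty plan is allowed — unsecured mesh occurs clinically (once in the
    source cohort) and yields FF = 0 with a warning rather than an error.
    """

    elements: Tuple[Tuple[str, int], ...] = ()
    glued_flat_area: float = 0.0

    def __post_init__(self) -> None:
        for kind, count in self.elements:
            FixationElementType.of(kind)  # validates kind
            if not (isinstance(count, int) and count >= 0):
                raise ValueError(f"count for {kind!r} must be a non-negative integer")
        if self.glued_flat_area < 0:
            raise ValueError("glued flat area must be >= 0 cm²")

    @classmethod
    def sutures(cls, n: int) -> "FixationPlan":
        return cls(elements=(("suture", n),))

    def __add__(self, other: "FixationPlan") -> "FixationPlan":
        return FixationPlan(
            elements=self.elements + other.elements,
            glued_flat_area=self.glued_flat_area + other.glued_flat_area,
        )


@dataclass(frozen=True)
class RepairPlan:
    """One repair design: mesh, position, fixation and defect geometry."""

    mesh: MeshSpec
    position: str
    fixation: FixationPlan
    defect: DefectGeometry
    overlap: Optional[OverlapSpec] = None

    def __post_init__(self) -> None:
        lookup_position(self.position)  # validates the code
        geometry.effective_defect_area(self.defect)  # must be > 0


@dataclass(frozen=True)
class CripInput:
    """CRIP as a direct value or as non-normative model parameters.

    Exactly one of ``value`` and the model inputs (``defect_area`` required,
    ``distension`` defaulting to the cohort median 20%) must be given.
    """

    value: Optional[float] = None
    defect_area: Optional[float] = None
    distension: Optional[float] = None
    calibration_constant: Optional[float] = None

    def __post_init__(self) -> None:
        direct = self.value is not None
        model = self.defect_area is not None
        if direct == model:
            raise ValueError("provide exactly one of: direct CRIP value, model inputs")
        if direct and not self.value > 0:
            raise ValueError("CRIP must be > 0")

    @property
    def is_model(self) -> bool:
        return self.value is None


@dataclass(frozen=True)
class PlanReport:
    """Derived quantities of one repair design."""

    mdar: float
    ff: float
    grip: float
    crip: float
    safety_margin: float
    durable: bool
    warnings: Tuple[str, ...] = ()
    rule: str = "multiplicative"
    crip_is_model: bool = False


def fixation_factor(plan: FixationPlan) -> float:
    """Sum of element counts weighted by per-unit coefficients.

    Glued flat area converts at two 8-mm spots per cm², 0.15 per spot.
    Additive over plan concatenation.
    """
    ff = sum(count * FIXATION_COEFFICIENTS[kind] for kind, count in plan.elements)
    ff += plan.glued_flat_area * GLUE_SPOTS_PER_CM2 * FIXATION_COEFFICIENTS["glue_spot"]
    return ff


def _rule_multiplicative(mdar: float, c_mesh: float, c_pos: float, ff: float) -> float:
    return mdar * c_mesh * c_pos * ff


#: Named GRIP combination rules.  ``multiplicative`` is the default; callers
#: can register alternatives without touching the scoring code.
GRIP_RULES: Dict[str, Callable[[float, float, float, float], float]] = {
    "multiplicative": _rule_multiplicative,
}
DEFAULT_RULE = "multiplicative"


def grip(plan: RepairPlan, rule: str = DEFAULT_RULE) -> float:
    """GRIP of a repair plan under the named combination rule."""
    defect_area = geometry.effective_defect_area(plan.defect)
    mdar = geometry.mdar(geometry.mesh_area(plan.mesh), defect_area)
    c_mesh = plan.mesh.device.effective_coefficient
    c_pos = lookup_position(plan.position)
    ff = fixation_factor(plan.fixation)
    return GRIP_RULES[rule](mdar, c_mesh, c_pos, ff)


def _default_crip_calibration() -> float:
    """Single-point calibration of the exploratory CRIP model.

    Anchored on the published worked example: CRIP 62 for a 94 cm² unstable
    area at the 20% default distension, giving k = 62 / (94 * 1.2).
    """
    return 62.0 / (94.0 * (1.0 + DEFAULT_DISTENSION_PCT / 100.0))


DEFAULT_CRIP_CALIBRATION: float = _default_crip_calibration()


def resolve_crip(inp: CripInput) -> float:
    """Resolve a CRIP input to a number.

    Direct values pass through.  The model form returns
    ``k * defect_area * (1 + distension/100)`` with ``k`` defaulting to the
    single-point worked-example calibration; model-derived CRIPs are flagged
    as non-normative in plan reports.
    """
    if not inp.is_model:
        return float(inp.value)
    distension = DEFAULT_DISTENSION_PCT if inp.distension is None else inp.distension
    k = DEFAULT_CRIP_CALIBRATION if inp.calibration_constant is None else inp.calibration_constant
    return k * inp.defect_area * (1.0 + distension / 100.0)


def safety_margin(grip_value: float, crip_value: float) -> float:
    """GRIP over CRIP; > 1 means the repair surpasses its critical threshold."""
    if crip_value <= 0:
        raise ValueError("CRIP must be > 0")
    if grip_value < 0:
        raise ValueError("GRIP must be >= 0")
    return grip_value / crip_value


def classify_durable(
    margin: float, threshold: float = DURABILITY_THRESHOLD
) -> bool:
    """Durable iff the safety margin reaches the threshold (closed boundary)."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    return margin >= threshold


def evaluate_plan(
    plan: RepairPlan,
    crip: CripInput,
    *,
    rule: str = DEFAULT_RULE,
    threshold: float = DURABILITY_THRESHOLD,
) -> PlanReport:
    """Full scoring of one repair plan: MDAR, FF, GRIP, margin, durability."""
    defect_area = geometry.effective_defect_area(plan.defect)
    mdar = geometry.mdar(geometry.mesh_area(plan.mesh), defect_area)
    ff = fixation_factor(plan.fixation)
    grip_value = grip(plan, rule=rule)
    crip_value = resolve_crip(crip)
    margin = safety_margin(grip_value, crip_value)
    warnings: List[str] = []
    if ff == 0:
        warnings.append("unsecured mesh: fixation factor is 0, GRIP is 0")
    if plan.overlap is not None and geometry.check_overlap(plan.overlap) == "warn":
        warnings.append(
            f"minimal overlap {plan.overlap.minimal_overlap:g} mm is below the "
            f"{geometry.MIN_OVERLAP_MM:g} mm recommendation"
        )
    if crip.is_model:
        warnings.append(
            "CRIP from the exploratory single-point-calibrated model (non-normative)"
        )
    return PlanReport(
        mdar=mdar,
        ff=ff,
        grip=grip_value,
        crip=crip_value,
        safety_margin=margin,
        durable=classify_durable(margin, threshold),
        warnings=tuple(warnings),
        rule=rule,
        crip_is_model=crip.is_model,
    )


#: Adjunct-technique tags in option exploration.  They are bookkeeping only:
#: a double peritoneal flap (DPF) gains space for mesh placement (area
#: multiplier on the available mesh area), a sandwich reconstruction (SW)
#: adds a second mesh layer's area to the MDAR numerator.  Their clinical
#: meaning is not modeled.
AREA_MODIFIERS: Dict[str, Dict[str, float]] = {
    "none": {},
    "TAR": {},  # posterior component separation: enables large meshes, no area change
    "DPF": {"mesh_area_multiplier": 1.0},
    "SW": {"mdar_add": 1.0},
}


@dataclass(frozen=True)
class RepairOption:
    """One row of the option-exploration table."""

    defect_diameter: float
    ff_label: str
    modifier: str
    mdar: float
    grip: float
    crip: float
    safety_margin: float
    durable: bool


def explore_options(
    defect_diameters: Sequence[float],
    mesh: MeshSpec,
    ff_variants: Sequence[FixationPlan],
    crip_curve: CripInput,
    modifiers: Sequence[str] = ("none",),
    *,
    position: str = "sublay_retromuscular",
    rule: str = DEFAULT_RULE,
    threshold: float = DURABILITY_THRESHOLD,
) -> List[RepairOption]:
    """Evaluate repair options over a grid of circular defect diameters.

    For each (diameter, fixation variant, modifier) combination the MDAR,
    GRIP, CRIP, safety margin and durability flag are computed, modeling the
    defect as a circle of the given diameter.  ``crip_curve`` must be the
    model form of :class:`CripInput`; its area is overridden per diameter.
    """
    if not defect_diameters or not ff_variants or not modifiers:
        raise ValueError("diameter, fixation and modifier grids must be non-empty")
    if not crip_curve.is_model:
        raise ValueError("explore_options needs a CRIP model curve, not a direct value")
    options: List[RepairOption] = []
    base_mesh_area = geometry.mesh_area(mesh)
    c_mesh = mesh.device.effective_coefficient
    c_pos = lookup_position(position)
    for modifier in modifiers:
        if modifier not in AREA_MODIFIERS:
            raise ValueError(f"unknown modifier {modifier!r}; known: {sorted(AREA_MODIFIERS)}")
        adj = AREA_MODIFIERS[modifier]
        for fp in ff_variants:
            ff = fixation_factor(fp)
            for d in defect_diameters:
                defect_area = math.pi * d**2 / 4.0
                mesh_area = base_mesh_area * adj.get("mesh_area_multiplier", 1.0)
                mdar = geometry.mdar(mesh_area, defect_area) + adj.get("mdar_add", 0.0)
                grip_value = GRIP_RULES[rule](mdar, c_mesh, c_pos, ff)
                crip_value = resolve_crip(
                    CripInput(
                        defect_area=defect_area,
                        distension=crip_curve.distension,
                        calibration_constant=crip_curve.calibration_constant,
                    )
                )
                margin = safety_margin(grip_value, crip_value)
                options.append(
                    RepairOption(
                        defect_diameter=d,
                        ff_label=f"FF{fixation_factor(fp):g}",
                        modifier=modifier,
                        mdar=mdar,
                        grip=grip_value,
                        crip=crip_value,
                        safety_margin=margin,
                        durable=classify_durable(margin, threshold),
                    )
                )
    return options
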