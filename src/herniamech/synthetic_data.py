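"""Seeded synthetic data: registry cohorts and rest/Valsalva phantom volumes.

No patient-level data from the source registry are public, so this module
generates (a) two-group cohorts with the published distributional structure
(group sizes, medians, ranges) and (b) paired abdominal-wall phantoms — a
flat sheet with a labeled orifice at rest, a spherical-cap bulge of known
height under load — with analytic ground truth for every quantity the
morphometry stage measures.

Distributional choices: sizes, times and counts are drawn log-normally
because the corresponding clinical histograms are strongly right-skewed with
extreme tails (orifice distension reaches 1800%).  Log-normal location is
set by the target median (``mu = ln(median)``) and the shape by a
method-of-moments heuristic from the printed extreme value:
``sigma = ln(max/median) / 2.6``, 2.6 being the standard-normal quantile of
the expected maximum of roughly 120 draws.  These families are stand-ins for
the unpublished empirical distributions and are labeled as such in the
generated ground-truth metadata.

Derived biomechanical fields (mesh area, MDAR, GRIP, CRIP) are computed
through the scoring pipeline from the sampled geometry — never sampled
independently — so every generated record is internally consistent, and any
GRIP-CRIP correlation arises only through the shared hernia-area draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import geometry, grip_core
from .cohort_stats import PatientRecord
from .coefficients import lookup_mesh
from .geometry import DefectGeometry, MeshSpec, OverlapSpec
from .grip_core import CripInput, FixationPlan, RepairPlan
from .morphometry import LabelVolume

__all__ = [
    "CohortConfig",
    "GroupSpec",
    "PhantomConfig",
    "generate_cohort",
    "generate_phantom_pair",
    "worked_example_fixture",
    "PHANTOM_LABELS",
]

#: Extreme-value quantile used by the sigma-from-range heuristic.
_RANGE_Z = 2.6


@dataclass(frozen=True)
class GroupSpec:
    """Per-group distribution targets (medians and printed extremes)."""

    n: int
    hernia_area_median: float  # cm²
    hernia_area_max: float
    fixation_points_median: float
    op_time_median: float  # min
    op_time_max: float
    risk_factor_mean: float
    prior_surgeries_mean: float


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults of the emulated two-group registry."""

    primary: GroupSpec = GroupSpec(
        n=119, hernia_area_median=78.0, hernia_area_max=259.0,
        fixation_points_median=42.0, op_time_median=150.0, op_time_max=480.0,
        risk_factor_mean=1.4, prior_surgeries_mean=1.9,
    )
    recurrent: GroupSpec = GroupSpec(
        n=44, hernia_area_median=161.0, hernia_area_max=412.0,
        fixation_points_median=84.0, op_time_median=228.5, op_time_max=420.0,
        risk_factor_mean=1.5, prior_surgeries_mean=2.5,
    )
    distension_median: float = 20.0  # %
    distension_max: float = 1800.0  # truncation bound (resampled, not clipped)
    distension_zero_mass: float = 0.1  # point mass at exactly 0%
    distension_missing_prob: float = 0.245  # scanned at rest only (40 of 163)
    los_median: float = 6.0  # days
    los_sigma: float = 0.45  # typical stays 3-14 d; pathological outliers not modeled
    complication_prob: float = 0.15
    nas_zero_mass: float = 0.8  # median NAS 0 in both groups
    fixation_sigma: float = 0.5
    overlap_median_mm: float = 50.0
    overlap_sigma: float = 0.3
    progrip_prob: float = 0.2  # high-grip alternative to the default Cicat mesh
    seed: int = 0

    def validate(self) -> None:
        for g in (self.primary, self.recurrent):
            if g.n < 0:
                raise ValueError("group sizes must be >= 0")
            for m in (g.hernia_area_median, g.fixation_points_median, g.op_time_median):
                if m <= 0:
                    raise ValueError("all medians must be > 0")
        for p in (self.distension_zero_mass, self.distension_missing_prob,
                  self.complication_prob, self.nas_zero_mass, self.progrip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.los_median <= 0 or self.distension_median <= 0:
            raise ValueError("all medians must be > 0")


def _sigma_from_range(median: float, maximum: float) -> float:
    return math.log(maximum / median) / _RANGE_Z


def _lognormal_median(rng: np.random.Generator, median: float, sigma: float,
                      size: Optional[int] = None):
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=size)


def _sample_distension(rng: np.random.Generator, cfg: CohortConfig) -> Optional[float]:
    if rng.random() < cfg.distension_missing_prob:
        return None
    if rng.random() < cfg.distension_zero_mass:
        return 0.0
    sigma = _sigma_from_range(cfg.distension_median, cfg.distension_max)
    while True:  # truncation by resampling, not clipping
        v = float(_lognormal_median(rng, cfg.distension_median, sigma))
        if v <= cfg.distension_max:
            return round(v, 1)


def _sample_nas(rng: np.random.Generator, cfg: CohortConfig) -> int:
    if rng.random() < cfg.nas_zero_mass:
        return 0
    return int(min(10, 1 + rng.geometric(0.5) - 1))


_ASA_PROBS = np.array([12, 65, 84, 1], dtype=float) / 162.0


def _sample_patient(rng: np.random.Generator, group: str, g: GroupSpec,
                    cfg: CohortConfig) -> PatientRecord:
    age = float(np.clip(rng.normal(63, 13), 27, 92))
    sex = "male" if rng.random() < 0.5 else "female"
    asa = int(rng.choice([1, 2, 3, 4], p=_ASA_PROBS))
    height = float(np.clip(rng.normal(171, 10), 151, 199))
    weight = float(np.clip(rng.normal(83, 19), 41, 140))
    bmi = round(weight / (height / 100.0) ** 2, 1)

    hernia_area = float(_lognormal_median(
        rng, g.hernia_area_median, _sigma_from_range(g.hernia_area_median, g.hernia_area_max)))
    distension = _sample_distension(rng, cfg)
    overlap_mm = float(_lognormal_median(rng, cfg.overlap_median_mm, cfg.overlap_sigma))
    fixation_points = max(0, int(round(_lognormal_median(
        rng, g.fixation_points_median, cfg.fixation_sigma))))

    # mesh sized from the circular-equivalent defect plus overlap on each side
    device = lookup_mesh("Progrip" if rng.random() < cfg.progrip_prob else "Dynamesh Cicat")
    defect = DefectGeometry(area_rest=hernia_area)
    d_cm = defect.equivalent_diameter
    minor = d_cm + 2.0 * overlap_mm / 10.0
    mesh = MeshSpec(device=device, shape="ellipse", width=minor, height=1.5 * minor)
    plan = RepairPlan(
        mesh=mesh,
        position="sublay_retromuscular",
        fixation=FixationPlan.sutures(fixation_points),
        defect=defect,
        overlap=OverlapSpec(minimal_overlap=overlap_mm),
    )
    crip_in = CripInput(defect_area=hernia_area, distension=distension)
    report = grip_core.evaluate_plan(plan, crip_in)

    op_time = float(_lognormal_median(
        rng, g.op_time_median, _sigma_from_range(g.op_time_median, g.op_time_max)))
    los = max(2.0, round(float(_lognormal_median(rng, cfg.los_median, cfg.los_sigma))))
    nas_rest = _sample_nas(rng, cfg)
    nas_load = min(10, nas_rest + (0 if rng.random() < cfg.nas_zero_mass else 1))

    return PatientRecord(
        group=group,
        age=round(age),
        sex=sex,
        asa=asa,
        height=round(height),
        weight=round(weight),
        bmi=bmi,
        risk_factor_count=int(rng.poisson(g.risk_factor_mean)),
        prior_surgeries=int(rng.poisson(g.prior_surgeries_mean)),
        hernia_area=round(hernia_area, 1),
        distension=distension,
        crip=round(report.crip, 1),
        mesh_area=round(geometry.mesh_area(mesh), 1),
        min_overlap=round(overlap_mm, 1),
        mdar=round(report.mdar, 1),
        fixation_points=fixation_points,
        grip=round(report.grip, 1),
        op_time=round(op_time),
        los=los,
        complication=bool(rng.random() < cfg.complication_prob),
        nas_rest=nas_rest,
        nas_load=nas_load,
        recurrence=False,  # no in-field recurrence at 1-year follow-up
    )


def generate_cohort(config: CohortConfig = CohortConfig()) -> Tuple[List[PatientRecord], Dict]:
    """Generate a two-group registry cohort plus its ground-truth metadata.

    Reproducible per seed; all records satisfy the registry invariants.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: List[PatientRecord] = []
    for group, g in (("primary", config.primary), ("recurrent", config.recurrent)):
        for _ in range(g.n):
            records.append(_sample_patient(rng, group, g, config))
    ground_truth = {
        "config": asdict(config),
        "note": (
            "log-normal stand-in distributions calibrated to printed medians "
            "and extremes; not the empirical registry distributions"
        ),
        "target_medians": {
            "hernia_area": {"primary": config.primary.hernia_area_median,
                            "recurrent": config.recurrent.hernia_area_median},
            "op_time": {"primary": config.primary.op_time_median,
                        "recurrent": config.recurrent.op_time_median},
            "fixation_points": {"primary": config.primary.fixation_points_median,
                                "recurrent": config.recurrent.fixation_points_median},
            "distension": config.distension_median,
            "los": config.los_median,
        },
    }
    return records, ground_truth


# -- phantom volumes ---------------------------------------------------------

PHANTOM_LABELS = {1: "abdominal_wall", 2: "unstable_zone"}


@dataclass(frozen=True)
class PhantomConfig:
    """A flat abdominal-wall sheet with a circular orifice that bulges under load.

    The load state replaces the flat orifice disc by a spherical-cap shell of
    the configured height; ground truth follows analytically: flat orifice
    area ``pi r^2``, cap surface area ``pi (r^2 + h^2)``, maximum surface
    displacement ``h``.
    """

    shape: Tuple[int, int, int] = (160, 160, 70)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    sheet_thickness_mm: float = 3.0
    orifice_radius_cm: float = 5.0
    bulge_height_cm: float = 4.0  # 0 for the rest state
    sheet_z0_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.orifice_radius_cm <= 0:
            raise ValueError("orifice radius must be > 0")
        if self.bulge_height_cm < 0:
            raise ValueError("bulge height must be >= 0")
        if self.sheet_thickness_mm <= 0:
            raise ValueError("sheet thickness must be > 0")

    @property
    def ground_truth(self) -> Dict[str, float]:
        r, h = self.orifice_radius_cm, self.bulge_height_cm
        flat = math.pi * r**2
        cap = math.pi * (r**2 + h**2)
        return {
            "orifice_area_rest_cm2": flat,
            "orifice_area_load_cm2": cap,
            "max_displacement_cm": h,
            "distension_pct": 100.0 * (cap - flat) / flat,
        }


def generate_phantom_pair(config: PhantomConfig = PhantomConfig()
                          ) -> Tuple[LabelVolume, LabelVolume, Dict[str, float]]:
    """Paired rest/load phantoms with the analytic ground-truth record.

    Rest: a flat sheet with the orifice disc labeled ``unstable_zone``.
    Load: the same sheet, the orifice replaced by a spherical-cap shell of
    the configured bulge height (the cap surface is offset downward by the
    sheet thickness to form the shell).  Deterministic; the seed field exists
    for config provenance only.
    """
    nx, ny, nz = config.shape
    sx, sy, sz = config.spacing
    r_mm = config.orifice_radius_cm * 10.0
    h_mm = config.bulge_height_cm * 10.0
    t = config.sheet_thickness_mm
    z0 = config.sheet_z0_mm
    if z0 + t + h_mm + 2 * sz > nz * sz:
        raise ValueError("bulge does not fit inside the grid")
    if r_mm + 2 * max(sx, sy) > min(nx * sx, ny * sy) / 2.0:
        raise ValueError("orifice does not fit inside the grid")

    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    z = np.arange(nz) * sz
    cx, cy = x[nx // 2], y[ny // 2]
    rho = np.sqrt((x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2)  # (nx, ny) mm

    in_slab = (z >= z0) & (z < z0 + t)  # (nz,)
    rest = np.zeros(config.shape, dtype=np.int16)
    rest[:, :, in_slab] = 1
    orifice = rho <= r_mm
    rest[orifice[:, :, None] & in_slab[None, None, :]] = 2

    if h_mm == 0.0:
        load = rest.copy()
    else:
        load = np.zeros(config.shape, dtype=np.int16)
        load[:, :, in_slab] = 1
        load[orifice[:, :, None] & in_slab[None, None, :]] = 0
        # spherical cap of base radius r and height h over the orifice
        radius_sphere = (r_mm**2 + h_mm**2) / (2.0 * h_mm)
        cap = np.zeros_like(rho)
        cap[orifice] = np.sqrt(
            np.maximum(radius_sphere**2 - rho[orifice] ** 2, 0.0)
        ) - (radius_sphere - h_mm)
        z_top = z0 + t + cap  # (nx, ny) top surface height, mm
        zz = z[None, None, :]
        shell = (
            orifice[:, :, None]
            & (zz < z_top[:, :, None])
            & (zz >= (z_top - t)[:, :, None])
        )
        load[shell] = 2

    rest_vol = LabelVolume(voxels=rest, spacing=config.spacing, label_map=dict(PHANTOM_LABELS))
    load_vol = LabelVolume(voxels=load, spacing=config.spacing, label_map=dict(PHANTOM_LABELS))
    return rest_vol, load_vol, config.ground_truth


# -- the published worked example -------------------------------------------

def worked_example_fixture() -> Tuple[RepairPlan, CripInput, Dict[str, float]]:
    """The published single-patient design example, for regression testing.

    A 20 x 30 cm rectangular Dynamesh Cicat mesh in sublay position over an
    unstable area measured 89 cm² at rest, 86 cm² under Valsalva and 94 cm²
    intraoperatively, fixed with 70 suture points; preoperative CRIP 62.
    Expected report values as printed: MDAR 6.4, safety margin 3.7 (printed
    GRIP 227 over CRIP 62), fixation factor 35; the adopted multiplicative
    rule reproduces the printed GRIP within 2%.
    """
    plan = RepairPlan(
        mesh=MeshSpec(device=lookup_mesh("Dynamesh Cicat"), shape="rectangle",
                      width=20.0, height=30.0),
        position="sublay_retromuscular",
        fixation=FixationPlan.sutures(70),
        defect=DefectGeometry(area_rest=89.0, area_load=86.0, area_intraop=94.0),
    )
    crip = CripInput(value=62.0)
    expected = {
        "mdar_1dp": 6.4,
        "ff": 35.0,
        "crip": 62.0,
        "grip_printed": 227.0,
        "grip_rel_tol": 0.02,
        "safety_margin_1dp": 3.7,
    }
    return plan, crip, expected
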