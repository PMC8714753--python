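import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herniamech.coefficients import MeshDevice, lookup_mesh
from herniamech.geometry import DefectGeometry, MeshSpec, OverlapSpec
from herniamech.grip_core import (
    CripInput,
    FixationPlan,
    RepairPlan,
    classify_durable,
    evaluate_plan,
    explore_options,
    fixation_factor,
    grip,
    resolve_crip,
    safety_margin,
)

CICAT = lookup_mesh("Dynamesh Cicat")


def make_plan(mesh_w=20.0, mesh_h=30.0, defect=94.0, position="sublay_retromuscular",
              sutures=70, device=CICAT):
    return RepairPlan(
        mesh=MeshSpec(device, "rectangle", mesh_w, mesh_h),
        position=position,
        fixation=FixationPlan.sutures(sutures),
        defect=DefectGeometry(area_intraop=defect),
    )


# -- fixation factor ---------------------------------------------------------

@pytest.mark.parametrize(
    "plan, expected",
    [
        (FixationPlan.sutures(100), 50.0),  # the FF50 labeling convention
        (FixationPlan.sutures(70), 35.0),
        (FixationPlan(glued_flat_area=20.0), 6.0),  # 20 cm² * 2 spots/cm² * 0.15
        (FixationPlan(), 0.0),
        (FixationPlan(elements=(("tack", 10), ("strong_tack", 4))), 5.0),
    ],
)
def test_fixation_factor_values(plan, expected):
    assert fixation_factor(plan) == pytest.approx(expected)


def test_negative_count_rejected():
    with pytest.raises(ValueError):
        FixationPlan(elements=(("suture", -1),))


@given(
    n1=st.integers(0, 200), n2=st.integers(0, 200),
    g1=st.floats(0, 50), g2=st.floats(0, 50),
)
@settings(max_examples=50, deadline=None)
def test_fixation_factor_additive_over_concatenation(n1, n2, g1, g2):
    p1 = FixationPlan(elements=(("suture", n1),), glued_flat_area=g1)
    p2 = FixationPlan(elements=(("tack", n2),), glued_flat_area=g2)
    assert fixation_factor(p1 + p2) == pytest.approx(fixation_factor(p1) + fixation_factor(p2))


# -- GRIP --------------------------------------------------------------------

def test_grip_reproduces_worked_example_within_2pct(worked_example):
    plan, _, expected = worked_example
    value = grip(plan)
    assert value == pytest.approx(600 / 94 * 1.0 * 1.0 * 35, rel=1e-9)
    assert abs(value - expected["grip_printed"]) / expected["grip_printed"] < expected["grip_rel_tol"]


def test_grip_linear_in_fixation_factor():
    base = make_plan(sutures=70)
    doubled = make_plan(sutures=140)
    assert grip(doubled) == pytest.approx(2 * grip(base))


def test_onlay_halves_grip_vs_sublay():
    assert grip(make_plan(position="onlay")) == pytest.approx(0.5 * grip(make_plan()))


def test_unsecured_mesh_scores_zero_with_warning_not_error():
    plan = make_plan(sutures=0)
    assert grip(plan) == 0.0
    report = evaluate_plan(plan, CripInput(value=62.0))
    assert report.grip == 0.0 and not report.durable
    assert any("unsecured" in w for w in report.warnings)


@given(
    scale=st.floats(min_value=1.01, max_value=3.0),
    sutures=st.integers(1, 200),
)
@settings(max_examples=40, deadline=None)
def test_grip_monotonicity(scale, sutures):
    """GRIP rises with mesh area, coefficients and fixation; falls with defect area."""
    base = make_plan(sutures=sutures)
    bigger_mesh = make_plan(mesh_w=20 * scale, mesh_h=30 * scale, sutures=sutures)
    bigger_defect = make_plan(defect=94 * scale, sutures=sutures)
    more_fix = make_plan(sutures=sutures + 1)
    stickier = make_plan(sutures=sutures, device=lookup_mesh("Progrip"))
    g = grip(base)
    assert grip(bigger_mesh) > g
    assert grip(bigger_defect) < g
    assert grip(more_fix) > g
    assert grip(stickier) > g


def test_grip_scales_linearly_with_mesh_coefficient():
    dev_half = MeshDevice("HalfStick", "B", 0.5)
    assert grip(make_plan(device=dev_half)) == pytest.approx(0.5 * grip(make_plan()))


# -- CRIP --------------------------------------------------------------------

def test_direct_crip_passes_through():
    assert resolve_crip(CripInput(value=62.0)) == 62.0


def test_model_crip_zero_distension_limit():
    assert resolve_crip(CripInput(defect_area=80.0, distension=0.0,
                                  calibration_constant=0.5)) == pytest.approx(40.0)


def test_model_crip_deterministic():
    a = CripInput(defect_area=94.0, distension=20.0)
    assert resolve_crip(a) == resolve_crip(CripInput(defect_area=94.0, distension=20.0))


def test_crip_input_requires_exactly_one_form():
    with pytest.raises(ValueError):
        CripInput(value=62.0, defect_area=94.0)
    with pytest.raises(ValueError):
        CripInput()


def test_model_crip_flagged_non_normative(worked_example):
    plan, _, _ = worked_example
    report = evaluate_plan(plan, CripInput(defect_area=94.0, distension=20.0))
    assert report.crip_is_model
    assert any("non-normative" in w for w in report.warnings)


# -- safety margin and durability -------------------------------------------

def test_printed_margin_reports_3_7():
    assert round(safety_margin(227, 62), 1) == 3.7


def test_margin_identity_and_degenerate():
    assert safety_margin(62, 62) == 1.0
    assert safety_margin(0, 62) == 0.0
    with pytest.raises(ValueError):
        safety_margin(100, 0)


@pytest.mark.parametrize(
    "margin, durable", [(3.7, True), (0.99, False), (1.0, True), (0.0, False)]
)
def test_durability_closed_boundary(margin, durable):
    assert classify_durable(margin, 1.0) is durable


# -- composition and exploration ---------------------------------------------

def test_report_fields_equal_individually_computed_operations(worked_example):
    plan, crip, _ = worked_example
    report = evaluate_plan(plan, crip)
    assert report.mdar == pytest.approx(600 / 94)
    assert report.ff == fixation_factor(plan.fixation)
    assert report.grip == pytest.approx(grip(plan))
    assert report.crip == resolve_crip(crip)
    assert report.safety_margin == pytest.approx(grip(plan) / resolve_crip(crip))
    assert report.durable == classify_durable(report.safety_margin)


def test_overlap_below_50mm_warned(worked_example):
    plan, crip, _ = worked_example
    short = RepairPlan(mesh=plan.mesh, position=plan.position, fixation=plan.fixation,
                       defect=plan.defect, overlap=OverlapSpec(minimal_overlap=40))
    report = evaluate_plan(short, crip)
    assert any("overlap" in w for w in report.warnings)


def test_explore_single_cell_matches_evaluate_plan():
    mesh = MeshSpec(CICAT, "ellipse", 30, 45)
    crip_curve = CripInput(defect_area=1.0)
    [opt] = explore_options([10.0], mesh, [FixationPlan.sutures(100)], crip_curve)
    defect = DefectGeometry(area_rest=math.pi * 25)
    plan = RepairPlan(mesh=mesh, position="sublay_retromuscular",
                      fixation=FixationPlan.sutures(100), defect=defect)
    report = evaluate_plan(plan, CripInput(defect_area=math.pi * 25))
    assert opt.mdar == pytest.approx(report.mdar)
    assert opt.grip == pytest.approx(report.grip)
    assert opt.crip == pytest.approx(report.crip)
    assert opt.durable == report.durable


def test_explore_mdar_strictly_decreasing_in_diameter():
    mesh = MeshSpec(CICAT, "ellipse", 30, 45)
    diameters = list(range(2, 31))
    opts = explore_options(diameters, mesh, [FixationPlan.sutures(100)],
                           CripInput(defect_area=1.0))
    mdars = [o.mdar for o in opts]
    assert all(a > b for a, b in zip(mdars, mdars[1:]))
    # independent arithmetic: MDAR = 1060 / (pi d^2 / 4)
    for o in opts:
        assert o.mdar == pytest.approx(
            (math.pi / 4 * 30 * 45) / (math.pi * o.defect_diameter**2 / 4))


def test_durable_boundary_diameter_non_decreasing_with_more_fixation():
    mesh = MeshSpec(CICAT, "ellipse", 30, 45)
    diameters = [float(d) for d in range(2, 31)]

    def largest_durable(sutures):
        opts = explore_options(diameters, mesh, [FixationPlan.sutures(sutures)],
                               CripInput(defect_area=1.0))
        durable = [o.defect_diameter for o in opts if o.durable]
        return max(durable) if durable else 0.0

    assert largest_durable(200) >= largest_durable(100)


def test_explore_empty_grids_rejected():
    mesh = MeshSpec(CICAT, "ellipse", 30, 45)
    with pytest.raises(ValueError):
        explore_options([], mesh, [FixationPlan.sutures(100)], CripInput(defect_area=1.0))
    with pytest.raises(ValueError):
        explore_options([10.0], mesh, [], CripInput(defect_area=1.0))


def test_explore_modifiers_are_bookkeeping():
    mesh = MeshSpec(CICAT, "ellipse", 30, 45)
    base, sw = explore_options([10.0], mesh, [FixationPlan.sutures(100)],
                               CripInput(defect_area=1.0), modifiers=["none", "SW"])
    assert sw.mdar == pytest.approx(base.mdar + 1.0)  # sandwich adds a mesh layer to MDAR
    assert sw.crip == base.crip
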