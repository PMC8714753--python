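"""Pipeline glue: configuration, plan-file loading, report rendering, provenance.

Plan configuration documents are YAML with explicit unit suffixes on every
dimensioned key (``width_cm``, ``area_rest_cm2``, ``overlap_mm``); a
dimensioned key without its unit suffix is a load error, never a guess.
Every output file embeds provenance: package version, a hash of the active
configuration, the seed, and the name of the GRIP combination rule used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import yaml

from . import __version__, cohort_stats, grip_core, morphometry
from .coefficients import CoefficientTable, builtin_table, load_table, lookup_mesh
from .geometry import DefectGeometry, MeshSpec, OverlapSpec
from .grip_core import CripInput, FixationPlan, PlanReport, RepairPlan

__all__ = [
    "PipelineConfig",
    "load_plan",
    "run_pipeline",
    "render_report",
    "render_comparisons",
    "config_hash",
]

log = logging.getLogger("herniamech")

PLAN_SCHEMA = "herniamech-plan/1"


@dataclass
class PipelineConfig:
    """Run-wide settings of the scoring pipeline."""

    coefficients_path: Optional[str] = None
    margin_threshold: float = grip_core.DURABILITY_THRESHOLD
    default_distension_pct: float = grip_core.DEFAULT_DISTENSION_PCT
    mdar_decimals: int = 1
    margin_decimals: int = 1
    output_dir: Optional[str] = None
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.default_distension_pct < 0:
            raise ValueError("default distension must be >= 0")
        if self.margin_threshold < 1.0:
            log.warning(
                "margin threshold %.2f is below 1.0: repairs not surpassing their "
                "CRIP will be classified durable", self.margin_threshold,
            )

    def table(self) -> CoefficientTable:
        if self.coefficients_path is None:
            return builtin_table()
        return load_table(self.coefficients_path)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the analysis-relevant configuration.

    Output location and log level do not influence any computed number and
    are excluded, so identical analyses hash identically wherever written.
    """
    fields = {k: v for k, v in asdict(config).items()
              if k not in ("output_dir", "log_level")}
    blob = json.dumps(fields, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _require_unit(mapping: dict, key: str, bare: str, context: str) -> float:
    if key not in mapping:
        if bare in mapping:
            raise ValueError(
                f"{context}: key {bare!r} lacks a unit suffix; use {key!r}"
            )
        raise ValueError(f"{context}: missing key {key!r}")
    return float(mapping[key])


def load_plan(path: Union[str, Path], table: Optional[CoefficientTable] = None
              ) -> Tuple[RepairPlan, CripInput]:
    """Load a repair-plan YAML document into a plan and its CRIP input."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: plan document must be a mapping")
    mesh_doc = doc.get("mesh") or {}
    device = lookup_mesh(str(mesh_doc.get("device", "")), table)
    mesh = MeshSpec(
        device=device,
        shape=str(mesh_doc.get("shape", "rectangle")),
        width=_require_unit(mesh_doc, "width_cm", "width", "mesh"),
        height=_require_unit(mesh_doc, "height_cm", "height", "mesh"),
    )
    defect_doc = doc.get("defect") or {}
    areas = {}
    for state in ("rest", "load", "intraop"):
        key, bare = f"area_{state}_cm2", f"area_{state}"
        if bare in defect_doc:
            raise ValueError(f"defect: key {bare!r} lacks a unit suffix; use {key!r}")
        if key in defect_doc:
            areas[f"area_{state}"] = float(defect_doc[key])
    defect = DefectGeometry(**areas)
    fix_doc = doc.get("fixation") or {}
    glued = float(fix_doc.pop("glued_flat_area_cm2", 0.0))
    elements = tuple((kind, int(count)) for kind, count in fix_doc.items())
    fixation = FixationPlan(elements=elements, glued_flat_area=glued)
    overlap = None
    if "overlap_mm" in doc:
        overlap = OverlapSpec(minimal_overlap=float(doc["overlap_mm"]))
    elif "overlap" in doc:
        raise ValueError("plan: key 'overlap' lacks a unit suffix; use 'overlap_mm'")
    plan = RepairPlan(
        mesh=mesh,
        position=str(doc.get("position", "sublay_retromuscular")),
        fixation=fixation,
        defect=defect,
        overlap=overlap,
    )
    crip_doc = doc.get("crip") or {}
    if "value" in crip_doc:
        crip = CripInput(value=float(crip_doc["value"]))
    else:
        crip = CripInput(
            defect_area=float(crip_doc.get("defect_area_cm2",
                                           max(v for v in areas.values()))),
            distension=crip_doc.get("distension_pct"),
            calibration_constant=crip_doc.get("calibration_constant"),
        )
    return plan, crip


def _one_liner(report: PlanReport, plan: Optional[RepairPlan] = None) -> str:
    """Clinical one-line summary in the registry's parenthetical style."""
    n_fix = sum(c for _, c in plan.fixation.elements) if plan is not None else None
    fix_part = f"{n_fix} fixation points; " if n_fix is not None else ""
    return (
        f"(CRIP: {report.crip:g}; MDAR: {report.mdar:.1f}; "
        f"{fix_part}GRIP {report.grip:.0f})"
    )


def render_report(report: PlanReport, plan: Optional[RepairPlan] = None,
                  config: Optional[PipelineConfig] = None) -> str:
    """Human-readable plan report: one-line summary plus a full table."""
    cfg = config or PipelineConfig()
    lines = [
        _one_liner(report, plan),
        "",
        f"{'MDAR':<16}{report.mdar:.{cfg.mdar_decimals}f}",
        f"{'fixation factor':<16}{report.ff:g}",
        f"{'GRIP':<16}{report.grip:.1f}  (rule: {report.rule})",
        f"{'CRIP':<16}{report.crip:.1f}"
        + ("  (exploratory model, non-normative)" if report.crip_is_model else ""),
        f"{'safety margin':<16}{report.safety_margin:.{cfg.margin_decimals}f}",
        f"{'durable':<16}{'yes' if report.durable else 'NO'}"
        f"  (threshold {cfg.margin_threshold:g}, margin at threshold counts as durable)",
    ]
    if report.warnings:
        lines.append("")
        lines.append("warnings:")
        lines.extend(f"  - {w}" for w in report.warnings)
    return "\n".join(lines) + "\n"


def render_comparisons(comparisons: Sequence[cohort_stats.GroupComparison]) -> str:
    """Delimited-text rendering of a group-comparison set."""
    header = "variable\tmedian_primary\tmedian_recurrent\tU\tp_value\tn_primary\tn_recurrent\tmethod"
    rows = [
        f"{c.variable}\t{c.median_primary:g}\t{c.median_recurrent:g}\t"
        f"{c.u_statistic:g}\t{c.p_value:.5g}\t{c.n_primary}\t{c.n_recurrent}\t{c.method}"
        for c in comparisons
    ]
    return "\n".join([header] + rows) + "\n"


def _provenance(config: PipelineConfig) -> Dict[str, Union[str, int]]:
    return {
        "tool": "herniamech",
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "grip_rule": grip_core.DEFAULT_RULE,
        "displacement_method": "closest_surface_point",
    }


def run_pipeline(
    config: PipelineConfig,
    *,
    plan_path: Optional[Union[str, Path]] = None,
    volume_paths: Optional[Tuple[Union[str, Path], Union[str, Path]]] = None,
    region: str = "unstable_zone",
    registry_path: Optional[Union[str, Path]] = None,
    compare_variables: Sequence[str] = ("hernia_area", "crip", "mesh_area", "mdar",
                                        "grip", "fixation_points", "op_time", "los",
                                        "nas_rest", "nas_load"),
) -> Dict[str, object]:
    """Run every stage for which an input was supplied; write outputs with provenance.

    Returns the report bundle as a dict; raises on the first stage error
    (callers surface a nonzero exit status).
    """
    if plan_path is None and volume_paths is None and registry_path is None:
        raise ValueError(
            "no inputs: supply a plan document, a rest/Valsalva volume pair, "
            "or a registry table (stages: plan, morph, cohort)"
        )
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    bundle: Dict[str, object] = {"provenance": _provenance(config)}

    if plan_path is not None:
        plan, crip = load_plan(plan_path, config.table())
        report = grip_core.evaluate_plan(plan, crip, threshold=config.margin_threshold)
        bundle["plan_report"] = report
        text = render_report(report, plan, config)
        if outdir:
            (outdir / "plan_report.txt").write_text(
                _provenance_header(config) + text)
    if volume_paths is not None:
        rest_path, load_path = volume_paths
        try:
            rest = morphometry.read_volume(rest_path)
            load = morphometry.read_volume(load_path)
        except Exception as exc:
            raise RuntimeError(f"volume stage failed on {rest_path} / {load_path}: {exc}") from exc
        result = morphometry.analyze_pair(rest, load, region)
        bundle["morphometry"] = result
        if outdir:
            (outdir / "morphometry.txt").write_text(
                _provenance_header(config) + _render_morphometry(result))
    if registry_path is not None:
        loaded = cohort_stats.load_registry(registry_path)
        comparisons = cohort_stats.compare_groups(loaded.records, compare_variables)
        bundle["registry"] = loaded
        bundle["comparisons"] = comparisons
        if outdir:
            (outdir / "comparisons.tsv").write_text(
                _provenance_header(config, comment="# ") + render_comparisons(comparisons))
            if len(loaded.rejects):
                loaded.rejects.to_csv(outdir / "registry_rejects.csv", index=False)
    return bundle


def _provenance_header(config: PipelineConfig, comment: str = "# ") -> str:
    prov = _provenance(config)
    return "".join(f"{comment}{k}: {v}\n" for k, v in prov.items())


def _render_morphometry(result: morphometry.MorphometryResult) -> str:
    dist = ("indeterminate (near-zero resting orifice)"
            if result.indeterminate else f"{result.distension:.0f}%")
    return (
        f"area_rest_cm2\t{result.area_rest:.1f}\n"
        f"area_load_cm2\t{result.area_load:.1f}\n"
        f"distension\t{dist}\n"
        f"max_displacement_cm\t{result.max_displacement:.1f}\n"
        f"method\t{result.method}\n"
    )
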