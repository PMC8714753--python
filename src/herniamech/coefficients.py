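"""Coefficient tables for the GRIP score: mesh, position and fixation factors.

Dynamic intermittent strain (DIS) bench testing classifies hernia meshes into
classes A/B/C and assigns each device a dimensionless dynamic-stiction
coefficient (``c_mesh``).  The mesh position relative to the abdominal-wall
muscle layers carries a second coefficient (``c_pos``), and every fixation
element type (suture bite, tack, glue spot) a per-unit coefficient.  This
module ships the seeded device table, provides case-insensitive lookup, and
lets users register additional devices without mutating the built-ins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, Optional

import yaml

__all__ = [
    "MeshDevice",
    "CoefficientTable",
    "POSITION_COEFFICIENTS",
    "FIXATION_COEFFICIENTS",
    "FixationElementType",
    "GLUE_SPOTS_PER_CM2",
    "builtin_table",
    "lookup_mesh",
    "lookup_position",
    "lookup_fixation",
    "register_mesh",
    "load_table",
    "dump_table",
    "UnknownDeviceError",
]

DIS_CLASSES = ("A", "B", "C")

#: Mesh position coefficients: onlay halves dynamic stiction relative to the
#: retromuscular sublay plane; intraperitoneal underlay (IPOM) loses 10%.
POSITION_COEFFICIENTS: Dict[str, float] = {
    "onlay": 0.5,
    "sublay_retromuscular": 1.0,
    "underlay_IPOM": 0.9,
}

#: Per-unit fixation coefficients.  Sutures are strong bonds (0.5 per bite),
#: most tacks intermediate (0.3), Securestrap-style tacks count as strong
#: (0.5), glue spots (8 mm width) are weak bonds (0.15 per spot).
FIXATION_COEFFICIENTS: Dict[str, float] = {
    "suture": 0.5,
    "tack": 0.3,
    "strong_tack": 0.5,
    "glue_spot": 0.15,
}

FIXATION_UNITS: Dict[str, str] = {
    "suture": "per bite",
    "tack": "per tack",
    "strong_tack": "per tack",
    "glue_spot": "per 8-mm spot",
}

#: Flat glued area converts at two 8-mm adhesive spots per square centimeter.
GLUE_SPOTS_PER_CM2: float = 2.0


class UnknownDeviceError(KeyError):
    """Raised when a mesh name is not in the built-in or user table."""


@dataclass(frozen=True)
class MeshDevice:
    """A hernia mesh with its DIS class and dynamic-stiction coefficient.

    ``adjustment`` is an optional multiplicative factor (default 1.0) for
    wet/dry or lubricant-dependent deviations from the bench coefficient;
    no per-device wet/dry values are tabulated, so it defaults to neutral.
    Anisotropy is recorded in ``notes`` only and never applied numerically.
    """

    name: str
    dis_class: str
    coefficient: float
    notes: str = ""
    adjustment: float = 1.0

    def __post_init__(self) -> None:
        if self.dis_class not in DIS_CLASSES:
            raise ValueError(f"dis_class must be one of {DIS_CLASSES}, got {self.dis_class!r}")
        if not self.coefficient > 0:
            raise ValueError(f"coefficient must be > 0, got {self.coefficient}")
        if not self.adjustment > 0:
            raise ValueError(f"adjustment must be > 0, got {self.adjustment}")

    @property
    def effective_coefficient(self) -> float:
        return self.coefficient * self.adjustment


@dataclass(frozen=True)
class FixationElementType:
    """A fixation element category with its per-unit coefficient."""

    kind: str
    coefficient_per_unit: float
    unit: str

    @classmethod
    def of(cls, kind: str) -> "FixationElementType":
        if kind not in FIXATION_COEFFICIENTS:
            raise KeyError(
                f"unknown fixation kind {kind!r}; known: {sorted(FIXATION_COEFFICIENTS)}"
            )
        return cls(kind, FIXATION_COEFFICIENTS[kind], FIXATION_UNITS[kind])


_TRADEMARK_RE = re.compile(r"[®™©]")


def normalize_name(name: str) -> str:
    """Normalize a device name: strip trademark glyphs, case, whitespace."""
    return _TRADEMARK_RE.sub("", name).replace(" ", "").replace("-", "").lower()


@dataclass
class CoefficientTable:
    """A mesh-device table: immutable built-ins plus user registrations."""

    builtins: Dict[str, MeshDevice] = field(default_factory=dict)
    custom: Dict[str, MeshDevice] = field(default_factory=dict)

    def lookup(self, name: str) -> MeshDevice:
        key = normalize_name(name)
        if key in self.builtins:
            return self.builtins[key]
        if key in self.custom:
            return self.custom[key]
        known = sorted(d.name for d in list(self.builtins.values()) + list(self.custom.values()))
        raise UnknownDeviceError(f"unknown device {name!r}; known devices: {known}")

    def register(self, device: MeshDevice) -> "CoefficientTable":
        """Return a new table with ``device`` added; built-ins are immutable."""
        key = normalize_name(device.name)
        if key in self.builtins or key in self.custom:
            raise ValueError(f"device {device.name!r} already present; built-ins are immutable")
        custom = dict(self.custom)
        custom[key] = device
        return CoefficientTable(builtins=self.builtins, custom=custom)

    def devices(self) -> Iterable[MeshDevice]:
        yield from self.builtins.values()
        yield from self.custom.values()


def _table_from_mapping(doc: dict) -> CoefficientTable:
    meshes = doc.get("meshes")
    if not isinstance(meshes, list):
        raise ValueError("coefficient table document must contain a 'meshes' list")
    builtins: Dict[str, MeshDevice] = {}
    for entry in meshes:
        dev = MeshDevice(
            name=str(entry["name"]),
            dis_class=str(entry["dis_class"]),
            coefficient=float(entry["coefficient"]),
            notes=str(entry.get("notes", "")),
        )
        key = normalize_name(dev.name)
        if key in builtins:
            raise ValueError(f"duplicate device name {dev.name!r} in table")
        builtins[key] = dev
    return CoefficientTable(builtins=builtins)


def load_table(path: Optional[str | Path] = None) -> CoefficientTable:
    """Load a coefficient table from YAML; default is the shipped table."""
    if path is None:
        text = resources.files("herniamech.data").joinpath("mesh_coefficients.yaml").read_text()
    else:
        text = Path(path).read_text()
    return _table_from_mapping(yaml.safe_load(text))


def dump_table(table: CoefficientTable) -> str:
    """Serialize a table to the YAML document format ``load_table`` reads."""
    doc = {
        "schema": "herniamech-mesh-table/1",
        "meshes": [
            {
                "name": d.name,
                "dis_class": d.dis_class,
                "coefficient": d.coefficient,
                "notes": d.notes,
            }
            for d in table.devices()
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


_BUILTIN: Optional[CoefficientTable] = None


def builtin_table() -> CoefficientTable:
    """The seeded table shipped with the package (cached)."""
    global _BUILTIN
    if _BUILTIN is None:
        _BUILTIN = load_table()
    return _BUILTIN


def lookup_mesh(name: str, table: Optional[CoefficientTable] = None) -> MeshDevice:
    """Look up a mesh device by (case/glyph-insensitive) name."""
    return (table or builtin_table()).lookup(name)


def lookup_position(code: str) -> float:
    """Position coefficient for a mesh plane code."""
    try:
        return POSITION_COEFFICIENTS[code]
    except KeyError:
        raise KeyError(
            f"unknown position code {code!r}; known: {sorted(POSITION_COEFFICIENTS)}"
        ) from None


def lookup_fixation(kind: str) -> float:
    """Per-unit coefficient for a fixation element kind."""
    return FixationElementType.of(kind).coefficient_per_unit


def register_mesh(
    device: MeshDevice, table: Optional[CoefficientTable] = None
) -> CoefficientTable:
    """Register a user device on a copy of ``table`` (default: built-ins)."""
    return (table or builtin_table()).register(device)
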