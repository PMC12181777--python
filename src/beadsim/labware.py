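"""Virtual deck: labware geometry, well addressing and deck occupancy.

The work surface is the 11-slot deck of a gantry-style liquid handler.
Labware (microplates, tip racks, vial racks, the camera-tool holder) is
described by small JSON definition files in the style of the Opentrons
labware-definition ecosystem; this module reads a documented subset of
that dialect plus a flat normalized form, and does the coordinate and
capacity arithmetic every other module relies on.

Coordinate conventions
----------------------
* Deck coordinates are 2-D (x, y) in millimetres.  x grows to the right
  across slot columns, y grows from the front row of slots toward the
  back.  Within a labware, well rows run along +y starting at row A.
* Slots are numbered 1-11 in the vendor's convention: a 3-wide, 4-deep
  grid with slot 1 at the front-left (slot 12 is the fixed trash and is
  not addressable).
* Each labware carries a ``height`` (mm) used only by the protocol
  engine's camera-collision rule.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

__all__ = [
    "LabwareKind",
    "LabwareDefinition",
    "WellAddress",
    "DeckLayout",
    "SchemaError",
    "GeometryError",
    "AddressError",
    "load_labware_definition",
    "save_labware_definition",
    "builtin_definition",
    "default_deck",
    "well_position",
    "condition_capacity",
    "SLOT_INDICES",
    "SLOT_FOOTPRINT",
]

# One deck slot accepts a standard SLAS footprint; anything larger cannot sit
# in a slot.
SLOT_FOOTPRINT = (128.0, 85.0)  # nominal (length/x, width/y) in mm
# Slots seat the standard SLAS footprint (127.76 x 85.48), so the fit check
# carries a 1 mm tolerance on the nominal slot size.
_FOOTPRINT_TOL = 1.0
SLOT_INDICES = tuple(range(1, 12))
# Centre-to-centre spacing of neighbouring slots (vendor grid).
_SLOT_PITCH = (132.5, 90.5)
_SLOT_COLUMNS = 3

LabwareKind = str
_KINDS = ("microplate", "tip_rack", "vial_rack", "tool_holder")


class SchemaError(ValueError):
    """A labware document is malformed; ``field`` names the culprit."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"labware field {field_name!r}: {message}")


class GeometryError(ValueError):
    """Labware geometry is inconsistent with the deck (e.g. oversized)."""


class AddressError(KeyError):
    """A well address does not exist on the labware, or a slot is empty."""


@dataclass(frozen=True)
class WellAddress:
    """A well on a rectangular labware, e.g. ``A1`` = first row, first column."""

    row: str
    col: int

    def __post_init__(self):
        if len(self.row) != 1 or self.row not in string.ascii_uppercase:
            raise AddressError(f"row must be a single letter A-Z, got {self.row!r}")
        if self.col < 1:
            raise AddressError(f"column must be >= 1, got {self.col}")

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        text = text.strip().upper()
        if len(text) < 2 or not text[0].isalpha() or not text[1:].isdigit():
            raise AddressError(f"cannot parse well address {text!r}")
        return cls(text[0], int(text[1:]))

    @property
    def row_index(self) -> int:
        """0-based row index (A -> 0)."""
        return string.ascii_uppercase.index(self.row)

    def __str__(self) -> str:
        return f"{self.row}{self.col}"


@dataclass(frozen=True)
class LabwareDefinition:
    """Geometry of one piece of labware occupying a single deck slot."""

    name: str
    kind: LabwareKind
    rows: int
    cols: int
    well_pitch: float  # mm between adjacent well centres
    a1_offset: tuple[float, float]  # (x, y) mm of well A1 from the labware corner
    well_depth: float  # mm
    well_volume: float  # µL working volume per well
    footprint: tuple[float, float] = SLOT_FOOTPRINT  # (length, width) mm
    height: float = 15.0  # overall labware height above deck, mm

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise SchemaError("kind", f"must be one of {_KINDS}, got {self.kind!r}")
        if self.rows < 1:
            raise SchemaError("rows", f"must be >= 1, got {self.rows}")
        if self.cols < 1:
            raise SchemaError("cols", f"must be >= 1, got {self.cols}")
        if self.well_pitch <= 0:
            raise SchemaError("well_pitch", "must be positive")
        length, width = self.footprint
        if (length > SLOT_FOOTPRINT[0] + _FOOTPRINT_TOL
                or width > SLOT_FOOTPRINT[1] + _FOOTPRINT_TOL):
            raise GeometryError(
                f"footprint {self.footprint} exceeds deck slot {SLOT_FOOTPRINT}"
            )

    @property
    def well_count(self) -> int:
        return self.rows * self.cols

    def contains(self, address: WellAddress) -> bool:
        return address.row_index < self.rows and 1 <= address.col <= self.cols

    def validate_address(self, address: WellAddress) -> WellAddress:
        if not self.contains(address):
            raise AddressError(
                f"address {address} out of range for {self.name} "
                f"({self.rows} rows x {self.cols} cols)"
            )
        return address

    def well_offset(self, address: WellAddress) -> tuple[float, float]:
        """(x, y) of a well centre relative to the labware corner."""
        self.validate_address(address)
        x = self.a1_offset[0] + (address.col - 1) * self.well_pitch
        y = self.a1_offset[1] + address.row_index * self.well_pitch
        return (x, y)


# ---------------------------------------------------------------------------
# JSON loading

_REQUIRED = {
    "name": str,
    "kind": str,
    "rows": int,
    "cols": int,
    "wellPitch": (int, float),
    "a1Offset": (list, tuple),
    "wellDepth": (int, float),
    "wellVolume": (int, float),
}


def _from_normalized(doc: Mapping) -> LabwareDefinition:
    for key, typ in _REQUIRED.items():
        if key not in doc:
            raise SchemaError(key, "missing")
        if not isinstance(doc[key], typ) or isinstance(doc[key], bool):
            raise SchemaError(key, f"expected {typ}, got {type(doc[key]).__name__}")
    off = doc["a1Offset"]
    if len(off) != 2:
        raise SchemaError("a1Offset", "must be a pair [x, y]")
    return LabwareDefinition(
        name=doc["name"],
        kind=doc["kind"],
        rows=doc["rows"],
        cols=doc["cols"],
        well_pitch=float(doc["wellPitch"]),
        a1_offset=(float(off[0]), float(off[1])),
        well_depth=float(doc["wellDepth"]),
        well_volume=float(doc["wellVolume"]),
        footprint=tuple(doc.get("footprint", SLOT_FOOTPRINT)),
        height=float(doc.get("height", 15.0)),
    )


_CATEGORY_TO_KIND = {
    "wellPlate": "microplate",
    "tipRack": "tip_rack",
    "tubeRack": "vial_rack",
    "reservoir": "vial_rack",
    "toolHolder": "tool_holder",
}


def _from_opentrons(doc: Mapping) -> LabwareDefinition:
    """Convert the supported subset of an Opentrons-style definition.

    Uses ``ordering`` (columns of row-major well names), the ``wells`` map for
    A1/B1/A2 coordinates, and ``dimensions`` for footprint.  The source dialect
    measures well y upward from the front-left corner (row A at the back); it
    is flipped here so that rows grow along +y from row A.
    """
    ordering = doc.get("ordering")
    wells = doc.get("wells")
    if not ordering or not isinstance(ordering, list):
        raise SchemaError("ordering", "missing or empty")
    if not isinstance(wells, Mapping) or "A1" not in wells:
        raise SchemaError("wells", "missing well map with A1")
    cols = len(ordering)
    rows = len(ordering[0])
    if any(len(c) != rows for c in ordering):
        raise SchemaError("ordering", "ragged column lengths")
    a1 = wells["A1"]
    for k in ("x", "y", "depth"):
        if k not in a1:
            raise SchemaError(f"wells.A1.{k}", "missing")
    if rows > 1:
        pitch = abs(a1["y"] - wells[ordering[0][1]]["y"])
    elif cols > 1:
        pitch = abs(wells[ordering[1][0]]["x"] - a1["x"])
    else:
        pitch = 9.0
    dims = doc.get("dimensions", {})
    length = float(dims.get("xDimension", SLOT_FOOTPRINT[0]))
    width = float(dims.get("yDimension", SLOT_FOOTPRINT[1]))
    height = float(dims.get("zDimension", 15.0))
    meta = doc.get("metadata", {})
    params = doc.get("parameters", {})
    name = params.get("loadName") or meta.get("displayName")
    if not name:
        raise SchemaError("metadata.displayName", "missing (no loadName either)")
    category = meta.get("displayCategory", "wellPlate")
    kind = _CATEGORY_TO_KIND.get(category)
    if kind is None:
        raise SchemaError("metadata.displayCategory", f"unsupported {category!r}")
    return LabwareDefinition(
        name=name,
        kind=kind,
        rows=rows,
        cols=cols,
        well_pitch=float(pitch),
        a1_offset=(float(a1["x"]), width - float(a1["y"])),
        well_depth=float(a1["depth"]),
        well_volume=float(a1.get("totalLiquidVolume", 0.0)),
        footprint=(length, width),
        height=height,
    )


def load_labware_definition(
    document: Union[str, Path, Mapping],
) -> LabwareDefinition:
    """Load a labware definition from a JSON file, JSON text, or dict.

    Accepts either the flat normalized form written by
    :func:`save_labware_definition` or the supported subset of the
    Opentrons-style dialect (``ordering``/``wells``/``dimensions``).
    Unknown extra fields are ignored.
    """
    if isinstance(document, Mapping):
        doc = document
    else:
        text = Path(document).read_text() if Path(str(document)).is_file() else str(document)
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SchemaError("<document>", f"not valid JSON: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise SchemaError("<document>", "top level must be an object")
    if "ordering" in doc or "wells" in doc:
        return _from_opentrons(doc)
    return _from_normalized(doc)


def save_labware_definition(defn: LabwareDefinition, path: Union[str, Path, None] = None) -> str:
    """Serialize to the normalized JSON form; round-trips through the loader."""
    doc = {
        "name": defn.name,
        "kind": defn.kind,
        "rows": defn.rows,
        "cols": defn.cols,
        "wellPitch": defn.well_pitch,
        "a1Offset": list(defn.a1_offset),
        "wellDepth": defn.well_depth,
        "wellVolume": defn.well_volume,
        "footprint": list(defn.footprint),
        "height": defn.height,
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def builtin_definition(name: str) -> LabwareDefinition:
    """Load one of the definitions shipped with the package.

    Available: ``plate_96_wellplate_360ul``, ``tiprack_1000ul``,
    ``tiprack_300ul``, ``vialrack_54_2ml``, ``camera_tool_holder``.
    """
    ref = resources.files("beadsim").joinpath("labware_defs", f"{name}.json")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise KeyError(f"no builtin labware definition named {name!r}") from None
    return load_labware_definition(json.loads(text))


# ---------------------------------------------------------------------------
# Deck layout

@dataclass
class DeckLayout:
    """Occupancy of the 11 deck slots (at most one labware per slot)."""

    slots: dict[int, LabwareDefinition] = field(default_factory=dict)

    def __post_init__(self):
        for idx in self.slots:
            if idx not in SLOT_INDICES:
                raise GeometryError(f"slot index {idx} outside 1-11")

    def load(self, slot: int, labware: LabwareDefinition) -> "DeckLayout":
        if slot not in SLOT_INDICES:
            raise GeometryError(f"slot index {slot} outside 1-11")
        if slot in self.slots:
            raise GeometryError(f"slot {slot} already occupied by {self.slots[slot].name}")
        self.slots[slot] = labware
        return self

    def labware_at(self, slot: int) -> Optional[LabwareDefinition]:
        return self.slots.get(slot)

    def require(self, slot: int) -> LabwareDefinition:
        lw = self.slots.get(slot)
        if lw is None:
            raise AddressError(f"slot {slot} is empty")
        return lw

    def find(self, kind: LabwareKind) -> list[int]:
        """Slot indices holding labware of the given kind, ascending."""
        return sorted(s for s, lw in self.slots.items() if lw.kind == kind)


def slot_origin(slot: int) -> tuple[float, float]:
    """Deck (x, y) of a slot's front-left corner."""
    if slot not in SLOT_INDICES:
        raise GeometryError(f"slot index {slot} outside 1-11")
    col = (slot - 1) % _SLOT_COLUMNS
    row = (slot - 1) // _SLOT_COLUMNS
    return (col * _SLOT_PITCH[0], row * _SLOT_PITCH[1])


def well_position(
    layout: DeckLayout, slot: int, address: Union[WellAddress, str]
) -> tuple[float, float]:
    """Deck (x, y) in mm of a well centre; deterministic pure arithmetic."""
    if isinstance(address, str):
        address = WellAddress.parse(address)
    labware = layout.require(slot)
    ox, oy = slot_origin(slot)
    wx, wy = labware.well_offset(address)
    return (ox + wx, oy + wy)


def condition_capacity(layout: DeckLayout) -> int:
    """Total number of screening conditions: wells over all microplates."""
    return sum(lw.well_count for lw in layout.slots.values() if lw.kind == "microplate")


def default_deck() -> DeckLayout:
    """The demo deck: plate in 1, tip racks in 8 and 9, vials in 10, tool in 11."""
    layout = DeckLayout()
    layout.load(1, builtin_definition("plate_96_wellplate_360ul"))
    layout.load(8, builtin_definition("tiprack_1000ul"))
    layout.load(9, builtin_definition("tiprack_300ul"))
    layout.load(10, builtin_definition("vialrack_54_2ml"))
    layout.load(11, builtin_definition("camera_tool_holder"))
    return layout
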