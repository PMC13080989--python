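"""CBU templates: typed, positioned fragment slots with constraints.

A template describes the shape of an organic CBU as an ordered sequence of
slots.  Terminal slots accept binding groups (and, for three-armed CBUs, a
node fragment); interior slots accept linkers at explicit sequence
positions.  Slot constraints (heavy-atom count, cyclicity, linearity) only
restrict which fragments are admissible - they never modify a fragment.

Asymmetric linkers (two inequivalent bonding sites) can be inserted in two
orientations, encoded as one bit per linker slot.  Under the symmetric
constraint, orientations of an asymmetric linker occupying more than one
position alternate along the sequence, which keeps the two coordination
environments of the CBU equivalent and is the enumeration mode used to
avoid isomer mixtures.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

from fragmops.fragment_core import Fragment

ARRANGEMENTS = ("two_linear", "two_bent", "three_planar")

#: binding-site degree implied by each arrangement
ARRANGEMENT_DEGREE = {"two_linear": 2, "two_bent": 2, "three_planar": 3}


@dataclass(frozen=True)
class Slot:
    """One fragment position in a template.

    ``constraints`` may contain ``max_atoms`` (heavy atoms), ``cyclic`` and
    ``linear`` booleans; absent keys are unconstrained.
    """

    position: int
    accepts: str  # frag_type
    constraints: dict = field(default_factory=dict)

    def admits(self, frag: Fragment) -> tuple[bool, str]:
        if frag.frag_type != self.accepts:
            return False, f"type mismatch at position {self.position}: " \
                          f"slot accepts {self.accepts}, got {frag.frag_type}"
        c = self.constraints
        if "max_atoms" in c and frag.n_heavy > c["max_atoms"]:
            return False, f"atom count {frag.n_heavy} exceeds {c['max_atoms']} " \
                          f"at position {self.position}"
        if "cyclic" in c and frag.flags["cyclic"] != c["cyclic"]:
            return False, f"cyclicity constraint violated at position {self.position}"
        if "linear" in c and frag.flags["linear"] != c["linear"]:
            return False, f"linearity constraint violated at position {self.position}"
        return True, ""


@dataclass(frozen=True)
class OrientationVector:
    """One bit per linker slot: which bonding site of the linker connects
    first when the CBU is grown from the binding group."""

    bits: tuple[int, ...]

    def __post_init__(self):
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("orientation bits must be 0 or 1")

    def __len__(self):
        return len(self.bits)

    def __iter__(self):
        return iter(self.bits)


@dataclass(frozen=True)
class CBUTemplate:
    name: str
    arrangement: str
    slots: tuple[Slot, ...]
    symmetric_required: bool = False

    def __post_init__(self):
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        object.__setattr__(self, "slots", tuple(self.slots))
        types = [s.accepts for s in self.slots]
        if self.arrangement in ("two_linear", "two_bent"):
            if types[0] != "binding_group" or types[-1] != "binding_group":
                raise ValueError("2-arm templates must terminate in binding groups")
        else:
            if types[0] != "binding_group" or types[-1] != "node":
                raise ValueError(
                    "three_planar templates run binding_group ... node"
                )
    @property
    def linker_slots(self) -> tuple[Slot, ...]:
        return tuple(s for s in self.slots if s.accepts == "linker")

    @property
    def degree(self) -> int:
        return ARRANGEMENT_DEGREE[self.arrangement]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "arrangement": self.arrangement,
            "slots": [
                {"position": s.position, "accepts": s.accepts,
                 "constraints": dict(s.constraints)}
                for s in self.slots
            ],
            "symmetric_required": self.symmetric_required,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CBUTemplate":
        return cls(
            name=d["name"],
            arrangement=d["arrangement"],
            slots=tuple(
                Slot(s["position"], s["accepts"], dict(s.get("constraints", {})))
                for s in d["slots"]
            ),
            symmetric_required=bool(d.get("symmetric_required", False)),
        )


def _two_arm(name: str, n_linkers: int, arrangement: str = "two_linear",
             constraints: dict | None = None, symmetric_required: bool = False
             ) -> CBUTemplate:
    slots = [Slot(0, "binding_group")]
    for k in range(n_linkers):
        slots.append(Slot(k + 1, "linker", dict(constraints or {})))
    slots.append(Slot(n_linkers + 1, "binding_group"))
    return CBUTemplate(name, arrangement, tuple(slots), symmetric_required)


def _three_arm(name: str, n_linkers: int, constraints: dict | None = None
               ) -> CBUTemplate:
    slots = [Slot(0, "binding_group")]
    for k in range(n_linkers):
        slots.append(Slot(k + 1, "linker", dict(constraints or {})))
    slots.append(Slot(n_linkers + 1, "node"))
    return CBUTemplate(name, "three_planar", tuple(slots))


def default_templates() -> list[CBUTemplate]:
    """Eight shipped template definitions: four 2-linear (one to three
    linker slots), two 2-bent, two 3-planar.  The slot constraints are the
    package's own approximations of common MOP linker topologies."""
    return [
        _two_arm("linear-1", 1, "two_linear"),
        _two_arm("linear-2", 2, "two_linear"),
        _two_arm("linear-3", 3, "two_linear"),
        _two_arm("linear-1-cyclic", 1, "two_linear", {"cyclic": True}),
        _two_arm("bent-1", 1, "two_bent", {"cyclic": False}),
        _two_arm("bent-2", 2, "two_bent"),
        _three_arm("planar-0", 0),
        _three_arm("planar-1", 1),
    ]


def load_templates(path) -> list[CBUTemplate]:
    data = json.loads(Path(path).read_text())
    return [CBUTemplate.from_dict(d) for d in data]


def save_templates(templates, path) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in templates], indent=2))


def validate_assignment(template: CBUTemplate, assignment: dict) -> tuple[bool, list[str]]:
    """Check a slot -> Fragment assignment against a template.

    Valid iff every slot is filled, fragment types match, all slot
    constraints hold, and exactly one binding-group species is used (no
    mixed binding groups across termini).  Returns ``(ok, reasons)``.
    """
    reasons: list[str] = []
    bg_keys = set()
    for slot in template.slots:
        frag = assignment.get(slot.position)
        if frag is None:
            reasons.append(f"position {slot.position} unfilled")
            continue
        ok, why = slot.admits(frag)
        if not ok:
            reasons.append(why)
        if slot.accepts == "binding_group" and frag.frag_type == "binding_group":
            bg_keys.add(frag.key)
    if len(bg_keys) > 1:
        reasons.append("mixed binding groups")
    return (not reasons), reasons


def expand_orientations(template: CBUTemplate, assignment: dict,
                        symmetric: bool) -> list[OrientationVector]:
    """All linker-orientation vectors to attempt for a valid assignment.

    Symmetric fragments contribute a fixed 0 bit.  Asymmetric linkers
    contribute both bits when ``symmetric`` is off.  Under the symmetric
    constraint, an asymmetric linker occupying more than one position gets
    alternating bits (bit = linker index mod 2) and exactly one vector is
    returned.
    """
    linker_slots = template.linker_slots
    if symmetric:
        occupancy: dict[str, int] = {}
        for slot in linker_slots:
            key = assignment[slot.position].key
            occupancy[key] = occupancy.get(key, 0) + 1
        bits = []
        for k, slot in enumerate(linker_slots):
            frag = assignment[slot.position]
            if frag.flags["symmetric"] or occupancy[frag.key] <= 1:
                bits.append(0)
            else:
                bits.append(k % 2)
        return [OrientationVector(tuple(bits))]
    choices = []
    for slot in linker_slots:
        frag = assignment[slot.position]
        choices.append((0,) if frag.flags["symmetric"] else (0, 1))
    return [OrientationVector(bits) for bits in itertools.product(*choices)]
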