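"""Synthesis-action vocabulary and its lossless textual serialization.

An experimental procedure is modelled as an ordered sequence of typed
actions (ADD, STIR, FILTER, ...), each carrying type-specific properties:
compound references, interval tokens for durations/temperatures/pH, a
filtration phase, and so on.  Compounds are referenced either positionally
("$2$" = second precursor, "$-1$" = first product) or by name ("ethanol").

The serialization is a flat, human-readable, machine-parseable line such as

    ADD $1$; STIR for @3@ at #4#; FILTER keep precipitate; YIELD $-1$

with one clause per action, clauses joined by "; ".  Duration, temperature
and pH properties hold either an interval-token index (rendered "@k@",
"#k#", "%k%") or a raw extracted string ("8 h", "RT") prior to
tokenization.  ``parse_action_text`` is the exact inverse of
``render_action_text`` on its image, which is what makes the text form
usable as a sequence-to-sequence target.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Union

from .errors import ActionParseError, ActionRenderError

__all__ = [
    "ACTION_TYPES",
    "Action",
    "ActionSequence",
    "CompoundRef",
    "parse_action_text",
    "render_action_text",
    "referenced_tokens",
]

# Action types with a property schema.
_CORE_TYPES = (
    "ADD",
    "COLLECTLAYER",
    "CONCENTRATE",
    "DRYSOLID",
    "DRYSOLUTION",
    "EXTRACT",
    "FILTER",
    "FOLLOWOTHERPROCEDURE",
    "INVALIDACTION",
    "MAKESOLUTION",
    "MICROWAVE",
    "NOACTION",
    "PH",
    "PURIFY",
    "QUENCH",
    "RECRYSTALLIZE",
    "REFLUX",
    "SETTEMPERATURE",
    "STIR",
    "WAIT",
    "WASH",
    "YIELD",
)

# Additional action types that occur in extraction output but carry no
# properties here; accepted so that real extracted data does not crash
# the pipeline.
_EXTRA_TYPES = ("SONICATE", "TRITURATE", "DEGAS", "PHASESEPARATION", "PARTITION")

ACTION_TYPES = frozenset(_CORE_TYPES) | frozenset(_EXTRA_TYPES)

_POSITIONAL_RE = re.compile(r"^\$(-?\d+)\$$")
_DURATION_TOKEN_RE = re.compile(r"^@(\d+)@$")
_TEMPERATURE_TOKEN_RE = re.compile(r"^#(\d+)#$")
_PH_TOKEN_RE = re.compile(r"^%(\d+)%$")

# A condition property is either an interval-token index (int) or the raw
# extracted string before tokenization.
ConditionValue = Union[int, str]


@dataclass(frozen=True)
class CompoundRef:
    """Reference to a compound, positional or by name.

    Positional index ``k`` is 1-based into the precursor list; negative
    indices count into the product list (``-1`` = first product).  Named
    references hold the compound name; multi-component names are joined
    with "/".
    """

    kind: str  # "positional" | "named"
    index: Optional[int] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "positional":
            if self.index is None or self.index == 0 or self.name is not None:
                raise ValueError("positional ref requires a nonzero index and no name")
        elif self.kind == "named":
            if not self.name or self.index is not None:
                raise ValueError("named ref requires a non-empty name and no index")
        else:
            raise ValueError(f"unknown CompoundRef kind {self.kind!r}")

    @classmethod
    def positional(cls, index: int) -> "CompoundRef":
        return cls(kind="positional", index=index)

    @classmethod
    def named(cls, name: str) -> "CompoundRef":
        return cls(kind="named", name=name)

    def render(self) -> str:
        if self.kind == "positional":
            return f"${self.index}$"
        return self.name  # type: ignore[return-value]

    @classmethod
    def parse(cls, text: str) -> "CompoundRef":
        m = _POSITIONAL_RE.match(text)
        if m:
            return cls.positional(int(m.group(1)))
        return cls.named(text)

    def to_dict(self) -> dict:
        if self.kind == "positional":
            return {"index": self.index}
        return {"name": self.name}

    @classmethod
    def from_dict(cls, d: dict) -> "CompoundRef":
        if "index" in d and d["index"] is not None:
            return cls.positional(int(d["index"]))
        return cls.named(d["name"])


@dataclass(frozen=True)
class Action:
    """One synthesis step: an action type plus admissible properties."""

    action_type: str
    compound: Optional[CompoundRef] = None
    solvent: Optional[CompoundRef] = None
    duration: Optional[ConditionValue] = None
    temperature: Optional[ConditionValue] = None
    ph: Optional[ConditionValue] = None
    phase: Optional[str] = None  # FILTER: "precipitate" | "filtrate"
    atmosphere: Optional[str] = None  # DRYSOLID: "vacuum"
    components: tuple = ()  # MAKESOLUTION
    repetitions: int = 1  # EXTRACT / WASH
    quantities: tuple = ()  # raw quantity mentions; dropped by postprocessing

    def __post_init__(self) -> None:
        if self.action_type not in ACTION_TYPES:
            raise ValueError(f"unknown action type {self.action_type!r}")
        schema = _SCHEMA[self.action_type]
        for prop in _PROPERTY_NAMES:
            if prop not in schema.allowed and _is_set(self, prop):
                raise ValueError(
                    f"property {prop!r} not admissible for {self.action_type}"
                )
        if self.phase is not None and self.phase not in ("precipitate", "filtrate"):
            raise ValueError(f"invalid filter phase {self.phase!r}")
        # atmosphere may hold any raw value pre-pipeline; postprocessing keeps
        # only "vacuum" on DRYSOLID
        if self.action_type == "MAKESOLUTION" and self.components and len(self.components) < 2:
            raise ValueError("MAKESOLUTION requires at least two components")
        if self.repetitions < 1:
            raise ValueError("repetitions must be positive")

    def replace(self, **kwargs) -> "Action":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d: dict = {"type": self.action_type}
        if self.compound is not None:
            d["compound"] = self.compound.to_dict()
        if self.solvent is not None:
            d["solvent"] = self.solvent.to_dict()
        for k in ("duration", "temperature", "ph", "phase", "atmosphere"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        if self.components:
            d["components"] = [c.to_dict() for c in self.components]
        if self.repetitions != 1:
            d["repetitions"] = self.repetitions
        if self.quantities:
            d["quantities"] = list(self.quantities)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Action":
        return cls(
            action_type=d["type"],
            compound=CompoundRef.from_dict(d["compound"]) if d.get("compound") else None,
            solvent=CompoundRef.from_dict(d["solvent"]) if d.get("solvent") else None,
            duration=d.get("duration"),
            temperature=d.get("temperature"),
            ph=d.get("ph"),
            phase=d.get("phase"),
            atmosphere=d.get("atmosphere"),
            components=tuple(CompoundRef.from_dict(c) for c in d.get("components", [])),
            repetitions=d.get("repetitions", 1),
            quantities=tuple(d.get("quantities", [])),
        )


@dataclass(frozen=True)
class ActionSequence:
    """Ordered list of actions; the unit of prediction."""

    actions: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "actions", tuple(self.actions))

    def __len__(self) -> int:
        return len(self.actions)

    def __iter__(self) -> Iterator[Action]:
        return iter(self.actions)

    def __getitem__(self, i):
        return self.actions[i]

    def to_dicts(self) -> list:
        return [a.to_dict() for a in self.actions]

    @classmethod
    def from_dicts(cls, items: list) -> "ActionSequence":
        return cls(tuple(Action.from_dict(d) for d in items))


_PROPERTY_NAMES = (
    "compound",
    "solvent",
    "duration",
    "temperature",
    "ph",
    "phase",
    "atmosphere",
    "components",
    "repetitions",
    "quantities",
)


def _is_set(action: Action, prop: str):
    v = getattr(action, prop)
    if prop == "repetitions":
        return v != 1
    if prop in ("components", "quantities"):
        return bool(v)
    return v is not None


@dataclass(frozen=True)
class _Slot:
    """One grammar slot: property name, introducing keyword (None = the
    property directly follows the action type), and rendering function."""

    prop: str
    keyword: Optional[tuple] = None  # tuple of keyword words, e.g. ("to", "pH")


@dataclass(frozen=True)
class _Schema:
    slots: tuple
    mandatory: tuple = ()

    @property
    def allowed(self) -> frozenset:
        extra = {"quantities"}  # raw records may carry quantities on any action
        if any(s.prop == "solvent" for s in self.slots):
            extra.add("repetitions")
        return frozenset(s.prop for s in self.slots) | extra


def _slots(*items) -> tuple:
    out = []
    for prop, kw in items:
        out.append(_Slot(prop, tuple(kw.split()) if kw else None))
    return tuple(out)


# Grammar: TYPE [compound] [with x] [for @d@] [at #t#] [keep phase]
#          [from solvent] [over agent] [to pH %p%] [under atmosphere]
_SCHEMA: dict = {
    "ADD": _Schema(_slots(("compound", None), ("temperature", "at")), ("compound",)),
    "MAKESOLUTION": _Schema(_slots(("components", "with")), ("components",)),
    "STIR": _Schema(_slots(("duration", "for"), ("temperature", "at"))),
    "WAIT": _Schema(_slots(("duration", "for"), ("temperature", "at"))),
    "REFLUX": _Schema(_slots(("duration", "for"))),
    "MICROWAVE": _Schema(_slots(("duration", "for"), ("temperature", "at"))),
    "SETTEMPERATURE": _Schema(_slots(("temperature", "at")), ("temperature",)),
    "FILTER": _Schema(_slots(("phase", "keep"))),
    "RECRYSTALLIZE": _Schema(_slots(("solvent", "from"))),
    "DRYSOLUTION": _Schema(_slots(("solvent", "over"))),
    "DRYSOLID": _Schema(
        _slots(("duration", "for"), ("temperature", "at"), ("atmosphere", "under"))
    ),
    "EXTRACT": _Schema(_slots(("solvent", "with"))),
    "WASH": _Schema(_slots(("solvent", "with"))),
    "QUENCH": _Schema(_slots(("compound", "with"), ("temperature", "at"))),
    "PH": _Schema(_slots(("compound", "with"), ("ph", "to pH"))),
    "YIELD": _Schema(_slots(("compound", None)), ("compound",)),
}
for _t in _CORE_TYPES + _EXTRA_TYPES:
    _SCHEMA.setdefault(_t, _Schema(()))


def _render_condition(value: ConditionValue, glyph: str) -> str:
    if isinstance(value, int):
        return f"{glyph}{value}{glyph}"
    return value


_CONDITION_GLYPH = {"duration": "@", "temperature": "#", "ph": "%"}
_CONDITION_TOKEN_RE = {
    "duration": _DURATION_TOKEN_RE,
    "temperature": _TEMPERATURE_TOKEN_RE,
    "ph": _PH_TOKEN_RE,
}


def _render_clause(action: Action, index: int) -> str:
    schema = _SCHEMA[action.action_type]
    parts = [action.action_type]
    for slot in schema.slots:
        value = getattr(action, slot.prop)
        if slot.prop in ("components",):
            if not value:
                if slot.prop in schema.mandatory:
                    raise ActionRenderError(index, f"missing {slot.prop}")
                continue
            rendered = " and ".join(c.render() for c in value)
        elif value is None:
            if slot.prop in schema.mandatory:
                raise ActionRenderError(index, f"missing {slot.prop}")
            continue
        elif slot.prop in ("compound", "solvent"):
            rendered = value.render()
        elif slot.prop in _CONDITION_GLYPH:
            rendered = _render_condition(value, _CONDITION_GLYPH[slot.prop])
        else:  # phase, atmosphere
            rendered = value
        if slot.keyword:
            parts.extend(slot.keyword)
        parts.append(rendered)
    if action.repetitions > 1:
        parts.append(f"{action.repetitions} x")
    return " ".join(parts)


def render_action_text(seq: ActionSequence) -> str:
    """Serialize an action sequence to its flat textual form."""
    return "; ".join(_render_clause(a, i) for i, a in enumerate(seq))


def _parse_condition(words: list, prop: str, clause_index: int) -> ConditionValue:
    text = " ".join(words)
    m = _CONDITION_TOKEN_RE[prop].match(text)
    if m:
        return int(m.group(1))
    return text


_REPETITION_RE = re.compile(r"^(\d+)$")


def _parse_clause(clause: str, clause_index: int) -> Action:
    words = clause.split(" ")
    if not words or not words[0]:
        raise ActionParseError(clause_index, "empty clause")
    action_type = words[0]
    if action_type not in ACTION_TYPES:
        raise ActionParseError(clause_index, f"unknown action type {action_type!r}")
    schema = _SCHEMA[action_type]
    rest = words[1:]

    repetitions = 1
    if len(rest) >= 2 and rest[-1] == "x" and _REPETITION_RE.match(rest[-2]):
        repetitions = int(rest[-2])
        rest = rest[:-2]

    props: dict = {}
    slots = list(schema.slots)
    i = 0
    for si, slot in enumerate(slots):
        if i >= len(rest):
            break
        # keyword positions of the remaining slots, used to delimit values
        later = [s.keyword for s in slots[si + 1:] if s.keyword]

        def _ends_value(j: int) -> bool:
            for kw in later:
                if tuple(rest[j:j + len(kw)]) == kw:
                    return True
            return False

        if slot.keyword is not None:
            if tuple(rest[i:i + len(slot.keyword)]) != slot.keyword:
                continue
            i += len(slot.keyword)
        j = i
        while j < len(rest) and not _ends_value(j):
            j += 1
        if j == i:
            raise ActionParseError(
                clause_index, f"empty value for {slot.prop!r} in {clause!r}"
            )
        value_words = rest[i:j]
        i = j
        if slot.prop == "components":
            comps, cur = [], []
            for w in value_words:
                if w == "and":
                    if not cur:
                        raise ActionParseError(clause_index, "empty component")
                    comps.append(CompoundRef.parse(" ".join(cur)))
                    cur = []
                else:
                    cur.append(w)
            if not cur:
                raise ActionParseError(clause_index, "empty component")
            comps.append(CompoundRef.parse(" ".join(cur)))
            if len(comps) < 2:
                raise ActionParseError(clause_index, "MAKESOLUTION needs >= 2 components")
            props["components"] = tuple(comps)
        elif slot.prop in ("compound", "solvent"):
            props[slot.prop] = CompoundRef.parse(" ".join(value_words))
        elif slot.prop in _CONDITION_GLYPH:
            props[slot.prop] = _parse_condition(value_words, slot.prop, clause_index)
        elif slot.prop == "phase":
            phase = " ".join(value_words)
            if phase not in ("precipitate", "filtrate"):
                raise ActionParseError(clause_index, f"invalid phase {phase!r}")
            props["phase"] = phase
        elif slot.prop == "atmosphere":
            props["atmosphere"] = " ".join(value_words)
    if i < len(rest):
        raise ActionParseError(
            clause_index, f"unparsed trailing words {' '.join(rest[i:])!r} in {clause!r}"
        )
    for prop in schema.mandatory:
        if prop not in props:
            raise ActionParseError(clause_index, f"missing mandatory {prop!r}")
    if repetitions != 1:
        if "solvent" not in schema.allowed:
            raise ActionParseError(clause_index, "repetitions not admissible here")
        props["repetitions"] = repetitions
    try:
        return Action(action_type=action_type, **props)
    except ValueError as exc:  # pragma: no cover - defensive
        raise ActionParseError(clause_index, str(exc))


def parse_action_text(text: str) -> ActionSequence:
    """Parse the flat textual form back into an ``ActionSequence``.

    Raises :class:`ActionParseError` on any malformed clause; a failed
    parse is never silently skipped, because parse failures feed the
    validity metric.
    """
    if text.strip() == "":
        return ActionSequence(())
    clauses = text.split("; ")
    return ActionSequence(tuple(_parse_clause(c, i) for i, c in enumerate(clauses)))


def _iter_refs(action: Action) -> Iterator[CompoundRef]:
    if action.compound is not None:
        yield action.compound
    if action.solvent is not None:
        yield action.solvent
    yield from action.components


_EMBEDDED_POSITIONAL_RE = re.compile(r"\$(-?\d+)\$")


def referenced_tokens(seq: ActionSequence) -> set:
    """Set of positional indices referenced anywhere in the sequence.

    Named references are scanned for embedded "$k$" placeholders, which
    arise for multi-component names where only some constituents map to
    equation positions.
    """
    out: set = set()
    for action in seq:
        for ref in _iter_refs(action):
            if ref.kind == "positional":
                out.add(ref.index)
            else:
                for m in _EMBEDDED_POSITIONAL_RE.finditer(ref.name or ""):
                    out.add(int(m.group(1)))
    return out
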