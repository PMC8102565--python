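"""Standardization pipeline: raw reaction records -> training pairs.

Raw records (JSONL) carry a chemical equation split into reactant /
reagent / product SMILES, an extracted action sequence with compound
names, raw condition strings and quantity mentions, a record-local
name -> SMILES map, and a language flag.  The pipeline turns each record
into a (canonical reaction SMILES, token-substituted action text) pair,
or rejects it under exactly one category of the rejection taxonomy:

* equation problems (invalid molecule / reaction SMILES, molecule on both
  sides),
* inadequate action sequences (refers to another procedure, invalid
  actions, too short, likely multiple reaction steps),
* condition strings that cannot be converted to numbers,
* names and molecules that cannot be mapped onto each other,
* duplicate reaction SMILES (one random survivor is kept).

Counts are conserved: retained + sum(rejections) == input count, always.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .actions import Action, ActionSequence, CompoundRef, render_action_text
from .compound_names import (
    NameMaps,
    StrippingRules,
    normalize_name,
    strip_name,
)
from .condition_tokens import (
    TokenTable,
    default_tables,
    parse_quantity_string,
    to_token,
)
from .errors import (
    MoleculeSmilesError,
    NameStrippingError,
    QuantityParseError,
    ReactionSmilesError,
    Smiles2ActionsError,
    TokenizationError,
)
from .reaction_smiles import (
    ReactionEquation,
    canonical_smiles,
    serialize_equation,
)

__all__ = [
    "REJECT_CATEGORIES",
    "ReactionRecord",
    "DatasetEntry",
    "DatasetStats",
    "PipelineConfig",
    "filter_record",
    "postprocess_actions",
    "tokenize_conditions",
    "substitute_compound_tokens",
    "deduplicate",
    "run_pipeline",
    "split_dataset",
    "load_records_jsonl",
    "save_dataset_jsonl",
    "load_dataset_jsonl",
]

# Rejection taxonomy in reporting/precedence order.  When several
# categories fire at the same pipeline stage, the earlier row wins.
REJECT_CATEGORIES = (
    "incomplete mapping of molecules",
    "refers to other procedure",
    "contains InvalidAction",
    "error in duration extraction",
    "likely to contain multiple reaction steps",
    "too short action sequence",
    "error in action sequence extraction",
    "error in temperature extraction",
    "molecule present both in the precursors and the products",
    "invalid molecule SMILES",
    "invalid reaction SMILES",
    "other",
    "duplicate reaction SMILES",
    "non-English",
)

_MIN_ACTIONS = 5

# Observable work-up / purification vocabulary used by the multi-step filter.
WORKUP_ACTIONS = frozenset(
    {
        "PURIFY",
        "RECRYSTALLIZE",
        "FILTER",
        "WASH",
        "EXTRACT",
        "DRYSOLUTION",
        "DRYSOLID",
        "CONCENTRATE",
        "COLLECTLAYER",
        "YIELD",
    }
)

_DURATION_CAPABLE = frozenset({"STIR", "REFLUX", "MICROWAVE", "DRYSOLID", "WAIT"})

_SAME_TEMPERATURE = frozenset({"same temperature", "the same temperature"})
_REFLUX_TEMPERATURE = frozenset({"reflux", "reflux temperature", "at reflux"})


@dataclass(frozen=True)
class ReactionRecord:
    """One raw extracted reaction record."""

    id: str
    reactants: tuple
    reagents: tuple
    products: tuple
    actions: ActionSequence
    local_name_map: dict = field(default_factory=dict)
    language: str = "en"
    extraction_error: bool = False

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "reactants": list(self.reactants),
            "reagents": list(self.reagents),
            "products": list(self.products),
            "actions": self.actions.to_dicts(),
            "name_map": dict(self.local_name_map),
            "language": self.language,
            "extraction_error": self.extraction_error,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionRecord":
        return cls(
            id=str(d["id"]),
            reactants=tuple(d.get("reactants", [])),
            reagents=tuple(d.get("reagents", [])),
            products=tuple(d.get("products", [])),
            actions=ActionSequence.from_dicts(d.get("actions", [])),
            local_name_map=dict(d.get("name_map", {})),
            language=d.get("language", "en"),
            extraction_error=bool(d.get("extraction_error", False)),
        )


@dataclass(frozen=True)
class DatasetEntry:
    """One retained training pair."""

    id: str
    reaction_smiles: str
    action_text: str


@dataclass
class DatasetStats:
    """Rejection counts per category plus the retained count."""

    input_count: int = 0
    retained: int = 0
    rejected: Dict[str, int] = field(default_factory=dict)

    def reject(self, category: str) -> None:
        if category not in REJECT_CATEGORIES:
            raise ValueError(f"unknown rejection category {category!r}")
        self.rejected[category] = self.rejected.get(category, 0) + 1

    @property
    def total_rejected(self) -> int:
        return sum(self.rejected.values())

    def check_conservation(self) -> None:
        if self.retained + self.total_rejected != self.input_count:
            raise AssertionError(
                f"count conservation violated: {self.retained} retained + "
                f"{self.total_rejected} rejected != {self.input_count} input"
            )

    def to_tsv(self) -> str:
        lines = ["Category\tNumber of reaction records"]
        for cat in REJECT_CATEGORIES:
            if cat in self.rejected:
                lines.append(f"{cat}\t{self.rejected[cat]}")
        lines.append(f"Final data set\t{self.retained}")
        lines.append(f"Total\t{self.input_count}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# equation standardization
# ---------------------------------------------------------------------------

def _standardize_equation(rec: ReactionRecord) -> ReactionEquation:
    """Canonicalize / dedup / sort both sides; raise categorized errors."""
    if not (list(rec.reactants) + list(rec.reagents)) or not list(rec.products):
        raise ReactionSmilesError("invalid reaction SMILES: empty side")
    precursors = sorted(
        {canonical_smiles(s) for s in list(rec.reactants) + list(rec.reagents)}
    )
    products = sorted({canonical_smiles(s) for s in rec.products})
    shared = set(precursors) & set(products)
    if shared:
        raise _BothSidesError(sorted(shared))
    return ReactionEquation(tuple(precursors), tuple(products))


class _BothSidesError(Smiles2ActionsError):
    def __init__(self, molecules):
        self.molecules = molecules
        super().__init__(f"molecule on both sides: {molecules}")


# ---------------------------------------------------------------------------
# action-level filtering
# ---------------------------------------------------------------------------

def _is_english(language: str) -> bool:
    return (language or "en").lower() in ("en", "eng", "english")


def filter_record(rec: ReactionRecord) -> Optional[str]:
    """Action-level filter: None to keep, else the rejection category.

    Rejects non-English records, extraction failures, sequences with
    FollowOtherProcedure or InvalidAction actions, sequences shorter than
    five actions, and sequences whose multiple Yield actions are interlaid
    with actions outside the work-up/purification vocabulary (a sign that
    the paragraph describes several reaction steps).
    """
    if not _is_english(rec.language):
        return "non-English"
    if rec.extraction_error:
        return "error in action sequence extraction"
    violations: Set[str] = set()
    types = [a.action_type for a in rec.actions]
    if "FOLLOWOTHERPROCEDURE" in types:
        violations.add("refers to other procedure")
    if "INVALIDACTION" in types:
        violations.add("contains InvalidAction")
    yields = [i for i, t in enumerate(types) if t == "YIELD"]
    if len(yields) >= 2:
        for a, b in zip(yields, yields[1:]):
            if any(t not in WORKUP_ACTIONS for t in types[a + 1 : b]):
                violations.add("likely to contain multiple reaction steps")
                break
    if len(rec.actions) < _MIN_ACTIONS:
        violations.add("too short action sequence")
    if not violations:
        return None
    return min(violations, key=REJECT_CATEGORIES.index)


# ---------------------------------------------------------------------------
# action postprocessing
# ---------------------------------------------------------------------------

class _SameTemperatureError(Smiles2ActionsError):
    """"same temperature" with no preceding explicit temperature."""


def postprocess_actions(seq: ActionSequence) -> ActionSequence:
    """Normalize an extracted action sequence.

    In order: drop NoAction; merge a Wait carrying a duration into the
    immediately preceding duration-capable action lacking one; infer the
    Filter phase from neighboring actions; resolve "same temperature"
    references; expand a leading MakeSolution into one Add per component;
    delete quantity mentions; force single repetitions on Extract/Wash;
    drop atmosphere values except vacuum on DrySolid.
    """
    actions: List[Action] = [a for a in seq if a.action_type != "NOACTION"]

    merged: List[Action] = []
    for a in actions:
        if (
            a.action_type == "WAIT"
            and a.duration is not None
            and merged
            and merged[-1].action_type in _DURATION_CAPABLE
            and merged[-1].action_type != "WAIT"
            and merged[-1].duration is None
        ):
            merged[-1] = merged[-1].replace(duration=a.duration)
        else:
            merged.append(a)
    actions = merged

    for i, a in enumerate(actions):
        if a.action_type == "FILTER" and a.phase is None:
            actions[i] = a.replace(phase=_infer_filter_phase(actions, i))

    last_temp = None
    for i, a in enumerate(actions):
        t = a.temperature
        if isinstance(t, str) and t.strip().lower() in _SAME_TEMPERATURE:
            if last_temp is None:
                raise _SameTemperatureError(f"action {i}")
            actions[i] = a.replace(temperature=last_temp)
        elif t is not None:
            last_temp = t

    if actions and actions[0].action_type == "MAKESOLUTION":
        head = actions[0]
        adds = [Action("ADD", compound=c) for c in head.components]
        actions = adds + actions[1:]

    out: List[Action] = []
    for a in actions:
        if a.quantities:
            a = a.replace(quantities=())
        if a.action_type in ("EXTRACT", "WASH") and a.repetitions != 1:
            a = a.replace(repetitions=1)
        if a.atmosphere is not None and not (
            a.action_type == "DRYSOLID" and a.atmosphere == "vacuum"
        ):
            a = a.replace(atmosphere=None)
        out.append(a)
    return ActionSequence(tuple(out))


def _infer_filter_phase(actions: Sequence[Action], i: int) -> str:
    """Heuristic phase for a Filter lacking one.

    Preceded by DrySolution or followed by Concentrate/Extract -> the
    filtrate carries the product; followed by Recrystallize/DrySolid, or
    by Yield within two actions -> the precipitate does.  Otherwise the
    filtrate (majority class).
    """
    prev_type = actions[i - 1].action_type if i > 0 else None
    next_type = actions[i + 1].action_type if i + 1 < len(actions) else None
    if prev_type == "DRYSOLUTION" or next_type in ("CONCENTRATE", "EXTRACT"):
        return "filtrate"
    if next_type in ("RECRYSTALLIZE", "DRYSOLID"):
        return "precipitate"
    within_two = [a.action_type for a in actions[i + 1 : i + 3]]
    if "YIELD" in within_two:
        return "precipitate"
    return "filtrate"


# ---------------------------------------------------------------------------
# condition tokenization
# ---------------------------------------------------------------------------

class _ConditionError(Smiles2ActionsError):
    def __init__(self, category: str, cause: Exception):
        self.category = category
        super().__init__(str(cause))


_CONDITION_CATEGORY = {
    "duration": "error in duration extraction",
    "temperature": "error in temperature extraction",
    "ph": "other",
}


def tokenize_conditions(
    seq: ActionSequence, tables: Optional[dict] = None
) -> ActionSequence:
    """Replace raw duration/temperature/pH strings with interval tokens."""
    if tables is None:
        tables = default_tables()
    out = []
    for a in seq:
        for prop in ("duration", "temperature", "ph"):
            v = getattr(a, prop)
            if not isinstance(v, str):
                continue
            if prop == "temperature" and v.strip().lower() in _REFLUX_TEMPERATURE:
                # reflux temperature is implied by the Reflux action itself
                a = a.replace(**{prop: None})
                continue
            try:
                value = parse_quantity_string(v, prop, tables)
                token = to_token(value, prop, tables)
            except (QuantityParseError, TokenizationError) as exc:
                raise _ConditionError(_CONDITION_CATEGORY[prop], exc)
            a = a.replace(**{prop: token})
        out.append(a)
    return ActionSequence(tuple(out))


# ---------------------------------------------------------------------------
# compound-name substitution
# ---------------------------------------------------------------------------

class _IncompleteMappingError(Smiles2ActionsError):
    pass


def _normalize_reagent_set(common_reagents: Iterable[str]) -> Set[str]:
    return {normalize_name(n) for n in common_reagents}


def substitute_compound_tokens(
    seq: ActionSequence,
    eq: ReactionEquation,
    maps: NameMaps,
    common_reagents: Iterable[str],
    local_name_map: Optional[Dict[str, str]] = None,
    rules: Optional[StrippingRules] = None,
) -> ActionSequence:
    """Replace compound names with positional tokens or common synonyms.

    Every named reference is stripped to root names; each root is mapped
    (record-local map first, then the global map) to a canonical SMILES.
    Roots whose molecule sits in the equation become positional tokens;
    roots absent from the equation are replaced by their most common
    synonym and kept only if on the common-reagents list.  If afterwards
    exactly one equation molecule and exactly one distinct unmapped name
    remain, they are matched to each other.  Any remaining unmapped
    molecule or name raises :class:`_IncompleteMappingError`.
    """
    reagent_norms = _normalize_reagent_set(common_reagents)
    local: Dict[str, str] = {}
    for name, smiles in (local_name_map or {}).items():
        try:
            local[normalize_name(name)] = canonical_smiles(smiles)
        except MoleculeSmilesError:
            continue

    covered: Set[int] = set()
    unmapped: Dict[str, List[Tuple[int, str, int]]] = {}
    # resolution per (action index, slot, component index): list of parts
    resolved: Dict[Tuple[int, str, int], List[object]] = {}

    def resolve_root(root: str, key: Tuple[int, str, int], parts: List[object]):
        norm = normalize_name(root)
        smiles = local.get(norm) or maps.name_to_smiles.get(norm)
        if smiles is not None:
            pos = eq.position_of(smiles)
            if pos != 0:
                covered.add(pos)
                parts.append(pos)
                return
            synonym = maps.smiles_to_name.get(smiles) or root
            if normalize_name(synonym) in reagent_norms or norm in reagent_norms:
                parts.append(synonym)
                return
            unmapped.setdefault(norm, []).append(key)
            parts.append(("?", root))
            return
        if norm in reagent_norms:
            parts.append(root)
            return
        unmapped.setdefault(norm, []).append(key)
        parts.append(("?", root))

    def iter_named_refs(action: Action, ai: int):
        if action.compound is not None and action.compound.kind == "named":
            yield (ai, "compound", 0), action.compound.name
        if action.solvent is not None and action.solvent.kind == "named":
            yield (ai, "solvent", 0), action.solvent.name
        for ci, comp in enumerate(action.components):
            if comp.kind == "named":
                yield (ai, "components", ci), comp.name

    for ai, action in enumerate(seq):
        for key, name in iter_named_refs(action, ai):
            parts: List[object] = []
            # the whole (unstripped) name may be a map key already
            whole = normalize_name(name)
            if whole in local or whole in maps.name_to_smiles:
                roots = [name]
            else:
                try:
                    roots = strip_name(name, rules)
                except NameStrippingError:
                    unmapped.setdefault(whole, []).append(key)
                    resolved[key] = [("?", name)]
                    continue
            for root in roots:
                resolve_root(root, key, parts)
            resolved[key] = parts

    # leftover matching: one unreferenced molecule + one unmapped name
    all_positions = set(range(1, eq.n_precursors + 1)) | {
        -(i + 1) for i in range(eq.n_products)
    }
    uncovered = all_positions - covered
    if len(uncovered) == 1 and len(unmapped) == 1:
        pos = next(iter(uncovered))
        norm = next(iter(unmapped))
        for parts in resolved.values():
            for i, p in enumerate(parts):
                if isinstance(p, tuple) and normalize_name(p[1]) == norm:
                    parts[i] = pos
        covered.add(pos)
        uncovered = set()
        unmapped = {}

    if unmapped or uncovered:
        raise _IncompleteMappingError(
            f"unmapped names {sorted(unmapped)}, unreferenced molecules "
            f"{sorted(uncovered)}"
        )

    def rebuild(key: Tuple[int, str, int]) -> CompoundRef:
        parts = resolved[key]
        if len(parts) == 1 and isinstance(parts[0], int):
            return CompoundRef.positional(parts[0])
        rendered = [f"${p}$" if isinstance(p, int) else str(p) for p in parts]
        return CompoundRef.named("/".join(rendered))

    out: List[Action] = []
    for ai, action in enumerate(seq):
        a = action
        if (ai, "compound", 0) in resolved:
            a = a.replace(compound=rebuild((ai, "compound", 0)))
        if (ai, "solvent", 0) in resolved:
            a = a.replace(solvent=rebuild((ai, "solvent", 0)))
        if a.components:
            comps = tuple(
                rebuild((ai, "components", ci)) if (ai, "components", ci) in resolved else c
                for ci, c in enumerate(a.components)
            )
            a = a.replace(components=comps)
        out.append(a)
    return ActionSequence(tuple(out))


# ---------------------------------------------------------------------------
# deduplication, pipeline driver, splitting
# ---------------------------------------------------------------------------

def deduplicate(
    entries: Sequence[DatasetEntry], seed: int
) -> Tuple[List[DatasetEntry], int]:
    """Keep one uniformly drawn entry per distinct reaction SMILES.

    Returns (survivors in original order, number removed).  Deterministic
    given (input order, seed).
    """
    groups: Dict[str, List[int]] = {}
    for i, e in enumerate(entries):
        groups.setdefault(e.reaction_smiles, []).append(i)
    rng = random.Random(seed)
    keep: Set[int] = set()
    for smiles in groups:  # insertion order: first occurrence
        idxs = groups[smiles]
        keep.add(idxs[rng.randrange(len(idxs))])
    survivors = [e for i, e in enumerate(entries) if i in keep]
    return survivors, len(entries) - len(survivors)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs besides the records themselves."""

    name_maps: NameMaps = field(default_factory=NameMaps)
    common_reagents: tuple = ()
    token_tables: Optional[dict] = None
    stripping_rules: Optional[StrippingRules] = None
    seed: int = 0

    def tables(self) -> dict:
        return self.token_tables if self.token_tables is not None else default_tables()


def process_record(
    rec: ReactionRecord, config: PipelineConfig
) -> Tuple[Optional[DatasetEntry], Optional[str]]:
    """Run one record through every stage; (entry, None) or (None, category)."""
    if not _is_english(rec.language):
        return None, "non-English"
    try:
        eq = _standardize_equation(rec)
    except MoleculeSmilesError:
        return None, "invalid molecule SMILES"
    except _BothSidesError:
        return None, "molecule present both in the precursors and the products"
    except ReactionSmilesError:
        return None, "invalid reaction SMILES"
    category = filter_record(rec)
    if category is not None:
        return None, category
    try:
        seq = postprocess_actions(rec.actions)
    except _SameTemperatureError:
        return None, "other"
    if len(seq) < _MIN_ACTIONS:
        # postprocessing may shorten a sequence below the cutoff
        return None, "too short action sequence"
    try:
        seq = tokenize_conditions(seq, config.tables())
    except _ConditionError as exc:
        return None, exc.category
    try:
        seq = substitute_compound_tokens(
            seq,
            eq,
            config.name_maps,
            config.common_reagents,
            local_name_map=rec.local_name_map,
            rules=config.stripping_rules,
        )
    except _IncompleteMappingError:
        return None, "incomplete mapping of molecules"
    try:
        text = render_action_text(seq)
    except Smiles2ActionsError:
        return None, "other"
    return DatasetEntry(rec.id, serialize_equation(eq), text), None


def run_pipeline(
    records: Iterable[ReactionRecord], config: PipelineConfig
) -> Tuple[List[DatasetEntry], DatasetStats]:
    """Apply filter -> postprocess -> tokenize -> substitute -> dedup.

    Never aborts the batch; every record ends up retained or counted under
    exactly one rejection category.
    """
    stats = DatasetStats()
    entries: List[DatasetEntry] = []
    for rec in records:
        stats.input_count += 1
        entry, category = process_record(rec, config)
        if entry is not None:
            entries.append(entry)
        else:
            stats.reject(category)  # type: ignore[arg-type]
    entries, n_dupes = deduplicate(entries, config.seed)
    for _ in range(n_dupes):
        stats.reject("duplicate reaction SMILES")
    stats.retained = len(entries)
    stats.check_conservation()
    return entries, stats


def split_dataset(
    dataset: Sequence[DatasetEntry],
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> Tuple[List[DatasetEntry], ...]:
    """Seeded random partition into len(fractions) disjoint exhaustive parts."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(dataset)
    order = list(range(n))
    random.Random(seed).shuffle(order)
    sizes = [int(round(n * f)) for f in fractions[:-1]]
    sizes.append(n - sum(sizes))
    if sizes[-1] < 0:
        raise ValueError("rounding produced a negative split size")
    parts: List[List[DatasetEntry]] = []
    start = 0
    for size in sizes:
        parts.append([dataset[i] for i in sorted(order[start : start + size])])
        start += size
    return tuple(parts)


# ---------------------------------------------------------------------------
# JSONL I/O
# ---------------------------------------------------------------------------

def load_records_jsonl(path: str) -> List[ReactionRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(ReactionRecord.from_dict(json.loads(line)))
    return records


def save_dataset_jsonl(dataset: Sequence[DatasetEntry], path: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for e in dataset:
            fh.write(
                json.dumps(
                    {"id": e.id, "rxn": e.reaction_smiles, "actions": e.action_text}
                )
                + "\n"
            )


def load_dataset_jsonl(path: str) -> List[DatasetEntry]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                d = json.loads(line)
                out.append(DatasetEntry(d["id"], d["rxn"], d["actions"]))
    return out
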