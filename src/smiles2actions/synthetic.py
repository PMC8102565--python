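"""Synthetic raw reaction records with known ground truth.

Patent-derived reaction corpora are proprietary, so every pipeline stage
and both predictors are exercised on generated records instead.  Each
record is built from a reaction template (a scaffold reaction with
substituent slots and a canonical action recipe) and then wrapped in the
noise the extraction process would add:

* quantity mentions on Add actions,
* compound-name variants within the OCR-confusion equivalence class of
  the name normalizer (case, spacing, l/1, O/0, dash variants),
* raw condition strings in varied spellings ("8 h", "eight hours",
  "overnight") that all fall in the same predefined interval,
* NoAction insertions,
* and, at configurable rates, planted defects mirroring the rejection
  taxonomy (FollowOtherProcedure, InvalidAction, too-short sequences,
  multi-step paragraphs, unparseable conditions, broken SMILES,
  unmappable names, duplicate reaction SMILES with divergent
  procedures, non-English records).

The ground truth emitted alongside each record holds the clean
(reaction SMILES, action text) pair and the planted defect label, so
tests can check exact recovery and exact rejection counts.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .actions import Action, ActionSequence, CompoundRef, render_action_text
from .pipeline import ReactionRecord
from .reaction_smiles import ReactionEquation, canonical_smiles, serialize_equation

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "write_records_jsonl",
    "write_truth_jsonl",
]

# ---------------------------------------------------------------------------
# reaction templates
# ---------------------------------------------------------------------------

# para/meta-substituted aryl cores; {x} receives the substituent
_RING = {"para": "c1ccc({x})cc1", "meta": "c1cccc({x})c1"}

_SUBSTS = [
    ("F", "4-fluoro"),
    ("Cl", "4-chloro"),
    ("Br", "4-bromo"),
    ("I", "4-iodo"),
    ("C", "4-methyl"),
    ("CC", "4-ethyl"),
    ("OC", "4-methoxy"),
    ("C#N", "4-cyano"),
    ("C(F)(F)F", "4-(trifluoromethyl)"),
    ("[N+](=O)[O-]", "4-nitro"),
    ("O", "4-hydroxy"),
    ("CCC", "4-propyl"),
]

# raw spellings per condition token; every spelling parses back into the
# same interval, which is what makes the noise reversible
_DURATION_SPELLINGS = {
    1: ["10 min", "15 min", "20 minutes", "ten minutes"],
    2: ["1 h", "one hour", "2 hours", "90 min", "1.5 h"],
    3: ["8 h", "8 hrs", "4 hours", "five hours", "3 h"],
    4: ["overnight", "1 day", "24 h", "36 hours", "16 h"],
    5: ["3 days", "72 h", "one week", "two days"],
}
_TEMPERATURE_SPELLINGS = {
    3: ["0 °C", "0 C", "5 °C", "ice bath", "−5 °C"],
    4: ["25 °C", "RT", "room temperature", "ambient temperature", "20 C", "77 F"],
    5: ["60 °C", "50 C", "140 F", "45 C"],
    6: ["100 °C", "90 C", "212 F", "110 °C"],
}


def _aryl(sub: str, pos: str) -> str:
    return _RING[pos].format(x=sub)


@dataclass(frozen=True)
class _Role:
    key: str
    name: str
    smiles: str
    reagent: bool = False  # listed among reagents rather than reactants


@dataclass(frozen=True)
class _Template:
    """A reaction scaffold with substituent slots and an action recipe.

    ``variants`` enumerates the full substituent space; ``build`` turns
    one variant into precursor/product roles; ``recipe`` is a list of
    action specs whose compound references name roles ("role", key),
    literal common reagents ("name", text) or the product ("product",)."""

    key: str
    variants: tuple
    build: "staticmethod"
    recipe: tuple


def _t_condensation() -> _Template:
    variants = tuple(
        (x, y, px, py)
        for x, _ in _SUBSTS
        for y, _ in _SUBSTS
        for px in ("para", "meta")
        for py in ("para", "meta")
    )

    def build(v):
        x, y, px, py = v
        lx = dict(_SUBSTS)[x]
        ly = dict(_SUBSTS)[y]
        roles = [
            _Role("dcc", "N,N'-dicyclohexylcarbodiimide",
                  "C(=NC1CCCCC1)=NC1CCCCC1", reagent=True),
            _Role("dcm", "dichloromethane", "ClCCl", reagent=True),
            _Role("acid", f"{lx}benzoic acid", f"OC(=O){_aryl(x, px)}"),
            _Role("amine", f"{ly}aniline", f"N{_aryl(y, py)}"),
        ]
        product = f"O=C(N{_aryl(y, py)}){_aryl(x, px)}"
        return roles, [product]

    recipe = (
        {"type": "ADD", "compound": ("role", "acid")},
        {"type": "ADD", "compound": ("role", "amine")},
        {"type": "ADD", "compound": ("role", "dcc")},
        {"type": "ADD", "compound": ("role", "dcm")},
        {"type": "STIR", "duration": 3, "temperature": 4},
        {"type": "FILTER", "phase": "precipitate"},
        {"type": "RECRYSTALLIZE", "solvent": ("name", "ethanol")},
        {"type": "YIELD", "compound": ("product",)},
    )
    return _Template("condensation", variants, staticmethod(build), recipe)


def _t_reductive_amination() -> _Template:
    variants = tuple(
        (x, y, k, px)
        for x, _ in _SUBSTS
        for y, _ in _SUBSTS
        for k in (1, 2, 3)
        for px in ("para", "meta")
    )

    def build(v):
        x, y, k, px = v
        lx = dict(_SUBSTS)[x]
        ly = dict(_SUBSTS)[y]
        chain = "C" * k
        amine = f"N{chain}{_aryl(y, 'para')}"
        roles = [
            _Role("acoh", "acetic acid", "CC(=O)O", reagent=True),
            _Role("aldehyde", f"{lx}benzaldehyde", f"O=C{_aryl(x, px)}"),
            _Role("etoh", "ethanol", "CCO", reagent=True),
            _Role("amine", f"{ly}phenylalkylamine", amine),
            _Role("red", "sodium cyanoborohydride", "[Na+]~[BH3-]C#N", reagent=True),
        ]
        product = f"C(N{chain}{_aryl(y, 'para')}){_aryl(x, px)}"
        return roles, [product]

    recipe = (
        {"type": "ADD", "compound": ("role", "aldehyde")},
        {"type": "ADD", "compound": ("role", "amine")},
        {"type": "ADD", "compound": ("role", "etoh")},
        {"type": "ADD", "compound": ("role", "acoh")},
        {"type": "ADD", "compound": ("role", "red")},
        {"type": "STIR", "duration": 4, "temperature": 4},
        {"type": "CONCENTRATE"},
        {"type": "PURIFY"},
        {"type": "YIELD", "compound": ("product",)},
    )
    return _Template("reductive_amination", variants, staticmethod(build), recipe)


_BASES = {
    "potassium carbonate": "O=C([O-])[O-]~[K+]~[K+]",
    "sodium carbonate": "O=C([O-])[O-]~[Na+]~[Na+]",
    "cesium carbonate": "O=C([O-])[O-]~[Cs+]~[Cs+]",
}


def _t_etherification() -> _Template:
    variants = tuple(
        (x, m, px, base)
        for x, _ in _SUBSTS
        for m in (1, 2, 3, 4, 5, 6)
        for px in ("para", "meta")
        for base in sorted(_BASES)
    )

    def build(v):
        x, m, px, base = v
        lx = dict(_SUBSTS)[x]
        chain = "C" * m
        roles = [
            _Role("phenol", f"{lx}phenol", f"O{_aryl(x, px)}"),
            _Role("base", base, _BASES[base], reagent=True),
            _Role("halide", "alkyl iodide", f"{chain}I"),
        ]
        product = f"{chain}O{_aryl(x, px)}"
        return roles, [product]

    recipe = (
        {"type": "ADD", "compound": ("role", "phenol")},
        {"type": "ADD", "compound": ("role", "base")},
        {"type": "ADD", "compound": ("role", "halide")},
        {"type": "REFLUX", "duration": 3},
        {"type": "FILTER", "phase": "filtrate"},
        {"type": "CONCENTRATE"},
        {"type": "PURIFY"},
        {"type": "YIELD", "compound": ("product",)},
    )
    return _Template("etherification", variants, staticmethod(build), recipe)


def _t_acylation() -> _Template:
    variants = tuple(
        (x, y, k, px)
        for x, _ in _SUBSTS
        for y, _ in _SUBSTS
        for k in (1, 2, 3)
        for px in ("para", "meta")
    )

    def build(v):
        x, y, k, px = v
        lx = dict(_SUBSTS)[x]
        ly = dict(_SUBSTS)[y]
        chain = "C" * k
        roles = [
            _Role("chloride", f"{lx}benzoyl chloride", f"ClC(=O){_aryl(x, px)}"),
            _Role("amine", f"{ly}benzylamine", f"N{chain}{_aryl(y, 'para')}"),
        ]
        product = f"O=C(N{chain}{_aryl(y, 'para')}){_aryl(x, px)}"
        return roles, [product]

    recipe = (
        {"type": "ADD", "compound": ("role", "chloride")},
        {"type": "ADD", "compound": ("role", "amine")},
        {"type": "STIR", "duration": 1, "temperature": 3},
        {"type": "QUENCH", "compound": ("name", "water")},
        {"type": "EXTRACT", "solvent": ("name", "ethyl acetate")},
        {"type": "WASH", "solvent": ("name", "brine")},
        {"type": "DRYSOLUTION", "solvent": ("name", "Na2SO4")},
        {"type": "FILTER", "phase": "filtrate"},
        {"type": "CONCENTRATE"},
        {"type": "YIELD", "compound": ("product",)},
    )
    return _Template("acylation", variants, staticmethod(build), recipe)


def _templates() -> List[_Template]:
    return [
        _t_condensation(),
        _t_reductive_amination(),
        _t_etherification(),
        _t_acylation(),
    ]


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

DEFECT_CATEGORIES = (
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
    "non-English",
)


@dataclass
class GeneratorConfig:
    """Study conditions for record generation.

    Noise rates reflect how frequently the corresponding artifact occurs
    in extracted patent procedures; defect rates default to zero so the
    no-noise limit is the default.
    """

    n_records: int = 1000
    seed: int = 0
    quantity_rate: float = 0.3
    name_variant_rate: float = 0.3
    noaction_rate: float = 0.1
    duplicate_rate: float = 0.0
    defect_rates: Dict[str, float] = field(default_factory=dict)
    template_weights: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        for k, v in self.defect_rates.items():
            if k not in DEFECT_CATEGORIES:
                raise ValueError(f"unknown defect category {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError("defect rates must be in [0, 1]")
        for r in (
            self.quantity_rate,
            self.name_variant_rate,
            self.noaction_rate,
            self.duplicate_rate,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("noise rates must be in [0, 1]")
        if sum(self.defect_rates.values()) + self.duplicate_rate > 1.0:
            raise ValueError("defect rates sum above 1")


@dataclass(frozen=True)
class GroundTruth:
    """Per-record ground truth: planted defect and the clean pair."""

    id: str
    template: str
    defect: Optional[str]  # None = clean record
    clean_reaction_smiles: Optional[str]
    clean_action_text: Optional[str]

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "template": self.template,
            "defect": self.defect,
            "clean_rxn": self.clean_reaction_smiles,
            "clean_actions": self.clean_action_text,
        }


# ---------------------------------------------------------------------------
# name corruption within the normalizer's equivalence class
# ---------------------------------------------------------------------------

def _corrupt_name(name: str, rng: random.Random) -> str:
    ops = []
    if any(c.islower() for c in name):
        ops.append("case")
    if "l" in name:
        ops.append("l_to_1")
    if "o" in name:
        ops.append("o_to_0")
    if "-" in name:
        ops.append("dash")
    if " " not in name and len(name) > 4:
        ops.append("space")
    if not ops:
        return name
    op = rng.choice(ops)
    if op == "case":
        # uppercasing "i" would leave the OCR-confusion equivalence class
        # (uppercase I normalizes to l, lowercase i does not)
        return "".join(c if c == "i" else c.upper() for c in name)
    if op == "l_to_1":
        i = name.index("l")
        return name[:i] + "1" + name[i + 1 :]
    if op == "o_to_0":
        i = name.index("o")
        return name[:i] + "0" + name[i + 1 :]
    if op == "dash":
        return name.replace("-", "–", 1)
    i = rng.randrange(1, len(name))
    return name[:i] + " " + name[i:]


# ---------------------------------------------------------------------------
# record assembly
# ---------------------------------------------------------------------------

def _clean_pair(
    roles: Sequence[_Role], products: Sequence[str], recipe: Sequence[dict]
) -> Tuple[ReactionEquation, str, Dict[str, int]]:
    """Canonical equation, clean action text, and role -> position map."""
    precursors = sorted({canonical_smiles(r.smiles) for r in roles})
    prods = sorted({canonical_smiles(p) for p in products})
    eq = ReactionEquation(tuple(precursors), tuple(prods))
    positions = {r.key: eq.position_of(canonical_smiles(r.smiles)) for r in roles}

    def ref(spec) -> CompoundRef:
        if spec[0] == "role":
            return CompoundRef.positional(positions[spec[1]])
        if spec[0] == "product":
            return CompoundRef.positional(-1)
        return CompoundRef.named(spec[1])

    actions = []
    for s in recipe:
        actions.append(
            Action(
                action_type=s["type"],
                compound=ref(s["compound"]) if "compound" in s else None,
                solvent=ref(s["solvent"]) if "solvent" in s else None,
                duration=s.get("duration"),
                temperature=s.get("temperature"),
                phase=s.get("phase"),
            )
        )
    return eq, render_action_text(ActionSequence(tuple(actions))), positions


def _raw_actions(
    roles: Sequence[_Role],
    recipe: Sequence[dict],
    cfg: GeneratorConfig,
    rng: random.Random,
    condition_override: Optional[Dict[int, int]] = None,
) -> List[Action]:
    """Named-reference raw actions with reversible noise applied."""
    by_key = {r.key: r for r in roles}

    def raw_name(role_key: str) -> str:
        name = by_key[role_key].name
        if rng.random() < cfg.name_variant_rate:
            name = _corrupt_name(name, rng)
        return name

    def ref(spec) -> CompoundRef:
        if spec[0] == "role":
            return CompoundRef.named(raw_name(spec[1]))
        if spec[0] == "product":
            return CompoundRef.named("title compound")
        return CompoundRef.named(spec[1])

    actions: List[Action] = []
    for i, s in enumerate(recipe):
        duration = s.get("duration")
        if condition_override and i in condition_override:
            duration = condition_override[i]
        props: dict = {}
        if duration is not None:
            props["duration"] = rng.choice(_DURATION_SPELLINGS[duration])
        if s.get("temperature") is not None:
            props["temperature"] = rng.choice(
                _TEMPERATURE_SPELLINGS[s["temperature"]]
            )
        if s.get("phase") is not None and rng.random() < 0.5:
            # phase sometimes left implicit; postprocessing must infer it
            props["phase"] = s["phase"]
        quantities = ()
        if s["type"] == "ADD" and rng.random() < cfg.quantity_rate:
            quantities = (f"{rng.randrange(1, 50)} mL",)
        actions.append(
            Action(
                action_type=s["type"],
                compound=ref(s["compound"]) if "compound" in s else None,
                solvent=ref(s["solvent"]) if "solvent" in s else None,
                phase=props.get("phase"),
                duration=props.get("duration"),
                temperature=props.get("temperature"),
                quantities=quantities,
            )
        )
    if rng.random() < cfg.noaction_rate:
        actions.insert(rng.randrange(len(actions) + 1), Action("NOACTION"))
    return actions


def _plant_defect(
    category: str,
    record: dict,
    rng: random.Random,
) -> None:
    """Mutate a clean raw record in place so the pipeline must reject it
    under exactly ``category``."""
    actions: List[Action] = record["actions"]
    if category == "refers to other procedure":
        actions.insert(rng.randrange(len(actions) + 1), Action("FOLLOWOTHERPROCEDURE"))
    elif category == "contains InvalidAction":
        actions.insert(rng.randrange(len(actions) + 1), Action("INVALIDACTION"))
    elif category == "error in duration extraction":
        for i, a in enumerate(actions):
            if a.duration is not None:
                actions[i] = a.replace(duration="several moons")
                break
        else:
            actions.insert(1, Action("STIR", duration="several moons"))
    elif category == "error in temperature extraction":
        for i, a in enumerate(actions):
            if a.temperature is not None:
                actions[i] = a.replace(temperature="unknown warmth")
                break
        else:
            actions.insert(1, Action("STIR", temperature="unknown warmth"))
    elif category == "likely to contain multiple reaction steps":
        actions.extend(
            [
                Action("ADD", compound=CompoundRef.named("intermediate 5")),
                Action("STIR", duration="1 h"),
                Action("YIELD", compound=CompoundRef.named("title compound")),
            ]
        )
    elif category == "too short action sequence":
        del actions[4:]
    elif category == "error in action sequence extraction":
        record["extraction_error"] = True
    elif category == "molecule present both in the precursors and the products":
        record["reactants"] = list(record["reactants"]) + list(record["products"])
    elif category == "invalid molecule SMILES":
        record["reactants"] = ["C1CC"] + list(record["reactants"])[1:]
    elif category == "invalid reaction SMILES":
        record["products"] = []
    elif category == "incomplete mapping of molecules":
        actions.insert(1, Action("ADD", compound=CompoundRef.named("compound 7a")))
    elif category == "other":
        actions.insert(0, Action("STIR", temperature="same temperature"))
    elif category == "non-English":
        record["language"] = "de"
    else:  # pragma: no cover
        raise ValueError(f"unplantable category {category!r}")


def generate(
    config: GeneratorConfig,
) -> Tuple[List[ReactionRecord], List[GroundTruth]]:
    """Generate raw records plus per-record ground truth.

    Deterministic given the seed.  Clean records survive the pipeline and
    reproduce their clean pair exactly; each defect-labelled record is
    rejected under its label.  When the substituent space of a template is
    exhausted, further draws reuse an earlier equation and are labelled as
    duplicates, so rejection counts stay exactly predictable.
    """
    rng = random.Random(config.seed)
    templates = _templates()
    weights = [
        (config.template_weights or {}).get(t.key, 1.0) for t in templates
    ]
    variant_pools: Dict[str, List] = {}
    for t in templates:
        pool = list(t.variants)
        rng.shuffle(pool)
        variant_pools[t.key] = pool
    used_count: Dict[str, int] = {t.key: 0 for t in templates}

    defect_items = sorted(config.defect_rates.items())
    records: List[ReactionRecord] = []
    truths: List[GroundTruth] = []
    # (template, variant) of clean emitted records; duplicates copy these so
    # that every duplicate is guaranteed to collide with a retained record
    emitted_clean: List[Tuple[_Template, tuple]] = []
    emitted_by_template: Dict[str, List[tuple]] = {}

    for i in range(config.n_records):
        rec_id = f"synthetic-{config.seed}-{i:06d}"

        # choose planted defect (mutually exclusive), duplicates included
        u = rng.random()
        defect: Optional[str] = None
        duplicate = False
        acc = 0.0
        for cat, rate in defect_items:
            acc += rate
            if u < acc:
                defect = cat
                break
        else:
            if u < acc + config.duplicate_rate and emitted_clean:
                duplicate = True

        template = rng.choices(templates, weights=weights, k=1)[0]
        if duplicate:
            template, variant = emitted_clean[rng.randrange(len(emitted_clean))]
        else:
            pool = variant_pools[template.key]
            if used_count[template.key] < len(pool):
                variant = pool[used_count[template.key]]
                used_count[template.key] += 1
            elif defect is not None:
                # rejected before dedup, so equation reuse is harmless
                variant = pool[rng.randrange(len(pool))]
            elif emitted_clean:
                # substituent space exhausted: reuse a clean equation and
                # label the record as a duplicate
                prior = emitted_by_template.get(template.key)
                if prior:
                    variant = prior[rng.randrange(len(prior))]
                else:
                    template, variant = emitted_clean[
                        rng.randrange(len(emitted_clean))
                    ]
                duplicate = True
            else:  # pragma: no cover - exhausted before any clean record
                variant = pool[rng.randrange(len(pool))]
                duplicate = True

        roles, products = template.build(variant)
        eq, clean_text, _ = _clean_pair(roles, products, template.recipe)

        condition_override = None
        if duplicate:
            # divergent procedure: shift one duration token where possible
            for j, s in enumerate(template.recipe):
                if s.get("duration") is not None:
                    alt = [k for k in _DURATION_SPELLINGS if k != s["duration"]]
                    condition_override = {j: rng.choice(alt)}
                    break

        raw = {
            "reactants": [r.smiles for r in roles if not r.reagent],
            "reagents": [r.smiles for r in roles if r.reagent],
            "products": list(products),
            "actions": _raw_actions(
                roles, template.recipe, config, rng, condition_override
            ),
            "language": "en",
            "extraction_error": False,
        }
        if defect is not None:
            _plant_defect(defect, raw, rng)
        if not duplicate and defect is None:
            emitted_clean.append((template, variant))
            emitted_by_template.setdefault(template.key, []).append(variant)

        name_map = {r.name: r.smiles for r in roles}
        name_map["title compound"] = products[0]
        records.append(
            ReactionRecord(
                id=rec_id,
                reactants=tuple(raw["reactants"]),
                reagents=tuple(raw["reagents"]),
                products=tuple(raw["products"]),
                actions=ActionSequence(tuple(raw["actions"])),
                local_name_map=name_map,
                language=raw["language"],
                extraction_error=raw["extraction_error"],
            )
        )
        truths.append(
            GroundTruth(
                id=rec_id,
                template=template.key,
                defect="duplicate reaction SMILES" if duplicate else defect,
                clean_reaction_smiles=None if defect else serialize_equation(eq),
                clean_action_text=None if defect else clean_text,
            )
        )
    return records, truths


def write_records_jsonl(records: Sequence[ReactionRecord], path: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(r.to_dict()) + "\n")


def write_truth_jsonl(truths: Sequence[GroundTruth], path: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for t in truths:
            fh.write(json.dumps(t.to_dict()) + "\n")
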