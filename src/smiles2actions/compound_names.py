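"""Compound-name stripping, normalization, and name<->SMILES mapping.

Names extracted from experimental text come wrapped in qualifiers
("saturated solution of sulfuric acid", "5 mL of a 1.0 M DCM solution of
boron tribromide") and are riddled with OCR artifacts and spelling
variants.  Matching them to the molecules of a chemical equation takes
three layers:

* :func:`strip_name` trims state/concentration/temperature/ratio
  qualifiers and splits multi-compound constructions, returning one root
  name per constituent.  The heuristics are data: a line-oriented rules
  file (packaged default in ``data/name_rules.txt``).
* :func:`normalize_name` collapses names into a normalized space where
  OCR-confusable spellings coincide (subscripts to ASCII, I/1 -> l,
  0 -> O, lowercasing, dash/prime removal, spelled-out Greek letters,
  space and special-character removal).  Readability of the result is
  irrelevant; only equality in normalized space matters.
* :class:`NameMaps` holds the modal normalized-name -> SMILES and
  SMILES -> raw-name tables built from observed (name, SMILES) pairs,
  giving each compound a most common synonym.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from .errors import NameStrippingError
from .reaction_smiles import canonical_smiles

__all__ = [
    "StrippingRules",
    "NameMaps",
    "strip_name",
    "normalize_name",
    "build_name_maps",
    "canonical_synonym",
]


# ---------------------------------------------------------------------------
# stripping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrippingRules:
    """Ordered stripping rules: ("split"|"remove", compiled regex)."""

    rules: tuple

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "StrippingRules":
        rules = []
        for lineno, line in enumerate(lines, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            try:
                op, pattern = line.split("\t", 1)
            except ValueError:
                raise ValueError(f"rules line {lineno}: expected '<op>\\t<regex>'")
            if op not in ("split", "remove"):
                raise ValueError(f"rules line {lineno}: unknown op {op!r}")
            rules.append((op, re.compile(pattern, re.IGNORECASE)))
        return cls(tuple(rules))

    @classmethod
    def from_file(cls, path: str) -> "StrippingRules":
        return cls.from_lines(Path(path).read_text(encoding="utf-8").splitlines())

    @classmethod
    def packaged(cls) -> "StrippingRules":
        text = resources.files("smiles2actions.data").joinpath(
            "name_rules.txt"
        ).read_text(encoding="utf-8")
        return cls.from_lines(text.splitlines())


_DEFAULT_RULES: Optional[StrippingRules] = None


def _default_rules() -> StrippingRules:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = StrippingRules.packaged()
    return _DEFAULT_RULES


def _tidy(part: str) -> str:
    part = re.sub(r"\s+", " ", part).strip()
    return part.strip(" ,;")


def strip_name(raw: str, rules: Optional[StrippingRules] = None) -> List[str]:
    """Trim qualifiers from a raw compound name.

    Returns one root name per constituent compound (multi-compound
    constructions such as "DCM solution of boron tribromide" yield two).
    Raises :class:`NameStrippingError` if nothing remains.
    """
    if not raw or not raw.strip():
        raise NameStrippingError("empty compound name")
    if rules is None:
        rules = _default_rules()

    parts = [raw]
    # splits first, applied recursively
    changed = True
    while changed:
        changed = False
        next_parts: List[str] = []
        for part in parts:
            for op, rx in rules.rules:
                if op != "split":
                    continue
                m = rx.match(part)
                if m and m.end() == len(part):
                    groups = [g for g in m.groups() if g and g.strip()]
                    if len(groups) >= 1 and groups != [part]:
                        next_parts.extend(groups)
                        changed = True
                        break
            else:
                next_parts.append(part)
        parts = next_parts

    out: List[str] = []
    for part in parts:
        for op, rx in rules.rules:
            if op == "remove":
                part = rx.sub(" ", part)
        part = _tidy(part)
        if part:
            out.append(part)
    if not out:
        raise NameStrippingError(f"nothing left after stripping {raw!r}")
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

_SUBSCRIPT_DIGITS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")
_CONFUSABLE = str.maketrans({"I": "l", "1": "l", "0": "O"})
_DASHES_AND_PRIMES = "-‐‑‒–—−′″ʹ'’´`"
_GREEK = {
    "alpha": "α", "beta": "β", "gamma": "γ", "delta": "δ", "epsilon": "ε",
    "zeta": "ζ", "eta": "η", "theta": "θ", "iota": "ι", "kappa": "κ",
    "lambda": "λ", "mu": "μ", "nu": "ν", "xi": "ξ", "omicron": "ο",
    "pi": "π", "rho": "ρ", "sigma": "σ", "tau": "τ", "upsilon": "υ",
    "phi": "φ", "chi": "χ", "psi": "ψ", "omega": "ω",
}
# standalone words only: "alpha-glucose" converts, "sulfoxide" does not
_GREEK_RE = re.compile(
    r"(?<![a-z])(" + "|".join(sorted(_GREEK, key=len, reverse=True)) + r")(?![a-z])"
)
DEFAULT_SPECIAL_CHARACTERS = "⋅×·∙•"  # dot/cross operators


def normalize_name(
    name: str, special_characters: str = DEFAULT_SPECIAL_CHARACTERS
) -> str:
    """Normalize a compound name for robust matching.

    Applies, in order: subscript digits to ASCII ("H_2_SO_4_" -> "H2SO4"),
    OCR-confusable unification (I/1 -> l, 0 -> O), lowercasing, dash and
    prime removal, spelled-out Greek letters to the Greek character,
    space removal, and removal of the configured special characters.
    Total and idempotent.
    """
    # subscripts: unicode subscript digits and the "_2_" convention
    t = name.translate(_SUBSCRIPT_DIGITS)
    t = re.sub(r"_(\d+)_", r"\1", t)
    # OCR-confusable characters (applies to every character, digits included)
    t = t.translate(_CONFUSABLE)
    t = t.lower()
    # Greek words are replaced while dashes/spaces still delimit them
    t = _GREEK_RE.sub(lambda m: _GREEK[m.group(1)], t)
    for ch in _DASHES_AND_PRIMES:
        t = t.replace(ch, "")
    t = t.replace(" ", "")
    for ch in special_characters:
        t = t.replace(ch, "")
    return t


# ---------------------------------------------------------------------------
# name <-> SMILES maps
# ---------------------------------------------------------------------------

@dataclass
class NameMaps:
    """Modal normalized-name -> canonical-SMILES and SMILES -> raw-name maps."""

    name_to_smiles: Dict[str, str] = field(default_factory=dict)
    smiles_to_name: Dict[str, str] = field(default_factory=dict)
    skipped: int = 0  # pairs with unparseable SMILES

    def save(self, directory: str) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for fname, mapping in (
            ("name_to_smiles.tsv", self.name_to_smiles),
            ("smiles_to_name.tsv", self.smiles_to_name),
        ):
            with open(d / fname, "w", encoding="utf-8") as fh:
                for k in sorted(mapping):
                    fh.write(f"{k}\t{mapping[k]}\n")

    @classmethod
    def load(cls, directory: str) -> "NameMaps":
        d = Path(directory)
        maps = cls()
        for fname, mapping in (
            ("name_to_smiles.tsv", maps.name_to_smiles),
            ("smiles_to_name.tsv", maps.smiles_to_name),
        ):
            with open(d / fname, encoding="utf-8") as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line:
                        continue
                    k, v = line.split("\t", 1)
                    mapping[k] = v
        return maps


def _modal(counter: Counter) -> str:
    # highest count wins; ties broken by lexicographically smaller value
    return min(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def build_name_maps(pairs: Iterable[Tuple[str, str]]) -> NameMaps:
    """Build modal name<->SMILES maps from observed (raw name, SMILES) pairs.

    SMILES are canonicalized; unparseable pairs are skipped and counted.
    Deterministic: ties resolve to the lexicographically smaller value, so
    the result is invariant under input order.
    """
    by_name: Dict[str, Counter] = defaultdict(Counter)
    by_smiles: Dict[str, Counter] = defaultdict(Counter)
    skipped = 0
    for raw_name, smiles in pairs:
        try:
            can = canonical_smiles(smiles)
        except Exception:
            skipped += 1
            continue
        by_name[normalize_name(raw_name)][can] += 1
        by_smiles[can][raw_name] += 1
    return NameMaps(
        name_to_smiles={k: _modal(c) for k, c in by_name.items()},
        smiles_to_name={k: _modal(c) for k, c in by_smiles.items()},
        skipped=skipped,
    )


def canonical_synonym(name: str, maps: NameMaps) -> Optional[str]:
    """Most common synonym of ``name`` via name -> SMILES -> name.

    Returns None when either hop is missing.
    """
    smiles = maps.name_to_smiles.get(normalize_name(name))
    if smiles is None:
        return None
    return maps.smiles_to_name.get(smiles)
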