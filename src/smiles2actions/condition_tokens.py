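"""Interval tokenization of temperatures, durations, and pH values.

Reported reaction conditions are noisy ("8 hrs", "overnight", "about
25 C"); exact values rarely matter as long as they fall in an adequate
range.  Conditions are therefore mapped onto predefined half-open numeric
intervals, each named by a token ("@3@" = third duration range, "#4#" =
fourth temperature range) and carrying a representative value used when a
predicted token must be turned back into a number.

The tables are configuration, not code: the packaged defaults live in
``data/condition_tokens.yaml`` and honor the anchor values 10 min -> @1@,
1 h -> @2@, 8 h -> @3@, 1 day -> @4@ and 25 degC -> #4#.
"""

from __future__ import annotations

import math
import re
from bisect import bisect_right
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional

import yaml

from .errors import QuantityParseError, TokenizationError

__all__ = [
    "KINDS",
    "TokenTable",
    "load_token_tables",
    "default_tables",
    "parse_quantity_string",
    "to_token",
    "from_token",
]

KINDS = ("temperature", "duration", "ph")


@dataclass(frozen=True)
class TokenTable:
    """Ordered half-open intervals [b_i, b_{i+1}) with representatives."""

    kind: str
    boundaries: tuple  # length n_tokens + 1, strictly increasing
    representatives: tuple  # length n_tokens, representatives[i] in interval i
    glyph: str

    def __post_init__(self) -> None:
        b, r = self.boundaries, self.representatives
        if len(b) != len(r) + 1:
            raise ValueError("need one more boundary than representatives")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")
        for i, rep in enumerate(r):
            if not (b[i] <= rep < b[i + 1]):
                raise ValueError(f"representative {rep} outside interval {i + 1}")

    @property
    def n_tokens(self) -> int:
        return len(self.representatives)

    def to_token(self, value: float) -> int:
        """1-based index of the unique interval containing ``value``."""
        idx = bisect_right(self.boundaries, value)
        if idx < 1 or idx > self.n_tokens:
            raise TokenizationError(
                f"{self.kind} value {value} outside admissible range"
            )
        return idx

    def from_token(self, index: int) -> float:
        if not 1 <= index <= self.n_tokens:
            raise TokenizationError(f"invalid {self.kind} token index {index}")
        return self.representatives[index - 1]

    def render(self, index: int) -> str:
        return f"{self.glyph}{index}{self.glyph}"


def load_token_tables(path: Optional[str] = None) -> Dict[str, TokenTable]:
    """Load token tables (and phrase defaults) from a YAML config."""
    if path is None:
        text = resources.files("smiles2actions.data").joinpath(
            "condition_tokens.yaml"
        ).read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    tables = {}
    for kind in KINDS:
        cfg = raw[kind]
        tables[kind] = TokenTable(
            kind=kind,
            boundaries=tuple(float(b) for b in cfg["boundaries"]),
            representatives=tuple(float(r) for r in cfg["representatives"]),
            glyph=cfg["glyph"],
        )
    tables["_phrases"] = raw.get("phrases", {})  # type: ignore[assignment]
    return tables


_DEFAULT: Optional[Dict[str, TokenTable]] = None


def default_tables() -> Dict[str, TokenTable]:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_token_tables()
    return _DEFAULT


_NUMBER_WORDS = {
    "zero": 0, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "thirteen": 13, "fourteen": 14, "fifteen": 15,
    "sixteen": 16, "seventeen": 17, "eighteen": 18, "nineteen": 19,
    "twenty": 20, "a": 1, "an": 1, "half": 0.5, "couple": 2, "few": 3,
    "several": 3,
}

_DURATION_UNITS = {
    "s": 1, "sec": 1, "secs": 1, "second": 1, "seconds": 1,
    "min": 60, "mins": 60, "minute": 60, "minutes": 60,
    "h": 3600, "hr": 3600, "hrs": 3600, "hour": 3600, "hours": 3600,
    "d": 86400, "day": 86400, "days": 86400,
    "week": 604800, "weeks": 604800,
}

_TEMP_UNITS = {
    "c": "C", "celsius": "C", "centigrade": "C",
    "f": "F", "fahrenheit": "F",
    "k": "K", "kelvin": "K",
    "degrees": "C", "degree": "C", "deg": "C",
}

_NUM_RE = r"[-+−]?\d+(?:\.\d+)?"


def _to_number(word: str) -> Optional[float]:
    word = word.replace("−", "-")
    if re.fullmatch(_NUM_RE, word):
        return float(word)
    return _NUMBER_WORDS.get(word)


def _clean(text: str) -> str:
    t = text.strip().lower()
    t = t.replace("°", " ")  # degree sign
    t = t.replace("–", "-").replace("—", "-")
    t = re.sub(r"\b(?:about|approximately|approx\.?|ca\.?|around|roughly|~)\s*", "", t)
    t = re.sub(r"\s+", " ", t)
    return t.strip()


def _parse_duration(t: str) -> float:
    # sum of (number, unit) terms: "1 h 30 min"
    term = re.compile(
        rf"({_NUM_RE}|{'|'.join(_NUMBER_WORDS)})[ ]*({'|'.join(_DURATION_UNITS)})\b"
    )
    total, pos, found = 0.0, 0, False
    for m in term.finditer(t):
        n = _to_number(m.group(1))
        if n is None:
            continue
        total += n * _DURATION_UNITS[m.group(2)]
        found = True
    if not found:
        raise QuantityParseError("duration", t)
    return total


def _parse_temperature(t: str) -> float:
    t = re.sub(r"\b(?:at|temperature of)\b", " ", t).strip()
    # value range "20-25 c" -> midpoint
    m = re.fullmatch(
        rf"({_NUM_RE})\s*(?:-|to)\s*({_NUM_RE})\s*([a-z]*\.?)", t
    )
    if m and (not m.group(3) or m.group(3).rstrip(".") in _TEMP_UNITS):
        lo, hi = float(m.group(1).replace("−", "-")), float(
            m.group(2).replace("−", "-")
        )
        unit = _TEMP_UNITS.get(m.group(3).rstrip("."), "C") if m.group(3) else "C"
        return _convert_temp((lo + hi) / 2.0, unit)
    m = re.fullmatch(
        rf"({_NUM_RE}|{'|'.join(_NUMBER_WORDS)})\s*([a-z]*\.?)", t
    )
    if m:
        n = _to_number(m.group(1))
        unit_word = m.group(2).rstrip(".")
        if n is not None and (not unit_word or unit_word in _TEMP_UNITS):
            return _convert_temp(n, _TEMP_UNITS.get(unit_word, "C"))
    # "degrees c", "deg. c" etc: number followed by two unit words
    m = re.fullmatch(rf"({_NUM_RE})\s*(?:degrees?|deg\.?)\s*([cf])\.?", t)
    if m:
        return _convert_temp(float(m.group(1).replace("−", "-")), m.group(2).upper())
    raise QuantityParseError("temperature", t)


def _convert_temp(value: float, unit: str) -> float:
    if unit == "F":
        return (value - 32.0) * 5.0 / 9.0
    if unit == "K":
        return value - 273.15
    return value


def _parse_ph(t: str) -> float:
    t = re.sub(r"\bph\b", " ", t).strip()
    m = re.search(_NUM_RE, t)
    if m is None:
        word = _NUMBER_WORDS.get(t)
        if word is None:
            raise QuantityParseError("ph", t)
        return float(word)
    return float(m.group(0).replace("−", "-"))


def parse_quantity_string(
    text: str, kind: str, tables: Optional[Dict[str, TokenTable]] = None
) -> float:
    """Convert a condition string to a number in canonical units.

    Canonical units: degrees Celsius, seconds, pH units.  Handles number
    words up to twenty, Fahrenheit/Kelvin conversion, value ranges
    (midpoint) and phrase defaults ("overnight", "RT", ...) from the
    token-table config.  Raises :class:`QuantityParseError` when the
    string cannot be resolved.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}")
    if tables is None:
        tables = default_tables()
    t = _clean(text)
    if not t:
        raise QuantityParseError(kind, text)
    phrases = tables.get("_phrases", {})
    if isinstance(phrases, dict):
        val = phrases.get(kind, {}).get(t)
        if val is not None:
            return float(val)
    if kind == "duration":
        return _parse_duration(t)
    if kind == "temperature":
        return _parse_temperature(t)
    return _parse_ph(t)


def to_token(
    value: float, kind: str, tables: Optional[Dict[str, TokenTable]] = None
) -> int:
    if tables is None:
        tables = default_tables()
    if not math.isfinite(value):
        raise TokenizationError(f"non-finite {kind} value")
    return tables[kind].to_token(value)


def from_token(
    index: int, kind: str, tables: Optional[Dict[str, TokenTable]] = None
) -> float:
    if tables is None:
        tables = default_tables()
    return tables[kind].from_token(index)
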