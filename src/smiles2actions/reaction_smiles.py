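"""Reaction SMILES parsing, canonicalization, and tokenization.

A chemical equation is written "precursors>>products" with "." separating
molecules; reactants and reagents are deliberately merged into a single
precursor list, since the distinction is often ambiguous.  Multi-fragment
entities (salts) keep their fragments attached with "~" instead of ".".

Canonical equations have each side canonicalized with RDKit,
deduplicated, and sorted byte-wise, so that the serialized string is
invariant to the order in which molecules were supplied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List, Tuple

from rdkit import Chem
from rdkit import RDLogger

from .errors import MoleculeSmilesError, ReactionSmilesError

RDLogger.DisableLog("rdApp.*")  # RDKit parse warnings are reported as errors here

__all__ = [
    "ReactionEquation",
    "canonical_smiles",
    "canonicalize_equation",
    "parse_reaction_smiles",
    "serialize_equation",
    "tokenize_smiles",
    "detokenize_smiles",
]

FRAGMENT_BOND = "~"


def canonical_smiles(smiles: str) -> str:
    """RDKit-canonical form of one molecule entity (may contain "~")."""
    if not smiles:
        raise MoleculeSmilesError("empty molecule SMILES")
    plain = smiles.replace(FRAGMENT_BOND, ".")
    mol = Chem.MolFromSmiles(plain)
    if mol is None:
        raise MoleculeSmilesError(f"invalid molecule SMILES {smiles!r}")
    can = Chem.MolToSmiles(mol)
    if FRAGMENT_BOND in smiles:
        can = can.replace(".", FRAGMENT_BOND)
    return can


@dataclass(frozen=True)
class ReactionEquation:
    """Precursor and product SMILES lists of one chemical equation."""

    precursors: tuple
    products: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "precursors", tuple(self.precursors))
        object.__setattr__(self, "products", tuple(self.products))

    @property
    def n_precursors(self) -> int:
        return len(self.precursors)

    @property
    def n_products(self) -> int:
        return len(self.products)

    def molecule_at(self, index: int) -> str:
        """Molecule at a positional token: k -> k-th precursor, -k -> k-th
        product (1-based)."""
        if index == 0:
            raise IndexError("positional index 0 is undefined")
        side = self.precursors if index > 0 else self.products
        i = abs(index) - 1
        if i >= len(side):
            raise IndexError(f"positional index {index} outside equation")
        return side[i]

    def position_of(self, smiles: str) -> int:
        """Signed positional index of a molecule, or 0 if absent."""
        if smiles in self.precursors:
            return self.precursors.index(smiles) + 1
        if smiles in self.products:
            return -(self.products.index(smiles) + 1)
        return 0


def canonicalize_equation(
    reactants: Iterable[str],
    reagents: Iterable[str],
    products: Iterable[str],
) -> ReactionEquation:
    """Merge reactants and reagents into precursors; canonicalize, dedup,
    and sort both sides.

    Raises :class:`MoleculeSmilesError` for an unparseable molecule and
    :class:`ReactionSmilesError` for an empty side or a molecule present
    on both sides.
    """
    precursors = sorted({canonical_smiles(s) for s in list(reactants) + list(reagents)})
    prods = sorted({canonical_smiles(s) for s in products})
    if not precursors or not prods:
        raise ReactionSmilesError("invalid reaction SMILES: empty side")
    shared = set(precursors) & set(prods)
    if shared:
        raise ReactionSmilesError(
            f"molecule present both in the precursors and the products: {sorted(shared)}"
        )
    return ReactionEquation(tuple(precursors), tuple(prods))


def parse_reaction_smiles(text: str) -> ReactionEquation:
    """Parse "precursors>>products" into an equation, preserving order.

    No canonicalization is applied; use :func:`canonicalize_equation` to
    enforce the canonical form.  Raises :class:`ReactionSmilesError` on a
    malformed string.
    """
    if text.count(">>") != 1:
        raise ReactionSmilesError(f"invalid reaction SMILES {text!r}: expected one '>>'")
    left, right = text.split(">>")
    precursors = tuple(s for s in left.split(".") if s)
    products = tuple(s for s in right.split(".") if s)
    if not precursors or not products:
        raise ReactionSmilesError(f"invalid reaction SMILES {text!r}: empty side")
    return ReactionEquation(precursors, products)


def serialize_equation(eq: ReactionEquation) -> str:
    return ".".join(eq.precursors) + ">>" + ".".join(eq.products)


_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|%\d{2}|>>|[BCNOSPFIbcnosp]"
    r"|[().=#\-+\\/:~@?*$]|\d)"
)


def tokenize_smiles(text: str) -> str:
    """Insert spaces between SMILES tokens of a reaction SMILES string.

    Bracket atoms, two-letter elements, ring-bond "%nn", and ">>" are
    single tokens; concatenating the tokens reproduces the input exactly.
    """
    if text == "":
        return ""
    tokens = _SMILES_TOKEN_RE.findall(text)
    if "".join(tokens) != text:
        bad = re.sub(_SMILES_TOKEN_RE, "", text)
        raise ReactionSmilesError(
            f"untokenizable characters {bad!r} in SMILES {text!r}"
        )
    return " ".join(tokens)


def detokenize_smiles(tokenized: str) -> str:
    return tokenized.replace(" ", "")
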