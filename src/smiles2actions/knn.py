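"""Nearest-neighbor action-sequence prediction over reaction fingerprints.

The model stores one fingerprint per training pair and answers a query
with the action text of the closest training reaction *having the same
number of precursors* — positional tokens then transfer directly, since
the counts match.  The packaged fingerprint is a deterministic structural
fingerprint (hashed circular-substructure counts of the precursor and
product sides, concatenated); any other vectorizer with the same
signature can be plugged in, e.g. a learned reaction fingerprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit.Chem import AllChem, MolFromSmiles
from rdkit.DataStructs import ConvertToNumpyArray

from .pipeline import DatasetEntry
from .reaction_smiles import ReactionEquation, parse_reaction_smiles

__all__ = ["structural_fingerprint", "FingerprintIndex", "fit", "predict"]

FINGERPRINT_LENGTH = 2048
_SIDE_LENGTH = FINGERPRINT_LENGTH // 2
_RADIUS = 3


def _molecule_counts(smiles: str) -> np.ndarray:
    mol = MolFromSmiles(smiles.replace("~", "."))
    if mol is None:
        raise ValueError(f"cannot fingerprint molecule {smiles!r}")
    fp = AllChem.GetHashedMorganFingerprint(mol, _RADIUS, nBits=_SIDE_LENGTH)
    arr = np.zeros(_SIDE_LENGTH, dtype=np.float32)
    ConvertToNumpyArray(fp, arr)
    return arr


def structural_fingerprint(eq: ReactionEquation) -> np.ndarray:
    """Concatenated hashed circular-substructure counts of the precursor
    and product sides.  Deterministic, fixed length, invariant to the
    order of molecules within each side.

    Keeping the two sides in separate halves (rather than taking their
    difference) avoids collisions between homologous reactions whose
    added substructures cancel across the arrow."""
    pre = sum((_molecule_counts(s) for s in eq.precursors),
              np.zeros(_SIDE_LENGTH, dtype=np.float32))
    prod = sum((_molecule_counts(s) for s in eq.products),
               np.zeros(_SIDE_LENGTH, dtype=np.float32))
    return np.concatenate([pre, prod])


Vectorizer = Callable[[ReactionEquation], np.ndarray]


@dataclass
class FingerprintIndex:
    """Exhaustive-search index over training fingerprints.

    ``match_products=True`` switches the compatibility constraint from
    "same precursor count" to "same precursor and product counts".
    """

    vectors: np.ndarray
    payloads: List[str]
    ids: List[str]
    counts: np.ndarray  # shape (n, 2): precursor and product counts
    match_products: bool = False
    buckets: Dict[tuple, np.ndarray] = field(default_factory=dict)

    def _key(self, n_precursors: int, n_products: int) -> tuple:
        return (n_precursors, n_products) if self.match_products else (n_precursors,)

    def build_buckets(self) -> None:
        self.buckets = {}
        for i in range(len(self.payloads)):
            key = self._key(int(self.counts[i, 0]), int(self.counts[i, 1]))
            self.buckets.setdefault(key, []).append(i)  # type: ignore[arg-type]
        self.buckets = {k: np.asarray(v, dtype=np.int64) for k, v in self.buckets.items()}

    def rows_for(self, eq: ReactionEquation) -> np.ndarray:
        """Bucket rows for a query; falls back to the nearest available
        precursor count when the exact bucket is empty."""
        key = self._key(eq.n_precursors, eq.n_products)
        rows = self.buckets.get(key)
        if rows is not None and len(rows):
            return rows
        if not self.buckets:
            raise ValueError("empty index")
        # nearest available count (L1 on the key tuple), deterministic
        best = min(
            self.buckets,
            key=lambda k: (sum(abs(a - b) for a, b in zip(k, key)), k),
        )
        return self.buckets[best]

    def save(self, directory: str) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "vectors.npy", self.vectors)
        np.save(d / "counts.npy", self.counts)
        (d / "payloads.txt").write_text(
            "".join(p + "\n" for p in self.payloads), encoding="utf-8"
        )
        (d / "index.json").write_text(
            json.dumps({"ids": self.ids, "match_products": self.match_products}),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, directory: str) -> "FingerprintIndex":
        d = Path(directory)
        meta = json.loads((d / "index.json").read_text(encoding="utf-8"))
        idx = cls(
            vectors=np.load(d / "vectors.npy"),
            counts=np.load(d / "counts.npy"),
            payloads=(d / "payloads.txt").read_text(encoding="utf-8").splitlines(),
            ids=meta["ids"],
            match_products=meta["match_products"],
        )
        idx.build_buckets()
        return idx


def fit(
    train_pairs: Sequence[DatasetEntry],
    vectorizer: Vectorizer = structural_fingerprint,
    match_products: bool = False,
) -> FingerprintIndex:
    """Build the fingerprint index from training pairs.

    Rows are ordered by record id so that nearest-neighbor ties resolve
    to the smallest training id.
    """
    if not train_pairs:
        raise ValueError("empty training set")
    pairs = sorted(train_pairs, key=lambda e: e.id)
    vectors = np.zeros((len(pairs), FINGERPRINT_LENGTH), dtype=np.float32)
    counts = np.zeros((len(pairs), 2), dtype=np.int64)
    payloads, ids = [], []
    for i, entry in enumerate(pairs):
        eq = parse_reaction_smiles(entry.reaction_smiles)
        vectors[i] = vectorizer(eq)
        counts[i] = (eq.n_precursors, eq.n_products)
        payloads.append(entry.action_text)
        ids.append(entry.id)
    index = FingerprintIndex(
        vectors=vectors,
        payloads=payloads,
        ids=ids,
        counts=counts,
        match_products=match_products,
    )
    index.build_buckets()
    return index


def predict(
    eq: ReactionEquation,
    index: FingerprintIndex,
    vectorizer: Vectorizer = structural_fingerprint,
) -> str:
    """Action text of the closest compatible training reaction (Euclidean)."""
    rows = index.rows_for(eq)
    q = vectorizer(eq)
    d = np.linalg.norm(index.vectors[rows] - q[None, :], axis=1)
    best = rows[int(np.argmin(d))]  # argmin is stable: ties -> smallest id
    return index.payloads[best]
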