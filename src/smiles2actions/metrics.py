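"""Evaluation metrics for predicted action sequences.

Predictions are compared against the ground truth as whole serialized
strings: syntactic validity (does the text parse, and does it reference
every molecule of the equation), corpus BLEU, the fraction of sequences
whose normalized Levenshtein similarity clears a threshold, random
baselines, a taxonomy of prediction/ground-truth differences built on a
minimal edit script over action types, and sequence-length histograms.

The ground truth is treated as the only correct answer — a deliberately
rigid scheme, since equivalent procedures can be phrased differently,
but the only one that compares models on equal footing.
"""

from __future__ import annotations

import json
import math
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib

from .actions import ActionSequence, parse_action_text, referenced_tokens
from .errors import ActionParseError
from .pipeline import DatasetEntry
from .reaction_smiles import ReactionEquation, parse_reaction_smiles

__all__ = [
    "validity",
    "levenshtein_similarity",
    "accuracy_at",
    "bleu",
    "random_baseline",
    "DifferenceCategory",
    "categorize_difference",
    "length_distributions",
    "EvaluationReport",
    "evaluate",
]

ACCURACY_THRESHOLDS = (1.0, 0.9, 0.75, 0.5)


# ---------------------------------------------------------------------------
# validity
# ---------------------------------------------------------------------------

def is_valid(pred_text: str, eq: ReactionEquation) -> bool:
    """A prediction is valid iff it parses and references every molecule."""
    try:
        seq = parse_action_text(pred_text)
    except ActionParseError:
        return False
    required = set(range(1, eq.n_precursors + 1)) | {
        -(i + 1) for i in range(eq.n_products)
    }
    return required <= referenced_tokens(seq)


def validity(pred_texts: Sequence[str], equations: Sequence[ReactionEquation]) -> float:
    """Fraction of predictions that parse and reference all molecules."""
    if len(pred_texts) != len(equations):
        raise ValueError("prediction/equation lists must align")
    if not pred_texts:
        return 1.0
    return sum(
        is_valid(p, eq) for p, eq in zip(pred_texts, equations)
    ) / len(pred_texts)


# ---------------------------------------------------------------------------
# Levenshtein similarity and threshold accuracies
# ---------------------------------------------------------------------------

def _edit_distance(a: str, b: str) -> int:
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def levenshtein_similarity(a: str, b: str, level: str = "char") -> float:
    """1 - editdistance(a, b) / max(|a|, |b|); 1.0 when both are empty.

    ``level="token"`` computes the distance over whitespace tokens
    instead of characters.
    """
    if level == "token":
        ta, tb = a.split(), b.split()
        vocab = {t: chr(0x100 + i) for i, t in enumerate(dict.fromkeys(ta + tb))}
        a = "".join(vocab[t] for t in ta)
        b = "".join(vocab[t] for t in tb)
    elif level != "char":
        raise ValueError(f"unknown level {level!r}")
    longest = max(len(a), len(b))
    if longest == 0:
        return 1.0
    return 1.0 - _edit_distance(a, b) / longest


def accuracy_at(
    preds: Sequence[str],
    refs: Sequence[str],
    threshold: float,
    level: str = "char",
) -> float:
    """Fraction of pairs with similarity >= threshold (1.0 = exact match)."""
    if len(preds) != len(refs):
        raise ValueError("prediction/reference lists must align")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if not preds:
        return 1.0
    if threshold == 1.0:
        hits = sum(p == r for p, r in zip(preds, refs))
    else:
        hits = sum(
            levenshtein_similarity(p, r, level) >= threshold
            for p, r in zip(preds, refs)
        )
    return hits / len(preds)


# ---------------------------------------------------------------------------
# BLEU
# ---------------------------------------------------------------------------

def _ngrams(tokens: List[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def bleu(preds: Sequence[str], refs: Sequence[str], max_n: int = 4) -> float:
    """Corpus-level BLEU over whitespace tokens, 4-gram, with brevity
    penalty and no smoothing; returns a value in [0, 1]."""
    if len(preds) != len(refs):
        raise ValueError("prediction/reference lists must align")
    matches = [0] * max_n
    totals = [0] * max_n
    pred_len = ref_len = 0
    for p, r in zip(preds, refs):
        tp, tr = p.split(), r.split()
        pred_len += len(tp)
        ref_len += len(tr)
        for n in range(1, max_n + 1):
            cp, cr = _ngrams(tp, n), _ngrams(tr, n)
            matches[n - 1] += sum(min(c, cr[g]) for g, c in cp.items())
            totals[n - 1] += max(len(tp) - n + 1, 0)
    if pred_len == 0 or any(t == 0 for t in totals):
        return 0.0
    if any(m == 0 for m in matches):
        return 0.0
    log_p = sum(math.log(m / t) for m, t in zip(matches, totals)) / max_n
    bp = 1.0 if pred_len > ref_len else math.exp(1.0 - ref_len / pred_len)
    return bp * math.exp(log_p)


# ---------------------------------------------------------------------------
# random baselines
# ---------------------------------------------------------------------------

def random_baseline(
    train: Sequence[DatasetEntry],
    test: Sequence[DatasetEntry],
    mode: str = "compatible",
    seed: int = 0,
) -> List[str]:
    """Randomly picked training action sequences as predictions.

    ``mode="all"`` draws uniformly from all training sequences;
    ``mode="compatible"`` draws among training reactions with the same
    precursor and product counts as the query (falling back to all when
    no compatible pattern exists).
    """
    if mode not in ("all", "compatible"):
        raise ValueError(f"unknown mode {mode!r}")
    if not train:
        raise ValueError("empty training set")
    rng = random.Random(seed)
    texts = [e.action_text for e in train]
    buckets: Dict[Tuple[int, int], List[str]] = {}
    if mode == "compatible":
        for e in train:
            eq = parse_reaction_smiles(e.reaction_smiles)
            buckets.setdefault((eq.n_precursors, eq.n_products), []).append(
                e.action_text
            )
    out = []
    for e in test:
        if mode == "all":
            out.append(texts[rng.randrange(len(texts))])
        else:
            eq = parse_reaction_smiles(e.reaction_smiles)
            pool = buckets.get((eq.n_precursors, eq.n_products)) or texts
            out.append(pool[rng.randrange(len(pool))])
    return out


# ---------------------------------------------------------------------------
# difference categorization
# ---------------------------------------------------------------------------

_DISPLAY = {
    "STIR": "Stir",
    "ADD": "Add",
    "REFLUX": "Reflux",
    "MICROWAVE": "Microwave",
    "WAIT": "Wait",
    "MAKESOLUTION": "MakeSolution",
    "PURIFY": "Purify",
    "WASH": "Wash",
    "SETTEMPERATURE": "Set Temperature",
    "FILTER": "Filter",
    "CONCENTRATE": "Concentrate",
    "COLLECTLAYER": "Collect Layer",
}

_NAMED_PROPERTY_TYPES = ("STIR", "ADD", "REFLUX")
_NAMED_SWAP_PAIRS = (
    ("STIR", "REFLUX"),
    ("STIR", "MICROWAVE"),
    ("STIR", "WAIT"),
    ("ADD", "MAKESOLUTION"),
)
_NAMED_MISSING_TYPES = (
    "PURIFY",
    "WASH",
    "SETTEMPERATURE",
    "FILTER",
    "CONCENTRATE",
    "STIR",
    "ADD",
    "COLLECTLAYER",
)


@dataclass(frozen=True)
class DifferenceCategory:
    """One cell of the difference taxonomy.

    ``others_identical`` is None for categories where the distinction
    does not apply (exact match, ordering, property differences,
    multiple-action categories)."""

    kind: str
    detail: Optional[str] = None
    others_identical: Optional[bool] = None

    @property
    def label(self) -> str:
        base = {
            "exact": "Exact match",
            "order": "Actions in different order",
            "property_one": f"Properties of one action are different: {self.detail}",
            "property_other": "Properties of another action type are different",
            "property_multiple": "Properties of multiple actions are different",
            "swap": f"Actions are swapped: {self.detail}",
            "swap_other": "Other swap of a single action",
            "missing": f"Action without counterpart: {self.detail}",
            "missing_other": "Another action type without counterpart",
            "only_ground_truth": "Multiple actions only in the ground truth",
            "only_prediction": "Multiple actions only in the prediction",
            "remaining": "Remaining cases",
        }[self.kind]
        return base


def _edit_script(
    ref_types: Sequence[str], pred_types: Sequence[str]
) -> List[Tuple[str, int, int]]:
    """Minimal edit script turning ref into pred over action types.

    Ops are ("match"|"sub", i, j), ("del", i, -1) for a ref-only action,
    ("ins", -1, j) for a prediction-only action.  Deterministic
    tie-break: diagonal first, then deletion, then insertion, giving the
    leftmost-minimal script.
    """
    m, n = len(ref_types), len(pred_types)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        dp[i][0] = i
    for j in range(n + 1):
        dp[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cost = 0 if ref_types[i - 1] == pred_types[j - 1] else 1
            dp[i][j] = min(dp[i - 1][j - 1] + cost, dp[i - 1][j] + 1, dp[i][j - 1] + 1)
    ops: List[Tuple[str, int, int]] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            cost = 0 if ref_types[i - 1] == pred_types[j - 1] else 1
            if dp[i][j] == dp[i - 1][j - 1] + cost:
                ops.append(("match" if cost == 0 else "sub", i - 1, j - 1))
                i, j = i - 1, j - 1
                continue
        if i > 0 and dp[i][j] == dp[i - 1][j] + 1:
            ops.append(("del", i - 1, -1))
            i -= 1
            continue
        ops.append(("ins", -1, j - 1))
        j -= 1
    ops.reverse()
    return ops


def categorize_difference(
    pred: ActionSequence, ref: ActionSequence
) -> DifferenceCategory:
    """Classify how a predicted sequence differs from the ground truth.

    Decision cascade: equality; equality as multisets (ordering);
    identical type sequences (property differences); a minimal edit
    script over action types with exactly one substitution (a swap) or
    exactly one insertion/deletion (an action without counterpart);
    two or more pure deletions/insertions; otherwise "remaining".
    """
    if tuple(pred) == tuple(ref):
        return DifferenceCategory("exact")
    if Counter(pred) == Counter(ref):
        return DifferenceCategory("order")
    pred_types = [a.action_type for a in pred]
    ref_types = [a.action_type for a in ref]
    if pred_types == ref_types:
        diff = [i for i, (p, r) in enumerate(zip(pred, ref)) if p != r]
        if len(diff) == 1:
            t = pred_types[diff[0]]
            if t in _NAMED_PROPERTY_TYPES:
                return DifferenceCategory("property_one", _DISPLAY[t])
            return DifferenceCategory("property_other")
        return DifferenceCategory("property_multiple")

    ops = _edit_script(ref_types, pred_types)
    subs = [op for op in ops if op[0] == "sub"]
    dels = [op for op in ops if op[0] == "del"]
    inss = [op for op in ops if op[0] == "ins"]
    matches = [op for op in ops if op[0] == "match"]

    def others_identical(excluded_ops) -> bool:
        return all(ref[i] == pred[j] for _, i, j in matches)

    if len(subs) == 1 and not dels and not inss:
        _, i, j = subs[0]
        ta, tb = ref_types[i], pred_types[j]
        ident = others_identical(subs)
        for pair in _NAMED_SWAP_PAIRS:
            if {ta, tb} == set(pair):
                detail = f"{_DISPLAY[pair[0]]} and {_DISPLAY[pair[1]]}"
                return DifferenceCategory("swap", detail, ident)
        return DifferenceCategory("swap_other", None, ident)

    if not subs and len(dels) + len(inss) == 1:
        if dels:
            t = ref_types[dels[0][1]]
        else:
            t = pred_types[inss[0][2]]
        ident = others_identical(dels or inss)
        if t in _NAMED_MISSING_TYPES:
            return DifferenceCategory("missing", _DISPLAY[t], ident)
        return DifferenceCategory("missing_other", None, ident)

    if not subs and not inss and len(dels) >= 2:
        return DifferenceCategory("only_ground_truth")
    if not subs and not dels and len(inss) >= 2:
        return DifferenceCategory("only_prediction")
    return DifferenceCategory("remaining")


# ---------------------------------------------------------------------------
# length distributions
# ---------------------------------------------------------------------------

def length_distributions(
    predictions: Dict[str, Sequence[str]],
    refs: Optional[Sequence[str]] = None,
    accuracy_levels: Tuple[float, ...] = (1.0, 0.75, 0.5),
) -> Dict[str, Dict]:
    """Histograms of predicted sequence lengths (number of actions).

    One histogram per model; when references are given, also one
    histogram per accuracy stratum and model.  Unparseable predictions
    are counted separately under "unparseable".
    """
    out: Dict[str, Dict] = {}
    for model, preds in predictions.items():
        hist: Counter = Counter()
        unparseable = 0
        lengths: List[Optional[int]] = []
        for p in preds:
            try:
                n = len(parse_action_text(p))
                hist[n] += 1
                lengths.append(n)
            except ActionParseError:
                unparseable += 1
                lengths.append(None)
        entry: Dict = {"histogram": dict(hist), "unparseable": unparseable}
        if refs is not None:
            if len(refs) != len(preds):
                raise ValueError("prediction/reference lists must align")
            for level in accuracy_levels:
                strat: Counter = Counter()
                for p, r, n in zip(preds, refs, lengths):
                    if n is None:
                        continue
                    sim = 1.0 if p == r else levenshtein_similarity(p, r)
                    if sim >= level:
                        strat[n] += 1
                entry[f"accuracy_{level:g}"] = dict(strat)
        out[model] = entry
    return out


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """All metrics for one model on one test set: headline scores plus
    the difference-category counts."""

    validity: float
    bleu: float
    accuracy_at: Dict[float, float]
    category_counts: Dict[str, int]
    length_histograms: Dict[str, Dict]
    n_pairs: int = 0

    def __post_init__(self) -> None:
        for v in (self.validity, *self.accuracy_at.values()):
            if not 0.0 <= v <= 1.0:
                raise AssertionError("fractions must lie in [0, 1]")
        ordered = sorted(self.accuracy_at)  # increasing threshold
        accs = [self.accuracy_at[t] for t in ordered]
        if any(a < b for a, b in zip(accs, accs[1:])):
            raise AssertionError("accuracy must be non-increasing in threshold")
        if self.category_counts and sum(self.category_counts.values()) != self.n_pairs:
            raise AssertionError("category counts must sum to the number of pairs")

    def to_json(self) -> str:
        return json.dumps(
            {
                "validity": self.validity,
                "bleu": self.bleu,
                "accuracy_at": {str(k): v for k, v in self.accuracy_at.items()},
                "category_counts": self.category_counts,
                "length_histograms": self.length_histograms,
                "n_pairs": self.n_pairs,
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["Metric\tValue (%)"]
        lines.append(f"Validity\t{100 * self.validity:.2f}")
        lines.append(f"BLEU score\t{100 * self.bleu:.2f}")
        for t in sorted(self.accuracy_at, reverse=True):
            lines.append(f"{100 * t:g}% accuracy\t{100 * self.accuracy_at[t]:.2f}")
        lines.append("")
        lines.append("Category\tCount")
        for cat, count in self.category_counts.items():
            lines.append(f"{cat}\t{count}")
        return "\n".join(lines) + "\n"


def evaluate(
    preds: Sequence[str],
    refs: Sequence[str],
    reaction_smiles: Sequence[str],
    level: str = "char",
) -> EvaluationReport:
    """Compute the full evaluation report for one model."""
    equations = [parse_reaction_smiles(s) for s in reaction_smiles]
    counts: Counter = Counter()
    for p, r in zip(preds, refs):
        try:
            ps = parse_action_text(p)
            rs = parse_action_text(r)
        except ActionParseError:
            counts["Unparseable prediction"] += 1
            continue
        cat = categorize_difference(ps, rs)
        key = cat.label
        if cat.others_identical is not None:
            key += (
                " | identical others" if cat.others_identical else " | different others"
            )
        counts[key] += 1
    return EvaluationReport(
        validity=validity(preds, equations),
        bleu=bleu(preds, refs),
        accuracy_at={t: accuracy_at(preds, refs, t, level) for t in ACCURACY_THRESHOLDS},
        category_counts=dict(counts),
        length_histograms=length_distributions({"model": preds}, refs),
        n_pairs=len(preds),
    )
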