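"""Evaluation metrics against independent oracles."""

import math
import random
from collections import Counter

import pytest

from smiles2actions.actions import parse_action_text
from smiles2actions.metrics import (
    accuracy_at,
    bleu,
    categorize_difference,
    is_valid,
    length_distributions,
    levenshtein_similarity,
    random_baseline,
    validity,
)
from smiles2actions.reaction_smiles import parse_reaction_smiles

from conftest import (
    CONDENSATION_REACTION_SMILES,
    CONDENSATION_ACTION_TEXT,
    AMINATION_GROUND_TRUTH,
    AMINATION_TRANSFORMER_PREDICTION,
)


# ---------------------------------------------------------------------------
# validity
# ---------------------------------------------------------------------------

def test_worked_example_is_valid():
    eq = parse_reaction_smiles(CONDENSATION_REACTION_SMILES)
    assert is_valid(CONDENSATION_ACTION_TEXT, eq)


def test_missing_molecule_invalidates():
    eq = parse_reaction_smiles(CONDENSATION_REACTION_SMILES)
    without_add3 = CONDENSATION_ACTION_TEXT.replace("ADD $3$; ", "")
    assert not is_valid(without_add3, eq)


def test_broken_clause_invalidates():
    eq = parse_reaction_smiles(CONDENSATION_REACTION_SMILES)
    assert not is_valid("ADD $1$; GLORP", eq)


# ---------------------------------------------------------------------------
# Levenshtein similarity vs brute-force DP oracle
# ---------------------------------------------------------------------------

def _dp_edit_distance(a: str, b: str) -> int:
    m, n = len(a), len(b)
    dp = list(range(n + 1))
    for i in range(1, m + 1):
        prev, dp[0] = dp[0], i
        for j in range(1, n + 1):
            cur = dp[j]
            dp[j] = min(dp[j] + 1, dp[j - 1] + 1, prev + (a[i - 1] != b[j - 1]))
            prev = cur
    return dp[n]


def test_similarity_examples():
    assert levenshtein_similarity("abc", "abc") == 1.0
    assert levenshtein_similarity("abc", "abd") == pytest.approx(2 / 3)
    assert levenshtein_similarity("", "a") == 0.0
    assert levenshtein_similarity("", "") == 1.0


def test_similarity_agrees_with_dp_oracle_on_10k_pairs():
    rng = random.Random(99)
    alphabet = "AD $1#@; abcdefg"
    for _ in range(10_000):
        a = "".join(rng.choices(alphabet, k=rng.randrange(0, 14)))
        b = "".join(rng.choices(alphabet, k=rng.randrange(0, 14)))
        longest = max(len(a), len(b))
        expected = 1.0 if longest == 0 else 1.0 - _dp_edit_distance(a, b) / longest
        assert levenshtein_similarity(a, b) == pytest.approx(expected)


def test_token_level_similarity():
    assert levenshtein_similarity("ADD $1$ now", "ADD $2$ now", level="token") == (
        pytest.approx(2 / 3)
    )


# ---------------------------------------------------------------------------
# threshold accuracies
# ---------------------------------------------------------------------------

def test_accuracy_exact_and_monotone():
    preds = ["aaaa", "aaab", "abbb", "bbbb"]
    refs = ["aaaa"] * 4
    assert accuracy_at(preds, refs, 1.0) == 0.25
    assert accuracy_at(preds, refs, 0.75) == 0.5
    acc = [accuracy_at(preds, refs, t) for t in (0.5, 0.75, 0.9, 1.0)]
    assert acc == sorted(acc, reverse=True)


def test_accuracy_identity():
    preds = ["ADD $1$; STIR", "YIELD $-1$"]
    for t in (1.0, 0.9, 0.75, 0.5):
        assert accuracy_at(preds, preds, t) == 1.0


def test_constructed_half_above_075():
    refs = ["aaaaaaaa"] * 4
    preds = ["aaaaaaaa", "aaaaaaab", "aaaabbbb", "bbbbbbbb"]
    assert accuracy_at(preds, refs, 0.75) == 0.5


# ---------------------------------------------------------------------------
# BLEU vs an independently coded implementation
# ---------------------------------------------------------------------------

def _oracle_bleu(preds, refs):
    """Textbook corpus BLEU, written independently of the package code."""
    weights = [0.25] * 4
    p_logs = []
    for n in range(1, 5):
        num = den = 0
        for p, r in zip(preds, refs):
            pt, rt = p.split(), r.split()
            pn = [tuple(pt[i : i + n]) for i in range(len(pt) - n + 1)]
            rn = Counter(tuple(rt[i : i + n]) for i in range(len(rt) - n + 1))
            seen = Counter()
            for g in pn:
                if rn[g] > seen[g]:
                    num += 1
                    seen[g] += 1
            den += len(pn)
        if den == 0 or num == 0:
            return 0.0
        p_logs.append(math.log(num / den))
    c = sum(len(p.split()) for p in preds)
    r = sum(len(x.split()) for x in refs)
    bp = 1.0 if c > r else math.exp(1 - r / c)
    return bp * math.exp(sum(w * l for w, l in zip(weights, p_logs)))


def test_bleu_identity_and_disjoint():
    preds = ["ADD $1$ ; STIR for @3@", "YIELD $-1$ done x y"]
    assert bleu(preds, preds) == pytest.approx(1.0)
    assert bleu(["a b c d e"], ["v w x y z"]) == 0.0


def test_bleu_matches_oracle_within_1e6():
    rng = random.Random(5)
    vocab = ["ADD", "STIR", "$1$", "$2$", "@3@", "#4#", "for", "at", ";", "YIELD"]
    for _ in range(50):
        preds, refs = [], []
        for _ in range(8):
            preds.append(" ".join(rng.choices(vocab, k=rng.randrange(5, 15))))
            refs.append(" ".join(rng.choices(vocab, k=rng.randrange(5, 15))))
        assert bleu(preds, refs) == pytest.approx(_oracle_bleu(preds, refs), abs=1e-6)


# ---------------------------------------------------------------------------
# random baselines
# ---------------------------------------------------------------------------

def test_compatible_baseline_fully_valid(clean_corpus, corpus_splits):
    train, _, test = corpus_splits
    preds = random_baseline(train, test, mode="compatible", seed=11)
    eqs = [parse_reaction_smiles(e.reaction_smiles) for e in test]
    assert validity(preds, eqs) == 1.0


def test_all_baseline_below_100_on_mixed_counts(corpus_splits):
    train, _, test = corpus_splits
    preds = random_baseline(train, test, mode="all", seed=11)
    eqs = [parse_reaction_smiles(e.reaction_smiles) for e in test]
    assert validity(preds, eqs) < 1.0


def test_baseline_deterministic(corpus_splits):
    train, _, test = corpus_splits
    a = random_baseline(train, test, mode="compatible", seed=4)
    b = random_baseline(train, test, mode="compatible", seed=4)
    assert a == b


# ---------------------------------------------------------------------------
# difference categorization
# ---------------------------------------------------------------------------

def _cat(pred_text, ref_text):
    return categorize_difference(
        parse_action_text(pred_text), parse_action_text(ref_text)
    )


def test_identical_sequences_exact_match():
    c = _cat(CONDENSATION_ACTION_TEXT, CONDENSATION_ACTION_TEXT)
    assert c.label == "Exact match"


def test_reordered_sequence():
    c = _cat("ADD $2$; ADD $1$; STIR", "ADD $1$; ADD $2$; STIR")
    assert c.label == "Actions in different order"


def test_property_difference_single_stir():
    c = _cat("ADD $1$; STIR for @2@", "ADD $1$; STIR for @3@")
    assert c.label == "Properties of one action are different: Stir"


def test_property_difference_multiple():
    c = _cat("ADD $1$ at #3#; STIR for @2@", "ADD $1$; STIR for @3@")
    assert c.label == "Properties of multiple actions are different"


def test_swap_stir_reflux_identical_others():
    c = _cat("ADD $1$; STIR; YIELD $-1$", "ADD $1$; REFLUX; YIELD $-1$")
    assert c.label == "Actions are swapped: Stir and Reflux"
    assert c.others_identical is True


def test_swap_with_other_property_changed():
    c = _cat("ADD $2$; STIR; YIELD $-1$", "ADD $1$; REFLUX; YIELD $-1$")
    assert c.label == "Actions are swapped: Stir and Reflux"
    assert c.others_identical is False


def test_other_swap():
    c = _cat("ADD $1$; FILTER; YIELD $-1$", "ADD $1$; CONCENTRATE; YIELD $-1$")
    assert c.label == "Other swap of a single action"


def test_extra_stir_diagnosed_as_action_without_counterpart():
    # the deep-learning prediction adds one extra Stir action before the
    # reductant addition; everything else matches the ground truth
    c = _cat(AMINATION_TRANSFORMER_PREDICTION, AMINATION_GROUND_TRUTH)
    assert c.label == "Action without counterpart: Stir"
    assert c.others_identical is True


def test_missing_purify():
    c = _cat("ADD $1$; YIELD $-1$", "ADD $1$; PURIFY; YIELD $-1$")
    assert c.label == "Action without counterpart: Purify"


def test_multiple_only_in_ground_truth():
    c = _cat("ADD $1$; YIELD $-1$", "ADD $1$; WASH with brine; PURIFY; YIELD $-1$")
    assert c.label == "Multiple actions only in the ground truth"


def test_multiple_only_in_prediction():
    c = _cat("ADD $1$; WASH with brine; PURIFY; YIELD $-1$", "ADD $1$; YIELD $-1$")
    assert c.label == "Multiple actions only in the prediction"


def test_remaining_cases():
    c = _cat("FILTER; WASH with brine; CONCENTRATE", "ADD $1$; STIR; YIELD $-1$")
    assert c.label == "Remaining cases"


def test_categorization_total_and_single_valued(corpus_splits):
    train, _, test = corpus_splits
    preds = random_baseline(train, test, mode="compatible", seed=1)
    n = 0
    for p, e in zip(preds, test):
        cat = categorize_difference(
            parse_action_text(p), parse_action_text(e.action_text)
        )
        assert cat.label
        n += 1
    assert n == len(test)


# ---------------------------------------------------------------------------
# length distributions
# ---------------------------------------------------------------------------

def test_length_histogram_point_mass():
    preds = ["ADD $1$; STIR; YIELD $-1$"] * 5
    out = length_distributions({"m": preds})
    assert out["m"]["histogram"] == {3: 5}
    assert out["m"]["unparseable"] == 0


def test_length_histogram_sums_and_unparseable():
    preds = ["ADD $1$; STIR", "broken ???", "YIELD $-1$"]
    out = length_distributions({"m": preds})
    assert sum(out["m"]["histogram"].values()) + out["m"]["unparseable"] == 3


def test_length_histogram_accuracy_strata():
    refs = ["ADD $1$; STIR", "ADD $2$; STIR"]
    preds = ["ADD $1$; STIR", "ADD $9$; REFLUX"]
    out = length_distributions({"m": preds}, refs)
    assert out["m"]["accuracy_1"] == {2: 1}
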