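"""Nearest-neighbor predictor: fingerprints, buckets, retrieval."""

import numpy as np
import pytest

from smiles2actions import knn
from smiles2actions.actions import parse_action_text
from smiles2actions.reaction_smiles import parse_reaction_smiles

from conftest import CONDENSATION_REACTION_SMILES


def _type_signature(text):
    return tuple(a.action_type for a in parse_action_text(text))


def test_fingerprint_deterministic_and_shaped():
    eq = parse_reaction_smiles(CONDENSATION_REACTION_SMILES)
    a = knn.structural_fingerprint(eq)
    b = knn.structural_fingerprint(eq)
    assert a.shape == (knn.FINGERPRINT_LENGTH,)
    assert np.array_equal(a, b)


def test_fingerprints_distinguish_fixture_reactions(clean_corpus):
    seen = {}
    for entry in clean_corpus["dataset"][:150]:
        fp = knn.structural_fingerprint(parse_reaction_smiles(entry.reaction_smiles))
        key = fp.tobytes()
        assert key not in seen, f"collision {entry.id} vs {seen.get(key)}"
        seen[key] = entry.id


def test_one_precursor_changed_changes_vector():
    a = parse_reaction_smiles("CCO.ClCCl>>CC=O")
    b = parse_reaction_smiles("CCCO.ClCCl>>CC=O")
    assert not np.array_equal(
        knn.structural_fingerprint(a), knn.structural_fingerprint(b)
    )


def test_fit_empty_raises():
    with pytest.raises(ValueError):
        knn.fit([])


def test_self_retrieval_is_exact(corpus_splits):
    train, _, _ = corpus_splits
    index = knn.fit(train)
    for entry in train:
        eq = parse_reaction_smiles(entry.reaction_smiles)
        assert knn.predict(eq, index) == entry.action_text


def test_precursor_count_constraint(corpus_splits):
    train, _, test = corpus_splits
    index = knn.fit(train)
    count_of = {}
    for entry in train:
        eq = parse_reaction_smiles(entry.reaction_smiles)
        count_of.setdefault(eq.n_precursors, set()).add(entry.action_text)
    for entry in test[:40]:
        eq = parse_reaction_smiles(entry.reaction_smiles)
        pred = knn.predict(eq, index)
        if eq.n_precursors in count_of:
            assert pred in count_of[eq.n_precursors]


def test_template_recovery_at_least_90_percent(clean_corpus, corpus_splits):
    train, _, test = corpus_splits
    index = knn.fit(train)
    template_of = {t.id: t.template for t in clean_corpus["truths"]}
    signature_of_template = {}
    for entry in clean_corpus["dataset"]:
        signature_of_template.setdefault(
            _type_signature(entry.action_text), template_of[entry.id]
        )
    hits = 0
    for entry in test:
        pred = knn.predict(parse_reaction_smiles(entry.reaction_smiles), index)
        if signature_of_template.get(_type_signature(pred)) == template_of[entry.id]:
            hits += 1
    assert hits / len(test) >= 0.90


def test_prediction_deterministic(corpus_splits):
    train, _, test = corpus_splits
    index = knn.fit(train)
    eq = parse_reaction_smiles(test[0].reaction_smiles)
    assert knn.predict(eq, index) == knn.predict(eq, index)


def test_empty_bucket_falls_back_to_nearest_count(corpus_splits):
    train, _, _ = corpus_splits
    two_precursor = [
        e for e in train
        if parse_reaction_smiles(e.reaction_smiles).n_precursors == 2
    ]
    index = knn.fit(two_precursor)
    # a 5-precursor query has no exact bucket, but prediction still works
    five = parse_reaction_smiles("C.CC.CCC.CCCC.CCCCC>>CCCCCC")
    pred = knn.predict(five, index)
    assert pred in {e.action_text for e in two_precursor}


def test_index_save_load_round_trip(tmp_path, corpus_splits):
    train, _, test = corpus_splits
    index = knn.fit(train[:30])
    index.save(tmp_path / "index")
    loaded = knn.FingerprintIndex.load(str(tmp_path / "index"))
    eq = parse_reaction_smiles(test[0].reaction_smiles)
    assert knn.predict(eq, loaded) == knn.predict(eq, index)
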