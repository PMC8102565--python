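"""Synthetic record generator: determinism, noise reversibility, defects."""

from collections import Counter

import pytest

from smiles2actions.actions import parse_action_text, referenced_tokens
from smiles2actions.compound_names import build_name_maps
from smiles2actions.pipeline import PipelineConfig, run_pipeline
from smiles2actions.reaction_smiles import parse_reaction_smiles
from smiles2actions.synthetic import (
    DEFECT_CATEGORIES,
    GeneratorConfig,
    generate,
)


def test_same_seed_identical_output():
    a_rec, a_truth = generate(GeneratorConfig(n_records=50, seed=123))
    b_rec, b_truth = generate(GeneratorConfig(n_records=50, seed=123))
    assert a_rec == b_rec
    assert a_truth == b_truth


def test_different_seed_differs():
    a_rec, _ = generate(GeneratorConfig(n_records=50, seed=1))
    b_rec, _ = generate(GeneratorConfig(n_records=50, seed=2))
    assert a_rec != b_rec


def test_clean_pairs_are_valid_pre_noise():
    _, truths = generate(GeneratorConfig(n_records=100, seed=9))
    for t in truths:
        assert t.defect is None
        seq = parse_action_text(t.clean_action_text)
        eq = parse_reaction_smiles(t.clean_reaction_smiles)
        required = set(range(1, eq.n_precursors + 1)) | {
            -(k + 1) for k in range(eq.n_products)
        }
        assert required <= referenced_tokens(seq)
        assert len(seq) >= 5


def test_no_noise_limit_retains_everything(clean_corpus):
    stats = clean_corpus["stats"]
    assert stats.retained == stats.input_count
    assert stats.rejected == {}


def test_clean_records_recovered_exactly(clean_corpus):
    entries = {e.id: e for e in clean_corpus["dataset"]}
    recovered = 0
    for t in clean_corpus["truths"]:
        e = entries[t.id]
        assert e.reaction_smiles == t.clean_reaction_smiles
        assert e.action_text == t.clean_action_text
        recovered += 1
    assert recovered == len(clean_corpus["truths"])


def test_planted_defects_recovered_with_planted_counts(common_reagents):
    rates = {c: 0.02 for c in DEFECT_CATEGORIES}
    config = GeneratorConfig(
        n_records=1500, seed=31, defect_rates=rates, duplicate_rate=0.03
    )
    records, truths = generate(config)
    planted = Counter(t.defect for t in truths if t.defect)
    maps = build_name_maps(
        (n, s) for r in records for n, s in r.local_name_map.items()
    )
    _, stats = run_pipeline(
        records, PipelineConfig(name_maps=maps, common_reagents=common_reagents, seed=2)
    )
    assert stats.rejected == dict(planted)
    stats.check_conservation()


def test_defect_frequencies_within_binomial_bounds():
    rates = {"contains InvalidAction": 0.05, "too short action sequence": 0.1}
    n = 4000
    _, truths = generate(GeneratorConfig(n_records=n, seed=77, defect_rates=rates))
    counts = Counter(t.defect for t in truths if t.defect)
    for cat, rate in rates.items():
        sigma = (n * rate * (1 - rate)) ** 0.5
        assert abs(counts[cat] - n * rate) <= 3 * sigma


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(n_records=10, defect_rates={"contains InvalidAction": 1.5})
    with pytest.raises(ValueError):
        GeneratorConfig(n_records=10, defect_rates={"no such category": 0.1})
    with pytest.raises(ValueError):
        GeneratorConfig(
            n_records=10,
            defect_rates={c: 0.09 for c in DEFECT_CATEGORIES},
        )


def test_records_have_local_name_maps():
    records, _ = generate(GeneratorConfig(n_records=20, seed=3))
    for r in records:
        assert "title compound" in r.local_name_map
        assert len(r.local_name_map) >= 3
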