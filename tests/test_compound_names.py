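"""Name stripping, normalization, and modal name<->SMILES maps."""

import pytest
from hypothesis import given, settings, strategies as st

from smiles2actions.compound_names import (
    NameMaps,
    build_name_maps,
    canonical_synonym,
    normalize_name,
    strip_name,
)
from smiles2actions.errors import NameStrippingError


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("saturated solution of sulfuric acid", ["sulfuric acid"]),
        ("1.0 M DCM solution of boron tribromide", ["DCM", "boron tribromide"]),
        ("ethanol", ["ethanol"]),
        ("5 mL of a 1.0 M DCM solution of boron tribromide",
         ["DCM", "boron tribromide"]),
        ("cold water", ["water"]),
        ("solid sodium carbonate", ["sodium carbonate"]),
        ("HCl (aq)", ["HCl"]),
        ("10 wt% palladium on carbon", ["palladium on carbon"]),
        ("ethyl acetate/THF", ["ethyl acetate", "THF"]),
        ("1:1 dioxane-water", ["dioxane-water"]),
        ("concentrated hydrochloric acid", ["hydrochloric acid"]),
    ],
)
def test_strip_name(raw, expected):
    assert strip_name(raw) == expected


def test_strip_name_empty_result_raises():
    with pytest.raises(NameStrippingError):
        strip_name("saturated")
    with pytest.raises(NameStrippingError):
        strip_name("   ")


@pytest.mark.parametrize(
    "name,expected",
    [
        ("H_2_SO_4_", "h2so4"),  # subscript convention, then lowercase
        ("dimethyl sulfoxide", "dimethylsulfoxide"),
        ("NiCl2 ⋅ 6H2O", "nicl26h2o"),
        ("NiCl2 × 6H2O", "nicl26h2o"),
        ("alpha-glucose", "αglucose"),
        ("N,N′-dimethylformamide", "n,ndimethylformamide"),
    ],
)
def test_normalize_name(name, expected):
    assert normalize_name(name) == expected


def test_normalize_unifies_ocr_confusables():
    # I/1 -> l and 0 -> O must land corrupted spellings on the clean form
    assert normalize_name("ethano1") == normalize_name("ethanol")
    assert normalize_name("meth0xy") == normalize_name("methoxy")
    assert normalize_name("4–Fluoroaniline") == normalize_name("4-fluoroaniline")


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.text(min_size=0, max_size=40))
def test_normalize_idempotent(name):
    once = normalize_name(name)
    assert normalize_name(once) == once


def test_build_name_maps_modal_choice():
    pairs = [("DMSO", "CS(C)=O")] * 3 + [("dimethyl sulfoxide", "CS(C)=O")]
    maps = build_name_maps(pairs)
    assert maps.smiles_to_name["CS(C)=O"] == "DMSO"
    assert maps.name_to_smiles[normalize_name("dimethyl sulfoxide")] == "CS(C)=O"


def test_build_name_maps_empty():
    maps = build_name_maps([])
    assert maps.name_to_smiles == {} and maps.smiles_to_name == {}


def test_build_name_maps_tie_break_lexicographic():
    pairs = [("beta", "CCO")] * 2 + [("alpha", "CCO")] * 2
    maps = build_name_maps(pairs)
    assert maps.smiles_to_name["CCO"] == "alpha"


def test_build_name_maps_order_invariant():
    pairs = [("DMSO", "CS(C)=O"), ("water", "O"), ("DMSO", "CS(C)=O"),
             ("dimethyl sulfoxide", "CS(C)=O"), ("water", "O")]
    a = build_name_maps(pairs)
    b = build_name_maps(list(reversed(pairs)))
    assert a.name_to_smiles == b.name_to_smiles
    assert a.smiles_to_name == b.smiles_to_name


def test_build_name_maps_skips_unparseable():
    maps = build_name_maps([("junk", "C1CC"), ("water", "O")])
    assert maps.skipped == 1
    assert "water" in maps.name_to_smiles


def test_canonical_synonym():
    pairs = [("DMSO", "CS(C)=O")] * 3 + [("dimethyl sulfoxide", "CS(C)=O")]
    maps = build_name_maps(pairs)
    assert canonical_synonym("dimethyl sulfoxide", maps) == "DMSO"
    assert canonical_synonym("DMSO", maps) == "DMSO"  # fixed point
    assert canonical_synonym("unknownium", maps) is None


def test_name_maps_tsv_round_trip(tmp_path):
    maps = build_name_maps([("DMSO", "CS(C)=O"), ("water", "O")])
    maps.save(tmp_path / "maps")
    loaded = NameMaps.load(tmp_path / "maps")
    assert loaded.name_to_smiles == maps.name_to_smiles
    assert loaded.smiles_to_name == maps.smiles_to_name
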