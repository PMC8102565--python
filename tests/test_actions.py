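"""Action vocabulary: serialization grammar and lossless round trip."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from smiles2actions.actions import (
    Action,
    ActionSequence,
    CompoundRef,
    parse_action_text,
    referenced_tokens,
    render_action_text,
)
from smiles2actions.errors import ActionParseError, ActionRenderError

from conftest import CONDENSATION_ACTION_TEXT, AMINATION_NEIGHBOR_PREDICTION, AMINATION_TRANSFORMER_PREDICTION


@pytest.mark.parametrize(
    "action,expected",
    [
        (Action("STIR", duration=3, temperature=4), "STIR for @3@ at #4#"),
        (Action("FILTER", phase="precipitate"), "FILTER keep precipitate"),
        (
            Action("DRYSOLUTION", solvent=CompoundRef.named("Na2SO4")),
            "DRYSOLUTION over Na2SO4",
        ),
        (Action("ADD", compound=CompoundRef.positional(1)), "ADD $1$"),
        (
            Action("EXTRACT", solvent=CompoundRef.named("ethyl acetate/THF")),
            "EXTRACT with ethyl acetate/THF",
        ),
        (Action("YIELD", compound=CompoundRef.positional(-1)), "YIELD $-1$"),
        (
            Action(
                "MAKESOLUTION",
                components=(
                    CompoundRef.positional(1),
                    CompoundRef.named("water"),
                ),
            ),
            "MAKESOLUTION with $1$ and water",
        ),
        (Action("DRYSOLID", atmosphere="vacuum"), "DRYSOLID under vacuum"),
        (
            Action("WASH", solvent=CompoundRef.named("brine"), repetitions=3),
            "WASH with brine 3 x",
        ),
    ],
)
def test_render_examples(action, expected):
    assert render_action_text(ActionSequence((action,))) == expected
    # and each rendered clause parses back to the identical action
    assert parse_action_text(expected)[0] == action


@pytest.mark.parametrize(
    "text,n_actions",
    [
        (CONDENSATION_ACTION_TEXT, 8),
        (AMINATION_TRANSFORMER_PREDICTION, 10),
        (AMINATION_NEIGHBOR_PREDICTION, 17),
    ],
)
def test_printed_sequences_parse_and_round_trip(text, n_actions):
    seq = parse_action_text(text)
    assert len(seq) == n_actions
    assert render_action_text(seq) == text


def test_referenced_tokens_condensation_example():
    seq = parse_action_text(CONDENSATION_ACTION_TEXT)
    assert referenced_tokens(seq) == {1, 2, 3, 4, -1}


def test_referenced_tokens_nearest_neighbor_column():
    seq = parse_action_text(AMINATION_NEIGHBOR_PREDICTION)
    assert referenced_tokens(seq) == {1, 2, 3, 4, 5, -1}


def test_referenced_tokens_empty():
    assert referenced_tokens(ActionSequence(())) == set()


def test_referenced_tokens_embedded_in_multicomponent_name():
    seq = parse_action_text("EXTRACT with $2$/ethanol")
    assert referenced_tokens(seq) == {2}


@pytest.mark.parametrize(
    "text",
    [
        "FROB $1$",  # unknown action keyword
        "FILTER keep slime",  # invalid phase
        "ADD",  # missing mandatory compound
        "STIR banana",  # trailing garbage
        "",  # empty clause via split
    ],
)
def test_malformed_clause_raises(text):
    with pytest.raises(ActionParseError):
        parse_action_text(text + "; YIELD $-1$")


def test_parse_error_carries_clause_index():
    with pytest.raises(ActionParseError) as exc:
        parse_action_text("ADD $1$; FROB")
    assert exc.value.clause_index == 1


def test_render_error_names_action_index():
    seq = ActionSequence((Action("ADD", compound=CompoundRef.positional(1)),
                          Action("YIELD")))
    with pytest.raises(ActionRenderError) as exc:
        render_action_text(seq)
    assert exc.value.action_index == 1


def test_properties_not_admissible_for_type():
    with pytest.raises(ValueError):
        Action("CONCENTRATE", duration=2)
    with pytest.raises(ValueError):
        Action("STIR", phase="precipitate")


# ---------------------------------------------------------------------------
# property: parse(render(s)) == s
# ---------------------------------------------------------------------------

_WORDS = ["sodium", "acetate", "boron", "tribromide", "DMSO", "4-fluoroaniline",
          "Na2SO4", "brine", "THF", "N,N'-dimethylamine"]


def _random_ref(rng: random.Random) -> CompoundRef:
    if rng.random() < 0.5:
        k = rng.randint(1, 8)
        return CompoundRef.positional(k if rng.random() < 0.7 else -k)
    name = " ".join(rng.sample(_WORDS, rng.randint(1, 2)))
    if rng.random() < 0.2:
        name += "/" + rng.choice(_WORDS)
    return CompoundRef.named(name)


def _random_action(rng: random.Random) -> Action:
    t = rng.choice(
        ["ADD", "STIR", "FILTER", "RECRYSTALLIZE", "DRYSOLUTION", "EXTRACT",
         "WASH", "QUENCH", "PH", "REFLUX", "MICROWAVE", "SETTEMPERATURE",
         "WAIT", "MAKESOLUTION", "YIELD", "CONCENTRATE", "PURIFY",
         "COLLECTLAYER", "DRYSOLID"]
    )
    kw = {}
    if t in ("ADD", "QUENCH", "YIELD", "PH"):
        kw["compound"] = _random_ref(rng)
    if t in ("RECRYSTALLIZE", "DRYSOLUTION", "EXTRACT", "WASH") and rng.random() < 0.9:
        kw["solvent"] = _random_ref(rng)
    if t in ("STIR", "REFLUX", "MICROWAVE", "WAIT", "DRYSOLID") and rng.random() < 0.7:
        kw["duration"] = rng.randint(1, 5)
    if t in ("STIR", "MICROWAVE", "WAIT", "QUENCH", "ADD", "DRYSOLID") and rng.random() < 0.5:
        kw["temperature"] = rng.randint(1, 7)
    if t == "SETTEMPERATURE":
        kw["temperature"] = rng.randint(1, 7)
    if t == "PH" and rng.random() < 0.8:
        kw["ph"] = rng.randint(1, 5)
    if t == "FILTER" and rng.random() < 0.8:
        kw["phase"] = rng.choice(["precipitate", "filtrate"])
    if t == "DRYSOLID" and rng.random() < 0.3:
        kw["atmosphere"] = "vacuum"
    if t == "MAKESOLUTION":
        kw["components"] = tuple(_random_ref(rng) for _ in range(rng.randint(2, 4)))
    if t in ("EXTRACT", "WASH") and rng.random() < 0.3:
        kw["repetitions"] = rng.randint(2, 4)
    return Action(t, **kw)


def test_round_trip_ten_thousand_random_sequences():
    rng = random.Random(20240917)
    for _ in range(10_000):
        seq = ActionSequence(
            tuple(_random_action(rng) for _ in range(rng.randint(1, 6)))
        )
        text = render_action_text(seq)
        assert parse_action_text(text) == seq
        # render is deterministic
        assert render_action_text(seq) == text


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**63 - 1))
def test_round_trip_hypothesis_seeded(seed):
    rng = random.Random(seed)
    seq = ActionSequence(tuple(_random_action(rng) for _ in range(rng.randint(0, 8))))
    assert parse_action_text(render_action_text(seq)) == seq


def test_json_round_trip():
    rng = random.Random(3)
    seq = ActionSequence(tuple(_random_action(rng) for _ in range(6)))
    assert ActionSequence.from_dicts(seq.to_dicts()) == seq
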