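"""Shared fixtures: small synthetic corpora and pipeline outputs.

Everything is generated programmatically at test time; session scope
keeps the expensive RDKit canonicalization work to one pass.
"""

import pytest

from smiles2actions.cli import _load_reagents
from smiles2actions.compound_names import build_name_maps
from smiles2actions.pipeline import PipelineConfig, run_pipeline, split_dataset
from smiles2actions.synthetic import GeneratorConfig, generate

# printed worked example: amide condensation between a quinolinone acid and
# aniline, mediated by DCC in DCM
CONDENSATION_REACTION_SMILES = (
    "C(=NC1CCCCC1)=NC1CCCCC1.ClCCl.CC1(C)CC(=O)Nc2cc(C(=O)O)ccc21.Nc1ccccc1"
    ">>CC1(C)CC(=O)Nc2cc(C(=O)Nc3ccccc3)ccc21"
)

CONDENSATION_ACTION_TEXT = (
    "ADD $1$; ADD $4$; ADD $2$; ADD $3$; STIR for @3@ at #4#; "
    "FILTER keep precipitate; RECRYSTALLIZE from ethanol; YIELD $-1$"
)

# reductive-amination test-set example: ground truth and the transformer
# prediction, which inserts one extra Stir action before the reductant
AMINATION_GROUND_TRUTH = (
    "ADD $2$; ADD $4$; ADD $3$; ADD $1$; ADD $5$; STIR for @4@ at #4#; "
    "CONCENTRATE; PURIFY; YIELD $-1$"
)
AMINATION_TRANSFORMER_PREDICTION = (
    "ADD $2$; ADD $4$; ADD $3$; ADD $1$; STIR for @2@ at #4#; ADD $5$; "
    "STIR for @4@ at #4#; CONCENTRATE; PURIFY; YIELD $-1$"
)
AMINATION_NEIGHBOR_PREDICTION = (
    "ADD $4$; ADD $3$; ADD $5$ at #4#; ADD $1$ at #4#; STIR for @1@ at #4#; "
    "ADD $2$; STIR for @4@; QUENCH with water; CONCENTRATE; "
    "EXTRACT with ethyl acetate/THF; WASH with brine; DRYSOLUTION over Na2SO4; "
    "FILTER keep filtrate; CONCENTRATE; ADD THF; PURIFY; YIELD $-1$"
)


@pytest.fixture(scope="session")
def common_reagents():
    return _load_reagents(None)


@pytest.fixture(scope="session")
def clean_corpus(common_reagents):
    """400 noise-free-defect-free records run through the pipeline."""
    records, truths = generate(GeneratorConfig(n_records=400, seed=5))
    maps = build_name_maps(
        (n, s) for r in records for n, s in r.local_name_map.items()
    )
    config = PipelineConfig(name_maps=maps, common_reagents=common_reagents, seed=1)
    dataset, stats = run_pipeline(records, config)
    return {
        "records": records,
        "truths": truths,
        "dataset": dataset,
        "stats": stats,
        "config": config,
    }


@pytest.fixture(scope="session")
def corpus_splits(clean_corpus):
    train, valid, test = split_dataset(clean_corpus["dataset"], (0.8, 0.1, 0.1), seed=2)
    return train, valid, test
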