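"""Translation model: corpus preparation, training mechanics, decoding.

These tests keep the networks tiny; the full desk-scale overfitting run
lives with the acceptance checks.
"""

import dataclasses

import numpy as np
import pytest

from smiles2actions import seq2seq
from smiles2actions.actions import parse_action_text
from smiles2actions.reaction_smiles import detokenize_smiles
from smiles2actions.seq2seq import Seq2SeqConfig
from smiles2actions.seq2seq.autograd import Tensor


TINY = Seq2SeqConfig(
    layers=1,
    hidden_size=32,
    embedding_size=32,
    attention_heads=4,
    accumulation_count=1,
    batch_size=8,
    steps=30,
    seed=0,
)


@pytest.fixture(scope="module")
def tiny_corpus(clean_corpus):
    dataset = clean_corpus["dataset"][:24]
    return seq2seq.prepare_corpus(dataset)


def test_prepare_corpus_aligned_and_parseable(clean_corpus, tmp_path):
    dataset = clean_corpus["dataset"][:10]
    src_path = tmp_path / "src.txt"
    tgt_path = tmp_path / "tgt.txt"
    sources, targets = seq2seq.prepare_corpus(dataset, str(src_path), str(tgt_path))
    assert len(sources) == len(targets) == 10
    assert src_path.read_text().count("\n") == 10
    for s, t, e in zip(sources, targets, dataset):
        assert detokenize_smiles(s) == e.reaction_smiles
        # condition/compound tokens are atomic whitespace tokens
        for tok in t.split():
            if tok.startswith(("$", "@", "#")):
                assert tok.rstrip(";") == tok or tok.endswith(";")
        assert parse_action_text(" ".join(t.split())) is not None


def test_training_loss_decreases(tiny_corpus):
    sources, targets = tiny_corpus
    model = seq2seq.train(sources, targets, TINY)
    assert len(model.training_log) == TINY.steps
    assert model.training_log[-1] < model.training_log[0]
    assert all(np.isfinite(l) for l in model.training_log)


def test_training_deterministic_given_seed(tiny_corpus):
    sources, targets = tiny_corpus
    a = seq2seq.train(sources, targets, TINY)
    b = seq2seq.train(sources, targets, TINY)
    assert a.training_log == b.training_log


def test_label_smoothing_zero_is_plain_cross_entropy():
    rng = np.random.default_rng(0)
    logits = Tensor(rng.normal(size=(6, 9)).astype(np.float32))
    targets = rng.integers(0, 9, size=6)
    mask = np.ones(6, dtype=np.float32)
    plain = logits.cross_entropy(targets, mask, label_smoothing=0.0)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    expected = -logp[np.arange(6), targets].mean()
    assert float(plain.data) == pytest.approx(expected, abs=1e-6)
    smoothed = logits.cross_entropy(targets, mask, label_smoothing=0.1)
    assert float(smoothed.data) != pytest.approx(expected, abs=1e-6)


def test_decoding_deterministic_and_beam1_equals_greedy(tiny_corpus):
    sources, targets = tiny_corpus
    model = seq2seq.train(sources, targets, TINY)
    rxn = detokenize_smiles(sources[0])
    t1, s1 = seq2seq.decode(model, rxn, beam=1)
    t2, s2 = seq2seq.decode(model, rxn, beam=1)
    assert (t1, s1) == (t2, s2)


def test_beam5_score_at_least_beam1(tiny_corpus):
    sources, targets = tiny_corpus
    model = seq2seq.train(sources, targets, TINY)
    for s in sources[:3]:
        rxn = detokenize_smiles(s)
        _, greedy = seq2seq.decode(model, rxn, beam=1)
        _, beamed = seq2seq.decode(model, rxn, beam=5)
        assert beamed >= greedy - 1e-6


def test_output_vocabulary_closed(tiny_corpus):
    sources, targets = tiny_corpus
    model = seq2seq.train(sources, targets, TINY)
    train_vocab = set(tok for t in targets for tok in t.split())
    for s in sources[:5]:
        text, _ = seq2seq.decode(model, detokenize_smiles(s), beam=1)
        for tok in text.split():
            assert tok in train_vocab | set(("<unk>",))


def test_model_save_load_round_trip(tiny_corpus, tmp_path):
    sources, targets = tiny_corpus
    model = seq2seq.train(sources, targets, TINY)
    model.save(tmp_path / "model")
    loaded = seq2seq.Seq2SeqModel.load(str(tmp_path / "model"))
    rxn = detokenize_smiles(sources[0])
    assert seq2seq.decode(loaded, rxn, beam=1) == seq2seq.decode(model, rxn, beam=1)


def test_config_validation():
    with pytest.raises(ValueError):
        Seq2SeqConfig(layers=0)
    with pytest.raises(ValueError):
        Seq2SeqConfig(label_smoothing=1.0)
    with pytest.raises(ValueError):
        Seq2SeqConfig(hidden_size=128, embedding_size=64)
    with pytest.raises(NotImplementedError):
        Seq2SeqConfig(architecture="bart")


def test_corpus_length_mismatch():
    with pytest.raises(ValueError):
        seq2seq.train(["C C"], [], TINY)


def test_autograd_matches_numeric_gradient():
    rng = np.random.default_rng(1)
    w = Tensor(rng.normal(size=(4, 3)).astype(np.float32))
    w.requires_grad = True
    x = Tensor(rng.normal(size=(2, 4)).astype(np.float32))
    targets = np.array([0, 2])
    mask = np.ones(2, dtype=np.float32)
    out = x.matmul(w).cross_entropy(targets, mask)
    out.backward()
    analytic = w.grad.copy()
    eps = 1e-3
    for i, j in [(0, 0), (1, 2), (3, 1)]:
        w2 = w.data.copy()
        w2[i, j] += eps
        za = Tensor(x.data).matmul(Tensor(w2)).cross_entropy(targets, mask)
        w2[i, j] -= 2 * eps
        zb = Tensor(x.data).matmul(Tensor(w2)).cross_entropy(targets, mask)
        numeric = (float(za.data) - float(zb.data)) / (2 * eps)
        assert analytic[i, j] == pytest.approx(numeric, abs=5e-3)
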