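"""Sequence-to-sequence prediction of action text from reaction SMILES.

Treats procedure prediction as translation: the tokenized reaction
SMILES is the source sentence, the serialized action sequence (with
positional compound tokens and interval condition tokens as atomic
words) is the target sentence.  The trainer ships two profiles:

* ``paper``: 4 layers, 256 hidden/embedding units, 8 attention heads,
  gradient accumulation 4, label smoothing 0 — the configuration used
  at corpus scale;
* ``desk``: 2 layers, 128 hidden units — small enough to train on a
  laptop CPU against synthetic corpora.

The trainer interface takes an architecture name so that alternative
encoder-decoder architectures (e.g. BART-style pretrained models) can be
registered; only the transformer is implemented here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..errors import Smiles2ActionsError
from ..pipeline import DatasetEntry
from ..reaction_smiles import (
    ReactionEquation,
    parse_reaction_smiles,
    serialize_equation,
    tokenize_smiles,
)
from .autograd import Adam, Tensor, no_grad
from .model import TransformerModel

__all__ = [
    "Seq2SeqConfig",
    "PROFILES",
    "Seq2SeqModel",
    "prepare_corpus",
    "train",
    "decode",
]

PAD, BOS, EOS, UNK = 0, 1, 2, 3
_SPECIALS = ("<pad>", "<bos>", "<eos>", "<unk>")


@dataclass
class Seq2SeqConfig:
    """Hyperparameters of the translation model and its training run."""

    architecture: str = "transformer"
    layers: int = 4
    hidden_size: int = 256
    embedding_size: int = 256
    attention_heads: int = 8
    ffn_size: Optional[int] = None
    accumulation_count: int = 4
    label_smoothing: float = 0.0
    batch_size: int = 16
    steps: int = 1000
    learning_rate: float = 1e-3
    warmup_steps: int = 40
    seed: int = 0
    beam_width: int = 1
    max_output_tokens: int = 200

    def __post_init__(self) -> None:
        for name in (
            "layers",
            "hidden_size",
            "embedding_size",
            "attention_heads",
            "accumulation_count",
            "batch_size",
            "steps",
            "beam_width",
            "max_output_tokens",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label smoothing must lie in [0, 1)")
        if self.embedding_size != self.hidden_size:
            raise ValueError(
                "this implementation ties embedding size to hidden size"
            )
        if self.architecture != "transformer":
            raise NotImplementedError(
                f"architecture {self.architecture!r} is not packaged; "
                "register an implementation to use it"
            )


PROFILES: Dict[str, Seq2SeqConfig] = {
    "paper": Seq2SeqConfig(
        layers=4,
        hidden_size=256,
        embedding_size=256,
        attention_heads=8,
        accumulation_count=4,
        label_smoothing=0.0,
        batch_size=64,
        steps=200000,
    ),
    "desk": Seq2SeqConfig(
        layers=2,
        hidden_size=128,
        embedding_size=128,
        attention_heads=8,
        accumulation_count=1,
        label_smoothing=0.0,
        batch_size=20,
        steps=400,
    ),
}


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

def prepare_corpus(
    dataset: Sequence[DatasetEntry],
    src_path: Optional[str] = None,
    tgt_path: Optional[str] = None,
) -> Tuple[List[str], List[str]]:
    """Line-aligned source/target corpora.

    Source lines are tokenized reaction SMILES; target lines are the
    serialized action text, whose whitespace tokens already keep "$k$",
    "@k@" and "#k#" atomic.  Optionally written to files.
    """
    sources = [tokenize_smiles(e.reaction_smiles) for e in dataset]
    targets = [e.action_text for e in dataset]
    if len(sources) != len(targets):  # pragma: no cover - construction
        raise Smiles2ActionsError("source/target length mismatch")
    if src_path:
        Path(src_path).parent.mkdir(parents=True, exist_ok=True)
        Path(src_path).write_text("".join(s + "\n" for s in sources), "utf-8")
    if tgt_path:
        Path(tgt_path).parent.mkdir(parents=True, exist_ok=True)
        Path(tgt_path).write_text("".join(t + "\n" for t in targets), "utf-8")
    return sources, targets


def _build_vocab(lines: Sequence[str]) -> Dict[str, int]:
    vocab = {tok: i for i, tok in enumerate(_SPECIALS)}
    for line in lines:
        for tok in line.split():
            if tok not in vocab:
                vocab[tok] = len(vocab)
    return vocab


def _encode(line: str, vocab: Dict[str, int], add_eos: bool) -> List[int]:
    ids = [vocab.get(tok, UNK) for tok in line.split()]
    return ids + [EOS] if add_eos else ids


def _pad_batch(seqs: List[List[int]]) -> Tuple[np.ndarray, np.ndarray]:
    width = max(len(s) for s in seqs)
    ids = np.zeros((len(seqs), width), dtype=np.int64)
    mask = np.zeros((len(seqs), width), dtype=np.float32)
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s
        mask[i, : len(s)] = 1.0
    return ids, mask


# ---------------------------------------------------------------------------
# model artifact
# ---------------------------------------------------------------------------

@dataclass
class Seq2SeqModel:
    """Trained model artifact: network weights plus both vocabularies."""

    config: Seq2SeqConfig
    src_vocab: Dict[str, int]
    tgt_vocab: Dict[str, int]
    network: TransformerModel
    training_log: List[float] = field(default_factory=list)

    @property
    def tgt_itos(self) -> List[str]:
        itos = [""] * len(self.tgt_vocab)
        for tok, i in self.tgt_vocab.items():
            itos[i] = tok
        return itos

    def save(self, directory: str) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(json.dumps(asdict(self.config)), "utf-8")
        (d / "vocab.json").write_text(
            json.dumps({"src": self.src_vocab, "tgt": self.tgt_vocab}), "utf-8"
        )
        (d / "log.json").write_text(json.dumps(self.training_log), "utf-8")
        np.savez(d / "weights.npz", **self.network.state_dict())

    @classmethod
    def load(cls, directory: str) -> "Seq2SeqModel":
        d = Path(directory)
        config = Seq2SeqConfig(**json.loads((d / "config.json").read_text("utf-8")))
        vocabs = json.loads((d / "vocab.json").read_text("utf-8"))
        network = TransformerModel(
            src_vocab=len(vocabs["src"]),
            tgt_vocab=len(vocabs["tgt"]),
            layers=config.layers,
            hidden=config.hidden_size,
            heads=config.attention_heads,
            ffn=config.ffn_size,
            seed=config.seed,
        )
        with np.load(d / "weights.npz") as data:
            network.load_state_dict({k: data[k] for k in data.files})
        log = json.loads((d / "log.json").read_text("utf-8"))
        return cls(config, vocabs["src"], vocabs["tgt"], network, log)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(
    sources: Sequence[str],
    targets: Sequence[str],
    config: Seq2SeqConfig,
) -> Seq2SeqModel:
    """Train the translation model by minimizing categorical
    cross-entropy on the output words.

    Deterministic given the seed (single device).  Aborts with a
    diagnostic if the loss turns non-finite.
    """
    if len(sources) != len(targets):
        raise ValueError("source/target corpora must align")
    if not sources:
        raise ValueError("empty corpus")
    src_vocab = _build_vocab(sources)
    tgt_vocab = _build_vocab(targets)
    network = TransformerModel(
        src_vocab=len(src_vocab),
        tgt_vocab=len(tgt_vocab),
        layers=config.layers,
        hidden=config.hidden_size,
        heads=config.attention_heads,
        ffn=config.ffn_size,
        seed=config.seed,
    )
    src_ids = [_encode(s, src_vocab, add_eos=True) for s in sources]
    tgt_ids = [_encode(t, tgt_vocab, add_eos=True) for t in targets]

    opt = Adam(network.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = len(src_ids)
    order = rng.permutation(n)
    cursor = 0
    log: List[float] = []

    for step in range(config.steps):
        lr = config.learning_rate * min(
            1.0, (step + 1) / max(config.warmup_steps, 1)
        )
        opt.zero_grad()
        accum_loss = 0.0
        for _ in range(config.accumulation_count):
            take = min(config.batch_size, n)
            if cursor + take > n:
                order = rng.permutation(n)
                cursor = 0
            batch = order[cursor : cursor + take]
            cursor += take
            sb, sm = _pad_batch([src_ids[i] for i in batch])
            tb, tm = _pad_batch([[BOS] + tgt_ids[i] for i in batch])
            memory = network.encode(sb, sm)
            logits = network.decode_logits(memory, sm, tb[:, :-1])
            b, l, v = logits.shape
            loss = logits.reshape(b * l, v).cross_entropy(
                tb[:, 1:].reshape(-1),
                tm[:, 1:].reshape(-1),
                label_smoothing=config.label_smoothing,
            )
            (loss * (1.0 / config.accumulation_count)).backward()
            accum_loss += float(loss.data) / config.accumulation_count
        if not math.isfinite(accum_loss):
            raise Smiles2ActionsError(
                f"training diverged at step {step}: loss {accum_loss}"
            )
        opt.step(lr=lr)
        log.append(accum_loss)
    return Seq2SeqModel(config, src_vocab, tgt_vocab, network, log)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _log_softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def decode(
    model: Seq2SeqModel,
    eq,
    beam: int = 1,
    max_len: Optional[int] = None,
) -> Tuple[str, float]:
    """Beam-search decode (beam=1 is greedy) into action text.

    Returns (text, cumulative log-probability of the emitted tokens).
    The best-scoring finished hypothesis is returned even if the text
    does not parse; validity is judged downstream.
    """
    if isinstance(eq, ReactionEquation):
        source = tokenize_smiles(serialize_equation(eq))
    else:
        source = tokenize_smiles(serialize_equation(parse_reaction_smiles(str(eq))))
    if beam < 1:
        raise ValueError("beam width must be positive")
    max_len = max_len or model.config.max_output_tokens
    itos = model.tgt_itos
    src = [_encode(source, model.src_vocab, add_eos=True)]
    sb, sm = _pad_batch(src)
    with no_grad():
        memory = model.network.encode(sb, sm)
        hyps: List[Tuple[List[int], float, bool]] = [([BOS], 0.0, False)]
        for _ in range(max_len):
            if all(done for _, _, done in hyps):
                break
            candidates: List[Tuple[List[int], float, bool]] = []
            for seq, score, done in hyps:
                if done:
                    candidates.append((seq, score, done))
                    continue
                tb = np.asarray([seq], dtype=np.int64)
                logits = model.network.decode_logits(memory, sm, tb)
                logp = _log_softmax(logits.data[0, -1])
                top = np.argsort(-logp, kind="stable")[:beam]
                for tok in top:
                    tok = int(tok)
                    candidates.append(
                        (seq + [tok], score + float(logp[tok]), tok == EOS)
                    )
            candidates.sort(key=lambda c: (-c[1], c[0]))
            hyps = candidates[:beam]
        best_seq, best_score, _ = max(hyps, key=lambda c: c[1])
    tokens = [itos[t] for t in best_seq[1:] if t not in (EOS, PAD, BOS)]
    return " ".join(tokens), best_score
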