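"""Transformer encoder-decoder over the autodiff core.

A standard pre-norm transformer: sinusoidal positions, multi-head scaled
dot-product attention, ReLU feed-forward blocks, residual connections,
and a final projection onto the target vocabulary.  Sized for desk-scale
corpora; the architecture follows the usual encoder-decoder translation
setup with the reaction SMILES as the source sentence and the action
text as the target sentence.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional

import numpy as np

from .autograd import Tensor

__all__ = ["TransformerModel"]

NEG_INF = np.float32(-1e9)


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(np.float32)


class TransformerModel:
    """Encoder-decoder transformer with explicit parameter dictionary."""

    def __init__(
        self,
        src_vocab: int,
        tgt_vocab: int,
        layers: int = 2,
        hidden: int = 128,
        heads: int = 8,
        ffn: Optional[int] = None,
        seed: int = 0,
    ):
        if hidden % heads != 0:
            raise ValueError("hidden size must be divisible by the head count")
        self.src_vocab = src_vocab
        self.tgt_vocab = tgt_vocab
        self.layers = layers
        self.hidden = hidden
        self.heads = heads
        self.ffn = ffn or 4 * hidden
        self.params: Dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        self._init_params(rng)

    # ------------------------------------------------------------------
    # parameters
    # ------------------------------------------------------------------

    def _param(self, name: str, shape, rng, scale: Optional[float] = None) -> Tensor:
        if scale is None:
            scale = 1.0 / math.sqrt(shape[0])
        t = Tensor(rng.normal(0.0, scale, size=shape).astype(np.float32))
        t.requires_grad = True
        self.params[name] = t
        return t

    def _init_params(self, rng) -> None:
        d, f = self.hidden, self.ffn
        self._param("src_emb", (self.src_vocab, d), rng, scale=0.02)
        self._param("tgt_emb", (self.tgt_vocab, d), rng, scale=0.02)
        for side, n in (("enc", self.layers), ("dec", self.layers)):
            for l in range(n):
                p = f"{side}{l}."
                blocks = ["self"] if side == "enc" else ["self", "cross"]
                for blk in blocks:
                    for w in ("wq", "wk", "wv", "wo"):
                        self._param(p + blk + "." + w, (d, d), rng)
                    self._param(p + blk + ".ln_g", (d,), rng, scale=0.0)
                    self.params[p + blk + ".ln_g"].data += 1.0
                    self._param(p + blk + ".ln_b", (d,), rng, scale=0.0)
                self._param(p + "ffn.w1", (d, f), rng)
                self._param(p + "ffn.w2", (f, d), rng)
                self._param(p + "ffn.ln_g", (d,), rng, scale=0.0)
                self.params[p + "ffn.ln_g"].data += 1.0
                self._param(p + "ffn.ln_b", (d,), rng, scale=0.0)
        for side in ("enc", "dec"):
            self._param(side + ".final_ln_g", (self.hidden,), rng, scale=0.0)
            self.params[side + ".final_ln_g"].data += 1.0
            self._param(side + ".final_ln_b", (self.hidden,), rng, scale=0.0)
        self._param("out_proj", (d, self.tgt_vocab), rng)

    def parameters(self) -> List[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    # ------------------------------------------------------------------
    # blocks
    # ------------------------------------------------------------------

    def _attention(
        self,
        prefix: str,
        x: Tensor,
        memory: Tensor,
        bias: Optional[np.ndarray],
    ) -> Tensor:
        """Multi-head attention of x over memory with an additive bias
        (mask) on the attention logits."""
        p = self.params
        b, lq, d = x.shape
        lk = memory.shape[1]
        h, dh = self.heads, d // self.heads

        def split(t: Tensor, length: int) -> Tensor:
            return t.reshape(b, length, h, dh).transpose(0, 2, 1, 3)

        q = split(x.matmul(p[prefix + "wq"]), lq)
        k = split(memory.matmul(p[prefix + "wk"]), lk)
        v = split(memory.matmul(p[prefix + "wv"]), lk)
        logits = q.matmul(k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        attn = logits.softmax(bias)
        ctx = attn.matmul(v).transpose(0, 2, 1, 3).reshape(b, lq, d)
        return ctx.matmul(p[prefix + "wo"])

    def _block(self, prefix: str, blk: str, x: Tensor, memory: Tensor, bias) -> Tensor:
        p = self.params
        normed = x.layer_norm(p[prefix + blk + ".ln_g"], p[prefix + blk + ".ln_b"])
        mem = normed if blk == "self" else memory
        return x + self._attention(prefix + blk + ".", normed, mem, bias)

    def _ffn(self, prefix: str, x: Tensor) -> Tensor:
        p = self.params
        normed = x.layer_norm(p[prefix + "ffn.ln_g"], p[prefix + "ffn.ln_b"])
        return x + normed.matmul(p[prefix + "ffn.w1"]).relu().matmul(
            p[prefix + "ffn.w2"]
        )

    # ------------------------------------------------------------------
    # forward
    # ------------------------------------------------------------------

    @staticmethod
    def _pad_bias(pad_mask: np.ndarray) -> np.ndarray:
        # pad_mask: (B, Lk) with 1 for real tokens -> bias (B, 1, 1, Lk)
        return np.where(pad_mask[:, None, None, :] > 0, np.float32(0), NEG_INF)

    def encode(self, src_ids: np.ndarray, src_mask: np.ndarray) -> Tensor:
        d = self.hidden
        x = self.params["src_emb"].embedding(src_ids) * math.sqrt(d)
        x = x + Tensor(sinusoidal_positions(src_ids.shape[1], d)[None, :, :])
        bias = self._pad_bias(src_mask)
        for l in range(self.layers):
            prefix = f"enc{l}."
            x = self._block(prefix, "self", x, x, bias)
            x = self._ffn(prefix, x)
        return x.layer_norm(
            self.params["enc.final_ln_g"], self.params["enc.final_ln_b"]
        )

    def decode_logits(
        self,
        memory: Tensor,
        src_mask: np.ndarray,
        tgt_ids: np.ndarray,
    ) -> Tensor:
        """Logits (B, Lt, V) for next-token prediction at every position."""
        d = self.hidden
        b, lt = tgt_ids.shape
        x = self.params["tgt_emb"].embedding(tgt_ids) * math.sqrt(d)
        x = x + Tensor(sinusoidal_positions(lt, d)[None, :, :])
        causal = np.triu(np.full((lt, lt), NEG_INF, dtype=np.float32), k=1)
        self_bias = causal[None, None, :, :]
        cross_bias = self._pad_bias(src_mask)
        for l in range(self.layers):
            prefix = f"dec{l}."
            x = self._block(prefix, "self", x, x, self_bias)
            x = self._block(prefix, "cross", x, memory, cross_bias)
            x = self._ffn(prefix, x)
        x = x.layer_norm(
            self.params["dec.final_ln_g"], self.params["dec.final_ln_b"]
        )
        return x.matmul(self.params["out_proj"])

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data for k, v in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unexpected parameter {k!r}")
            self.params[k].data = np.asarray(v, dtype=np.float32)
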