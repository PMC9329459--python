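"""Decoder-only autoregressive language model over token sequences.

The model factorizes the probability of a token sequence W as
p(W) = Π_i p(w_i | w_<i) and is trained by minimizing the mean negative
log-likelihood (cross-entropy, nats per token) over a corpus.  The
architecture is a standard pre-norm transformer decoder: learned token and
positional embeddings, multi-head scaled dot-product self-attention with a
causal mask, GELU feed-forward blocks, and an untied output head.

The output head is zero-initialized, so a freshly constructed model assigns
the exact uniform distribution 1/V to every token — a convenient analytic
anchor (loss ln V, perplexity V) used throughout the test battery.

Everything — forward pass, backpropagation, Adam — is implemented directly
in numpy, which is fast enough for the desk-scale configurations this
package targets (a few layers, widths ≤ a few hundred).  The full-scale
configuration (36 layers, width 1280, 512-token blocks) is retained as a
named preset for completeness; training it requires accelerator hardware
and is out of scope here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from os import PathLike
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LMConfig",
    "LanguageModel",
    "TokenBlock",
    "paper_scale_config",
    "blockize",
    "clm_loss",
    "perplexity",
    "train",
]


@dataclass(frozen=True)
class LMConfig:
    """Architecture and optimization hyperparameters.

    Desk defaults (4 layers, width 128, 4 heads, 256-token context) train in
    minutes on one CPU; all fields are free to shrink further for tests.
    """

    vocab_size: int
    n_layers: int = 4
    d_model: int = 128
    n_heads: int = 4
    context_length: int = 256
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_tokens: int = 4096
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 2:
            raise ValueError("vocab_size must be >= 2")
        if self.context_length < 2:
            raise ValueError("context_length must be >= 2")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")


def paper_scale_config(vocab_size: int = 50_256) -> LMConfig:
    """The full-scale GPT-2-large-shaped preset: 36 layers, width 1280,
    20 heads, 512-token blocks, Adam(0.9, 0.999) at learning rate 1e-3,
    65,536 tokens per batch.  Provided as a reference configuration; not
    trainable at desk scale."""
    return LMConfig(
        vocab_size=vocab_size,
        n_layers=36,
        d_model=1280,
        n_heads=20,
        context_length=512,
        learning_rate=1e-3,
        batch_tokens=65_536,
    )


@dataclass(frozen=True)
class TokenBlock:
    """A bounded run of token ids fed to the model as one training example."""

    ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.ids)


def blockize(
    token_sequences: Sequence[Sequence[int]],
    context_length: int,
    eos_id: int,
) -> list[TokenBlock]:
    """Concatenate token sequences with EOS separators and chunk them.

    Every sequence is followed by one EOS token; the resulting stream is cut
    into blocks of ``context_length`` tokens.  A trailing block shorter than
    2 tokens (nothing to predict) is dropped.
    """
    stream: list[int] = []
    for ids in token_sequences:
        stream.extend(int(i) for i in ids)
        stream.append(int(eos_id))
    blocks = []
    for start in range(0, len(stream), context_length):
        chunk = stream[start : start + context_length]
        if len(chunk) >= 2:
            blocks.append(TokenBlock(ids=tuple(chunk)))
    return blocks


# ---------------------------------------------------------------------------
# numerical primitives
# ---------------------------------------------------------------------------


def _layernorm_forward(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_backward(dy, cache):
    xhat, inv, g = cache
    N = xhat.shape[-1]
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dx = (
        inv
        / N
        * (
            N * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )
    )
    return dx, dg, db


_GELU_C = math.sqrt(2.0 / math.pi)


def _gelu_forward(x):
    inner = _GELU_C * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    return 0.5 * x * (1.0 + t), (x, t)


def _gelu_backward(dy, cache):
    x, t = cache
    dinner = _GELU_C * (1.0 + 3 * 0.044715 * x**2)
    return dy * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner)


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class LanguageModel:
    """A trainable causal transformer exposing next-token distributions."""

    def __init__(self, config: LMConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        D, V, C, L = config.d_model, config.vocab_size, config.context_length, config.n_layers
        scale = 0.02
        resid_scale = scale / math.sqrt(2 * L)
        p: dict[str, np.ndarray] = {}
        p["wte"] = rng.normal(0, scale, (V, D))
        p["wpe"] = rng.normal(0, scale, (C, D))
        for l in range(L):
            p[f"h{l}.ln1.g"] = np.ones(D)
            p[f"h{l}.ln1.b"] = np.zeros(D)
            p[f"h{l}.qkv.w"] = rng.normal(0, scale, (D, 3 * D))
            p[f"h{l}.qkv.b"] = np.zeros(3 * D)
            p[f"h{l}.proj.w"] = rng.normal(0, resid_scale, (D, D))
            p[f"h{l}.proj.b"] = np.zeros(D)
            p[f"h{l}.ln2.g"] = np.ones(D)
            p[f"h{l}.ln2.b"] = np.zeros(D)
            p[f"h{l}.fc.w"] = rng.normal(0, scale, (D, 4 * D))
            p[f"h{l}.fc.b"] = np.zeros(4 * D)
            p[f"h{l}.out.w"] = rng.normal(0, resid_scale, (4 * D, D))
            p[f"h{l}.out.b"] = np.zeros(D)
        p["lnf.g"] = np.ones(D)
        p["lnf.b"] = np.zeros(D)
        # zero-initialized untied head: fresh model is exactly uniform
        p["head.w"] = np.zeros((D, V))
        p["head.b"] = np.zeros(V)
        self.params = p
        self._adam_m: dict[str, np.ndarray] | None = None
        self._adam_v: dict[str, np.ndarray] | None = None
        self._adam_t = 0

    # -- forward ----------------------------------------------------------

    def _forward(self, ids: np.ndarray, with_cache: bool = False):
        """Run the network on an int array of shape (B, T); return logits."""
        cfg, p = self.config, self.params
        B, T = ids.shape
        if T > cfg.context_length:
            raise ValueError(f"context of {T} tokens exceeds context_length {cfg.context_length}")
        H = cfg.n_heads
        D = cfg.d_model
        hd = D // H
        x = p["wte"][ids] + p["wpe"][:T][None, :, :]
        mask = np.triu(np.full((T, T), -1e30), k=1)
        caches = []
        for l in range(cfg.n_layers):
            a, ln1c = _layernorm_forward(x, p[f"h{l}.ln1.g"], p[f"h{l}.ln1.b"])
            qkv = a @ p[f"h{l}.qkv.w"] + p[f"h{l}.qkv.b"]
            q, k, v = np.split(qkv, 3, axis=-1)
            q = q.reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            k = k.reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            v = v.reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(hd) + mask
            att = _softmax(scores)
            o = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
            proj = o @ p[f"h{l}.proj.w"] + p[f"h{l}.proj.b"]
            x_attn = x + proj
            m, ln2c = _layernorm_forward(x_attn, p[f"h{l}.ln2.g"], p[f"h{l}.ln2.b"])
            hpre = m @ p[f"h{l}.fc.w"] + p[f"h{l}.fc.b"]
            hact, geluc = _gelu_forward(hpre)
            mlp = hact @ p[f"h{l}.out.w"] + p[f"h{l}.out.b"]
            x_out = x_attn + mlp
            if with_cache:
                caches.append((a, ln1c, q, k, v, att, o, x_attn, m, ln2c, geluc, hact))
            x = x_out
        xf, lnfc = _layernorm_forward(x, p["lnf.g"], p["lnf.b"])
        logits = xf @ p["head.w"] + p["head.b"]
        if with_cache:
            return logits, (ids, caches, xf, lnfc, mask)
        return logits

    def _backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        cfg, p = self.config, self.params
        ids, caches, xf, lnfc, mask = cache
        B, T = ids.shape
        H, D = cfg.n_heads, cfg.d_model
        hd = D // H
        g: dict[str, np.ndarray] = {}
        flat = lambda arr: arr.reshape(-1, arr.shape[-1])

        g["head.w"] = flat(xf).T @ flat(dlogits)
        g["head.b"] = flat(dlogits).sum(axis=0)
        dxf = dlogits @ p["head.w"].T
        dx, g["lnf.g"], g["lnf.b"] = _layernorm_backward(dxf, lnfc)

        for l in reversed(range(cfg.n_layers)):
            a, ln1c, q, k, v, att, o, x_attn, m, ln2c, geluc, hact = caches[l]
            # mlp branch
            dmlp = dx
            g[f"h{l}.out.w"] = flat(hact).T @ flat(dmlp)
            g[f"h{l}.out.b"] = flat(dmlp).sum(axis=0)
            dhact = dmlp @ p[f"h{l}.out.w"].T
            dhpre = _gelu_backward(dhact, geluc)
            g[f"h{l}.fc.w"] = flat(m).T @ flat(dhpre)
            g[f"h{l}.fc.b"] = flat(dhpre).sum(axis=0)
            dm = dhpre @ p[f"h{l}.fc.w"].T
            dx_attn_fromln, g[f"h{l}.ln2.g"], g[f"h{l}.ln2.b"] = _layernorm_backward(dm, ln2c)
            dx_attn = dx + dx_attn_fromln
            # attention branch
            dproj = dx_attn
            g[f"h{l}.proj.w"] = flat(o).T @ flat(dproj)
            g[f"h{l}.proj.b"] = flat(dproj).sum(axis=0)
            do = (dproj @ p[f"h{l}.proj.w"].T).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            datt = do @ v.transpose(0, 1, 3, 2)
            dv = att.transpose(0, 1, 3, 2) @ do
            dscores = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
            dscores /= math.sqrt(hd)
            dq = dscores @ k
            dk = dscores.transpose(0, 1, 3, 2) @ q
            dqkv = np.concatenate(
                [
                    t.transpose(0, 2, 1, 3).reshape(B, T, D)
                    for t in (dq, dk, dv)
                ],
                axis=-1,
            )
            g[f"h{l}.qkv.w"] = flat(a).T @ flat(dqkv)
            g[f"h{l}.qkv.b"] = flat(dqkv).sum(axis=0)
            da = dqkv @ p[f"h{l}.qkv.w"].T
            dx_fromln, g[f"h{l}.ln1.g"], g[f"h{l}.ln1.b"] = _layernorm_backward(da, ln1c)
            dx = dx_attn + dx_fromln

        g["wpe"] = np.zeros_like(p["wpe"])
        g["wpe"][:T] = dx.sum(axis=0)
        g["wte"] = np.zeros_like(p["wte"])
        np.add.at(g["wte"], ids.reshape(-1), dx.reshape(-1, D))
        return g

    # -- public inference surface ------------------------------------------

    def next_token_distribution(self, context: TokenBlock | Sequence[int]) -> np.ndarray:
        """Probability vector over the vocabulary for the next token.

        The context must hold between 1 and context_length − 1 tokens so a
        further token can still be placed.
        """
        ids = list(context.ids if isinstance(context, TokenBlock) else context)
        if not (1 <= len(ids) < self.config.context_length):
            raise ValueError(
                f"context length must be in [1, {self.config.context_length - 1}], got {len(ids)}"
            )
        return _softmax(self.next_token_logits(ids))

    def next_token_logits(self, context: Sequence[int]) -> np.ndarray:
        ids = np.asarray(list(context), dtype=np.int64)[None, :]
        if np.any(ids < 0) or np.any(ids >= self.config.vocab_size):
            raise ValueError("context contains out-of-vocabulary ids")
        logits = self._forward(ids)
        return logits[0, -1]

    def positionwise_distributions(self, context: Sequence[int]) -> np.ndarray:
        """Next-token distributions at every position: shape (T, V)."""
        ids = np.asarray(list(context), dtype=np.int64)[None, :]
        logits = self._forward(ids)
        return _softmax(logits[0], axis=-1)

    # -- loss and optimization ---------------------------------------------

    def _batch_loss_grads(self, inputs: np.ndarray, targets: np.ndarray, want_grads: bool):
        """Mean NLL per predicted token; targets of -1 are padding."""
        valid = targets >= 0
        n_valid = int(valid.sum())
        if n_valid == 0:
            raise ValueError("no predictable positions in batch")
        if want_grads:
            logits, cache = self._forward(inputs, with_cache=True)
        else:
            logits = self._forward(inputs)
        logp = logits - logits.max(axis=-1, keepdims=True)
        logp = logp - np.log(np.exp(logp).sum(axis=-1, keepdims=True))
        tgt = np.where(valid, targets, 0)
        picked = np.take_along_axis(logp, tgt[..., None], axis=-1)[..., 0]
        loss = float(-(picked * valid).sum() / n_valid)
        if not want_grads:
            return loss, None
        probs = np.exp(logp)
        dlogits = probs
        np.subtract.at(
            dlogits.reshape(-1, dlogits.shape[-1]),
            (np.arange(tgt.size), tgt.reshape(-1)),
            1.0,
        )
        dlogits *= valid[..., None] / n_valid
        return loss, self._backward(dlogits, cache)

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.config
        if self._adam_m is None:
            self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
            self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        # global-norm gradient clipping for desk-scale stability
        norm = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        if cfg.grad_clip and norm > cfg.grad_clip:
            scale = cfg.grad_clip / norm
            grads = {k: g * scale for k, g in grads.items()}
        self._adam_t += 1
        t = self._adam_t
        b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, 1e-8
        for k, gk in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * gk
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * gk * gk
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    # -- checkpointing -----------------------------------------------------

    def save(self, directory: str | PathLike) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2)
        np.savez(d / "params.npz", **self.params)

    @classmethod
    def load(cls, directory: str | PathLike) -> "LanguageModel":
        d = Path(directory)
        with open(d / "config.json") as fh:
            cfg = LMConfig(**json.load(fh))
        model = cls(cfg)
        with np.load(d / "params.npz") as data:
            model.params = {k: data[k] for k in data.files}
        return model


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def _pad_batch(blocks: Sequence[TokenBlock]) -> tuple[np.ndarray, np.ndarray]:
    """Stack blocks into (inputs, targets) arrays; targets padded with -1."""
    for b in blocks:
        if len(b) < 2:
            raise ValueError("blocks must hold at least 2 tokens (one prediction)")
    T = max(len(b) for b in blocks) - 1
    inputs = np.zeros((len(blocks), T), dtype=np.int64)
    targets = np.full((len(blocks), T), -1, dtype=np.int64)
    for i, b in enumerate(blocks):
        ids = np.asarray(b.ids, dtype=np.int64)
        inputs[i, : len(ids) - 1] = ids[:-1]
        targets[i, : len(ids) - 1] = ids[1:]
    return inputs, targets


def clm_loss(model: LanguageModel, batch: Sequence[TokenBlock]) -> float:
    """Mean negative log-likelihood per predicted token, in nats.

    Equals −(1/T)·Σ log p(w_i | w_<i) over every predictable position of
    every block.  Blocks shorter than 2 tokens are a contract error.
    """
    if not batch:
        raise ValueError("batch must be non-empty")
    total_nll = 0.0
    total_n = 0
    chunk = 64
    for start in range(0, len(batch), chunk):
        blocks = batch[start : start + chunk]
        inputs, targets = _pad_batch(blocks)
        n = int((targets >= 0).sum())
        loss, _ = model._batch_loss_grads(inputs, targets, want_grads=False)
        total_nll += loss * n
        total_n += n
    return total_nll / total_n


def perplexity(model: LanguageModel, corpus: Sequence[TokenBlock]) -> float:
    """exp of the mean per-token cross-entropy; V for a uniform model."""
    return float(np.exp(clm_loss(model, corpus)))


def train(
    model: LanguageModel,
    split,
    tokenizer,
    steps: int,
    eval_every: int | None = None,
) -> pd.DataFrame:
    """Adam-optimize the model on a train/validation split.

    Sequences are tokenized, concatenated with EOS separators and chunked to
    the context length; each step samples a batch of blocks (without
    replacement within an epoch) and applies one Adam update.  Returns a
    trace frame with columns (step, train_loss, val_loss); validation loss
    is computed on held-out blocks only, every ``eval_every`` steps and at
    the end.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not split.train:
        raise ValueError("empty training set")
    cfg = model.config
    enc = lambda recs: [tokenizer.encode(r.sequence) for r in recs]
    train_blocks = blockize(enc(split.train), cfg.context_length, tokenizer.eos_id)
    val_blocks = blockize(enc(split.validation), cfg.context_length, tokenizer.eos_id)
    if not train_blocks:
        raise ValueError("training set produced no blocks")
    if eval_every is None:
        eval_every = max(1, steps // 10)
    batch_size = max(1, cfg.batch_tokens // cfg.context_length)
    rng = np.random.default_rng(cfg.seed + 1)
    order = rng.permutation(len(train_blocks))
    cursor = 0
    rows = []
    for step in range(1, steps + 1):
        if cursor + batch_size > len(order):
            order = rng.permutation(len(train_blocks))
            cursor = 0
        take = order[cursor : cursor + batch_size]
        cursor += batch_size
        batch = [train_blocks[i] for i in take]
        inputs, targets = _pad_batch(batch)
        loss, grads = model._batch_loss_grads(inputs, targets, want_grads=True)
        model._adam_step(grads)
        val_loss = math.nan
        if val_blocks and (step % eval_every == 0 or step == steps):
            val_loss = clm_loss(model, val_blocks)
        rows.append({"step": step, "train_loss": loss, "val_loss": val_loss})
    return pd.DataFrame(rows)
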