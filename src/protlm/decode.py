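"""Sequence emission from a next-token-distribution provider.

Strategies: greedy argmax, beam search over cumulative log-probability, and
seeded stochastic sampling with temperature, top-k, nucleus (top-p) and
repetition-penalty transforms.  The transform pipeline is fixed and
documented: repetition penalty on the logits, temperature, softmax, top-k,
top-p, renormalize, then select — so every filter acts on an explicit
probability vector and at least one token always survives.

A provider is anything with ``vocab_size``, an ``eos_id`` (or None) and a
``next_token_logits(context_ids) -> np.ndarray`` method; the transformer
:class:`~protlm.lm.LanguageModel` plugs in via :class:`LMProvider`, and test
fixtures can supply hand-written conditional tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "DecodingConfig",
    "GenerationResult",
    "Provider",
    "LMProvider",
    "apply_repetition_penalty",
    "top_k_filter",
    "top_p_filter",
    "greedy_decode",
    "beam_search",
    "sample_decode",
    "repeat_rate",
]


@runtime_checkable
class Provider(Protocol):
    """Minimal contract a decoding backend must satisfy."""

    vocab_size: int
    eos_id: int | None

    def next_token_logits(self, context_ids: Sequence[int]) -> np.ndarray: ...


class LMProvider:
    """Adapts a trained :class:`~protlm.lm.LanguageModel` for decoding.

    Keeps a sliding window of the most recent ``context_length - 1`` tokens
    so generation can run past the model's context window; optionally carries
    the tokenizer used to detokenize emissions.
    """

    def __init__(self, model, tokenizer=None, eos_id: int | None = None):
        self.model = model
        self.tokenizer = tokenizer
        self.vocab_size = model.config.vocab_size
        if eos_id is None and tokenizer is not None:
            eos_id = tokenizer.eos_id
        self.eos_id = eos_id

    def next_token_logits(self, context_ids: Sequence[int]) -> np.ndarray:
        window = list(context_ids)[-(self.model.config.context_length - 1) :]
        if not window:
            window = [self.eos_id if self.eos_id is not None else 0]
        return self.model.next_token_logits(window)

    def detokenize(self, ids: Sequence[int]) -> str:
        if self.tokenizer is None:
            return ""
        return self.tokenizer.decode(ids)


@dataclass(frozen=True)
class DecodingConfig:
    """Sampling-strategy parameters.

    The generation budget defaults to a 250-token window; a sequence still
    running when the budget is exhausted is flagged as truncated rather than
    terminated.
    """

    strategy: Literal["greedy", "beam", "sample"] = "sample"
    beam_width: int = 1
    top_k: int | None = None
    top_p: float = 1.0
    temperature: float = 1.0
    repetition_penalty: float = 1.0
    max_new_tokens: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1 or None")
        if not (0.0 < self.top_p <= 1.0):
            raise ValueError("top_p must be in (0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.repetition_penalty < 1.0:
            raise ValueError("repetition_penalty must be >= 1")
        if self.max_new_tokens < 1:
            raise ValueError("max_new_tokens must be >= 1")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")


@dataclass(frozen=True)
class GenerationResult:
    """An emitted sequence with termination status and model log-probability.

    ``terminated`` is False exactly when the token budget ran out before an
    end-of-sequence token; ``logprob`` is the total log-probability of the
    emitted (non-EOS) tokens under the unmodified model distribution.
    """

    ids: tuple[int, ...]
    sequence: str
    terminated: bool
    logprob: float


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def apply_repetition_penalty(
    logits: np.ndarray, context_ids: Sequence[int], penalty: float
) -> np.ndarray:
    """Discount logits of tokens already present in the context.

    Positive scores are divided by the penalty and non-positive scores
    multiplied by it, so a penalized token's score always drops.  Penalty 1
    is the identity.
    """
    if penalty < 1.0:
        raise ValueError("penalty must be >= 1")
    out = np.array(logits, dtype=float, copy=True)
    seen = set(int(i) for i in context_ids)
    for tok in seen:
        if out[tok] > 0:
            out[tok] /= penalty
        else:
            out[tok] *= penalty
    return out


def top_k_filter(probs: np.ndarray, k: int) -> np.ndarray:
    """Keep the k most probable tokens and renormalize.

    Ties at the k-th probability break toward the lower token id (stable
    sort on descending probability).
    """
    probs = np.asarray(probs, dtype=float)
    V = probs.size
    if not (1 <= k <= V):
        raise ValueError(f"k must be in [1, {V}]")
    if k == V:
        return probs / probs.sum()
    order = np.argsort(-probs, kind="stable")
    keep = order[:k]
    out = np.zeros_like(probs)
    out[keep] = probs[keep]
    return out / out.sum()


def top_p_filter(probs: np.ndarray, p: float) -> np.ndarray:
    """Nucleus filter: keep the smallest probability-sorted prefix with
    cumulative mass ≥ p, renormalized.  At least one token survives."""
    probs = np.asarray(probs, dtype=float)
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    if p == 1.0:
        return probs / probs.sum()
    order = np.argsort(-probs, kind="stable")
    csum = np.cumsum(probs[order])
    cutoff = int(np.searchsorted(csum, p, side="left")) + 1
    keep = order[:cutoff]
    out = np.zeros_like(probs)
    out[keep] = probs[keep]
    return out / out.sum()


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - np.max(x)
    e = np.exp(z)
    return e / e.sum()


def _transformed_probs(
    logits: np.ndarray, context_ids: Sequence[int], config: DecodingConfig
) -> np.ndarray:
    """penalty → temperature → softmax → top-k → top-p → renormalize."""
    scores = apply_repetition_penalty(logits, context_ids, config.repetition_penalty)
    probs = _softmax(scores / config.temperature)
    if config.top_k is not None:
        probs = top_k_filter(probs, min(config.top_k, probs.size))
    probs = top_p_filter(probs, config.top_p)
    return probs


def _raw_logprob(logits: np.ndarray, token: int) -> float:
    z = logits - np.max(logits)
    return float(z[token] - np.log(np.exp(z).sum()))


# ---------------------------------------------------------------------------
# decoding strategies
# ---------------------------------------------------------------------------


def _finish(provider, ids: list[int], terminated: bool, logprob: float) -> GenerationResult:
    seq = provider.detokenize(ids) if hasattr(provider, "detokenize") else ""
    return GenerationResult(
        ids=tuple(ids), sequence=seq, terminated=terminated, logprob=logprob
    )


def greedy_decode(
    provider: Provider, prompt: Sequence[int] = (), config: DecodingConfig | None = None
) -> GenerationResult:
    """Deterministic argmax emission after the transform pipeline."""
    config = config or DecodingConfig(strategy="greedy")
    context = list(prompt)
    emitted: list[int] = []
    logprob = 0.0
    terminated = False
    for _ in range(config.max_new_tokens):
        logits = provider.next_token_logits(context)
        probs = _transformed_probs(logits, context, config)
        tok = int(np.argmax(probs))
        if provider.eos_id is not None and tok == provider.eos_id:
            terminated = True
            break
        logprob += _raw_logprob(logits, tok)
        emitted.append(tok)
        context.append(tok)
    return _finish(provider, emitted, terminated, logprob)


def beam_search(
    provider: Provider, prompt: Sequence[int] = (), config: DecodingConfig | None = None
) -> list[GenerationResult]:
    """Breadth-limited search over cumulative (transformed) log-probability.

    Candidates are scored by the sum of log-probabilities after the
    repetition-penalty and temperature transforms, so ``beam_width=1``
    reproduces greedy decoding for any configuration; with the default
    transforms (penalty 1, temperature 1) the score is exactly the raw model
    log-probability, making an exhaustive beam equal to brute-force
    enumeration.  EOS-completed beams are retired and compete by total
    score.  No length normalization is applied.
    """
    config = config or DecodingConfig(strategy="beam")
    prompt = tuple(prompt)
    # (emitted ids, beam score, raw logprob of emitted tokens, terminated)
    live: list[tuple[tuple[int, ...], float, float]] = [((), 0.0, 0.0)]
    finished: list[tuple[tuple[int, ...], float, float, bool]] = []
    for _ in range(config.max_new_tokens):
        if not live:
            break
        candidates: list[tuple[tuple[int, ...], float, float]] = []
        for ids, score, raw in live:
            context = list(prompt + ids)
            logits = provider.next_token_logits(context)
            pen = apply_repetition_penalty(logits, context, config.repetition_penalty)
            z = pen / config.temperature
            z = z - np.max(z)
            tlogp = z - np.log(np.exp(z).sum())
            rawz = logits - np.max(logits)
            rawlogp = rawz - np.log(np.exp(rawz).sum())
            for tok in range(provider.vocab_size):
                # raw logprob tracks emitted (non-EOS) tokens only
                raw_inc = 0.0 if tok == provider.eos_id else float(rawlogp[tok])
                candidates.append(
                    (ids + (tok,), score + float(tlogp[tok]), raw + raw_inc)
                )
        candidates.sort(key=lambda c: (-c[1], c[0]))
        live = []
        for ids, score, raw in candidates[: config.beam_width]:
            if provider.eos_id is not None and ids[-1] == provider.eos_id:
                finished.append((ids[:-1], score, raw, True))
            else:
                live.append((ids, score, raw))
    finished.extend((ids, score, raw, False) for ids, score, raw in live)
    finished.sort(key=lambda c: (-c[1], c[0]))
    return [
        _finish(provider, list(ids), term, raw)
        for ids, _score, raw, term in finished[: config.beam_width]
    ]


def sample_decode(
    provider: Provider, prompt: Sequence[int] = (), config: DecodingConfig | None = None
) -> GenerationResult:
    """Seeded stochastic emission from the transformed distribution."""
    config = config or DecodingConfig(strategy="sample")
    rng = np.random.default_rng(config.seed)
    context = list(prompt)
    emitted: list[int] = []
    logprob = 0.0
    terminated = False
    for _ in range(config.max_new_tokens):
        logits = provider.next_token_logits(context)
        probs = _transformed_probs(logits, context, config)
        tok = int(rng.choice(probs.size, p=probs))
        if provider.eos_id is not None and tok == provider.eos_id:
            terminated = True
            break
        logprob += _raw_logprob(logits, tok)
        emitted.append(tok)
        context.append(tok)
    return _finish(provider, emitted, terminated, logprob)


def repeat_rate(sequence: str, n: int) -> float:
    """Fraction of repeated n-grams: 1 − distinct/total."""
    if len(sequence) < n:
        raise ValueError(f"sequence of length {len(sequence)} shorter than n={n}")
    total = len(sequence) - n + 1
    distinct = len({sequence[i : i + n] for i in range(total)})
    return 1.0 - distinct / total
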