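"""Synthetic corpora with known statistical structure.

First-order Markov grammars over small alphabets provide training and
evaluation corpora whose optimal cross-entropy (the entropy rate) is known in
closed form, so the tokenizer, language model, decoding and calibration layers
can be tested end-to-end against analytic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.csgraph as csgraph

from .io_seq import LengthSpec, SequenceRecord, Source

__all__ = [
    "MarkovGrammar",
    "two_state_grammar",
    "standard_test_grammar",
    "sample_corpus",
    "entropy_rate",
    "stationary_distribution",
    "recovery_report",
]


@dataclass(frozen=True)
class MarkovGrammar:
    """A first-order Markov sequence source.

    ``transitions[i, j]`` is the probability of emitting symbol j immediately
    after symbol i; ``initial`` is the distribution of the first symbol.
    Sequence lengths are drawn independently from ``length_spec``.
    """

    alphabet: tuple[str, ...]
    initial: np.ndarray
    transitions: np.ndarray
    length_spec: LengthSpec = field(default_factory=LengthSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        initial = np.asarray(self.initial, dtype=float)
        transitions = np.asarray(self.transitions, dtype=float)
        object.__setattr__(self, "initial", initial)
        object.__setattr__(self, "transitions", transitions)
        if transitions.shape != (k, k):
            raise ValueError("transition matrix shape must match alphabet size")
        if initial.shape != (k,):
            raise ValueError("initial vector shape must match alphabet size")
        if np.any(transitions < 0) or np.any(initial < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each transition row must sum to 1")
        if not np.isclose(initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")


def two_state_grammar(
    stay: float = 0.9,
    length_spec: LengthSpec | None = None,
    seed: int = 0,
) -> MarkovGrammar:
    """Symmetric two-symbol chain that stays in its state with probability ``stay``."""
    p = float(stay)
    return MarkovGrammar(
        alphabet=("A", "B"),
        initial=np.array([0.5, 0.5]),
        transitions=np.array([[p, 1 - p], [1 - p, p]]),
        length_spec=length_spec or LengthSpec(),
        seed=seed,
    )


def standard_test_grammar() -> MarkovGrammar:
    """The fixed three-symbol grammar used for repository-stable checks.

    Rows are deliberately non-symmetric so that parameter recovery cannot
    succeed by learning marginal frequencies alone.
    """
    return MarkovGrammar(
        alphabet=("A", "B", "C"),
        initial=np.array([0.5, 0.3, 0.2]),
        transitions=np.array(
            [
                [0.70, 0.20, 0.10],
                [0.10, 0.60, 0.30],
                [0.25, 0.25, 0.50],
            ]
        ),
        length_spec=LengthSpec(min_len=20, max_len=200, mean=100.0, sd=30.0),
        seed=7,
    )


def sample_corpus(grammar: MarkovGrammar, n: int, seed: int | None = None) -> list[SequenceRecord]:
    """Draw ``n`` sequences from the grammar, reproducibly under its seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(grammar.seed if seed is None else seed)
    k = len(grammar.alphabet)
    lengths = grammar.length_spec.sample_lengths(n, rng)
    # cumulative rows let each chain be driven by one uniform draw per step
    cum_T = np.cumsum(grammar.transitions, axis=1)
    cum_init = np.cumsum(grammar.initial)
    records = []
    for i, L in enumerate(lengths):
        u = rng.random(int(L))
        states = np.empty(int(L), dtype=np.int64)
        states[0] = np.searchsorted(cum_init, u[0], side="right")
        for t in range(1, int(L)):
            states[t] = np.searchsorted(cum_T[states[t - 1]], u[t], side="right")
        states = np.minimum(states, k - 1)
        seq = "".join(grammar.alphabet[s] for s in states)
        records.append(SequenceRecord(id=f"synthetic_{i:05d}", sequence=seq, source=Source.NATURAL))
    return records


def stationary_distribution(transitions: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution π with πP = π, via the unit left eigenvector."""
    T = np.asarray(transitions, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    if abs(vals[idx] - 1.0) > 1e-8:
        raise ValueError("no unit eigenvalue: matrix is not row-stochastic")
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    # polish with a few power iterations to the requested tolerance
    for _ in range(10_000):
        nxt = pi @ T
        if np.max(np.abs(nxt - pi)) < tol:
            return nxt
        pi = nxt
    return pi


def _is_irreducible(transitions: np.ndarray) -> bool:
    adj = (np.asarray(transitions) > 0).astype(np.int8)
    n_comp, _ = csgraph.connected_components(adj, directed=True, connection="strong")
    return n_comp == 1


def entropy_rate(grammar: MarkovGrammar) -> float:
    """Entropy rate Σ_i π_i Σ_j −P_ij ln P_ij in nats per symbol.

    This is the optimal cross-entropy any model can reach on the grammar's
    transition structure.  Requires an irreducible chain.
    """
    if not _is_irreducible(grammar.transitions):
        raise ValueError("entropy rate requires an irreducible chain")
    pi = stationary_distribution(grammar.transitions)
    P = grammar.transitions
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    return float(-(pi @ plogp.sum(axis=1)))


def recovery_report(model, grammar: MarkovGrammar, tokenizer, n_probe: int = 200, probe_seed: int = 1234):
    """How well a trained model recovered the grammar.

    Returns ``(loss_gap, max_tv)`` where ``loss_gap`` is the model's
    cross-entropy on a fresh probe corpus minus the grammar's entropy rate,
    and ``max_tv`` is the largest total-variation distance between the
    model's per-state conditional (averaged over probe positions whose
    previous symbol is that state) and the true transition row.

    Both quantities are computed over *transition positions only* — positions
    whose target and predecessor are both alphabet symbols — with the model's
    distribution renormalized over the alphabet.  End-of-sequence bookkeeping
    tokens therefore do not contribute: the comparison is against the
    grammar's transition structure, which carries no length model.

    Requires a character-level tokenizer (one token per residue); otherwise
    per-state conditionals are not well defined.
    """
    if any(len(tok) != 1 for tok in tokenizer.vocab_tokens() if tok not in tokenizer.specials):
        raise ValueError("recovery_report requires a character-level tokenizer")

    alphabet = list(grammar.alphabet)
    sym_ids = np.array([tokenizer.token_to_id[s] for s in alphabet])
    probe = sample_corpus(grammar, n_probe, seed=probe_seed)

    k = len(alphabet)
    sum_dist = np.zeros((k, k))
    counts = np.zeros(k, dtype=np.int64)
    total_nll = 0.0
    n_positions = 0
    ctx_len = model.config.context_length
    for rec in probe:
        ids = tokenizer.encode(rec.sequence)
        ids_arr = np.asarray(ids)
        if len(ids) < 2:
            continue
        # windowed forward passes; conditionals read from every position
        start = 0
        while start < len(ids) - 1:
            window = ids[start : start + ctx_len]
            probs = model.positionwise_distributions(window)  # (T, V)
            sub = probs[:, sym_ids]
            sub = sub / sub.sum(axis=1, keepdims=True)
            prev_states = np.searchsorted(sym_ids, ids_arr[start : start + len(window)])
            for t in range(len(window) - 1):
                # skip re-scored overlap positions except on the first window
                if start > 0 and t < ctx_len // 2:
                    continue
                s_prev = prev_states[t]
                s_next = prev_states[t + 1]
                sum_dist[s_prev] += sub[t]
                counts[s_prev] += 1
                total_nll -= np.log(max(sub[t, s_next], 1e-300))
                n_positions += 1
            if start + ctx_len >= len(ids):
                break
            start += ctx_len // 2
    if n_positions == 0:
        raise ValueError("probe corpus yielded no transition positions")

    cross_entropy = total_nll / n_positions
    gap = cross_entropy - entropy_rate(grammar)
    tvs = []
    for s in range(k):
        if counts[s] == 0:
            continue
        mean_cond = sum_dist[s] / counts[s]
        tvs.append(0.5 * np.abs(mean_cond - grammar.transitions[s]).sum())
    return float(gap), float(max(tvs))
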