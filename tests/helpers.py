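"""Shared test fixtures: hand-specified decoding providers and oracles."""

from __future__ import annotations

import numpy as np


class TableProvider:
    """A next-token provider whose logits depend only on the last token.

    ``table[i]`` is the logit vector after token i; ``initial`` applies to an
    empty context.  A hand-walkable stand-in for a trained model.
    """

    def __init__(self, table, initial=None, eos_id=None, symbols=None):
        self.table = np.asarray(table, dtype=float)
        self.vocab_size = self.table.shape[1]
        self.eos_id = eos_id
        self.initial = (
            np.zeros(self.vocab_size) if initial is None else np.asarray(initial, float)
        )
        self.symbols = symbols

    def next_token_logits(self, context_ids):
        if not len(context_ids):
            return self.initial.copy()
        return self.table[context_ids[-1]].copy()

    def detokenize(self, ids):
        if self.symbols is None:
            return "".join(chr(ord("A") + i) for i in ids)
        return "".join(self.symbols[i] for i in ids)


def sequence_logprob(provider, seq, prompt=()) -> float:
    """Raw model log-probability of emitting ``seq`` after ``prompt``."""
    lp = 0.0
    ctx = list(prompt)
    for t in seq:
        logits = provider.next_token_logits(ctx)
        z = logits - logits.max()
        lp += float(z[t] - np.log(np.exp(z).sum()))
        ctx.append(int(t))
    return lp


def bfs_components(nodes, edges):
    """Independent connected-components oracle: plain BFS over an adjacency
    dict, no graph library involved."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        seen.add(start)
        while frontier:
            cur = frontier.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    comp.add(nxt)
                    frontier.append(nxt)
        comps.append(comp)
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def brute_force_bpe_first_merge(seqs):
    """Most frequent adjacent symbol pair (lexicographic tie-break) by
    direct enumeration — the oracle for the first training merge."""
    counts = {}
    for s in seqs:
        for i in range(len(s) - 1):
            pair = (s[i], s[i + 1])
            counts[pair] = counts.get(pair, 0) + 1
    if not counts:
        return None
    return min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
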