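"""Decoding-parameter selection by amino-acid-propensity matching.

Well-trained causal LMs can still emit degenerate sequences under a poor
sampling configuration, so the decoding parameters are chosen empirically: a
grid of (repetition penalty, top-k, top-p) cells is swept, a batch of
sequences is sampled per cell, and each cell is scored by how far the pooled
amino-acid frequencies of its sample deviate from a natural reference
profile — summed absolute difference (L1) over the reference's most common
residues, with full-alphabet L1 reported as a secondary column.  Cells are
ranked ascending by that distance.

The full historical sweep (penalty 1.1–3.0 step 0.1, top-k 250–1000 step 50,
top-p 0.7–1.0 step 0.05, 100 sequences per cell → 2240 cells) is available
via :func:`paper_grid`; desk-scale sweeps use far smaller grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decode import DecodingConfig, LMProvider, sample_decode
from .io_seq import SequenceRecord, filter_truncated

__all__ = [
    "PropensityProfile",
    "GridSpec",
    "paper_grid",
    "propensity_profile",
    "top_common_residues",
    "propensity_distance",
    "grid_calibrate",
]


@dataclass(frozen=True)
class PropensityProfile:
    """Relative residue frequencies with the residue count behind them."""

    frequencies: Mapping[str, float]
    n_residues: int

    def __post_init__(self) -> None:
        vals = np.array(list(self.frequencies.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("frequencies must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    def get(self, residue: str) -> float:
        return float(self.frequencies.get(residue, 0.0))


@dataclass(frozen=True)
class GridSpec:
    """The decoding-parameter grid and per-cell sample size."""

    repetition_penalties: tuple[float, ...]
    top_ks: tuple[int, ...]
    top_ps: tuple[float, ...]
    samples_per_cell: int = 100

    def __post_init__(self) -> None:
        if not (self.repetition_penalties and self.top_ks and self.top_ps):
            raise ValueError("all grid axes must be non-empty")
        if self.samples_per_cell < 1:
            raise ValueError("samples_per_cell must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.repetition_penalties) * len(self.top_ks) * len(self.top_ps)

    def cells(self):
        for pen in self.repetition_penalties:
            for k in self.top_ks:
                for p in self.top_ps:
                    yield (pen, k, p)


def paper_grid(samples_per_cell: int = 100) -> GridSpec:
    """The full sweep: penalties 1.1–3.0 (step 0.1), top-k 250–1000 (step
    50), top-p 0.7–1.0 (step 0.05) — 20 × 16 × 7 = 2240 cells."""
    return GridSpec(
        repetition_penalties=tuple(np.round(np.linspace(1.1, 3.0, 20), 1)),
        top_ks=tuple(range(250, 1001, 50)),
        top_ps=tuple(np.round(np.linspace(0.70, 1.00, 7), 2)),
        samples_per_cell=samples_per_cell,
    )


def propensity_profile(records: Sequence[SequenceRecord | str]) -> PropensityProfile:
    """Pooled residue frequencies over all sequences."""
    seqs = [r.sequence if isinstance(r, SequenceRecord) else r for r in records]
    counts: dict[str, int] = {}
    total = 0
    for s in seqs:
        for ch in s:
            counts[ch] = counts.get(ch, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("no residues in input")
    freqs = {ch: c / total for ch, c in sorted(counts.items())}
    return PropensityProfile(frequencies=freqs, n_residues=total)


def top_common_residues(reference: PropensityProfile, m: int = 7) -> list[str]:
    """The m most frequent residues, descending; ties alphabetical."""
    nonzero = [(r, f) for r, f in reference.frequencies.items() if f > 0]
    if m > len(nonzero):
        raise ValueError(f"m={m} exceeds {len(nonzero)} residues with nonzero frequency")
    ranked = sorted(nonzero, key=lambda rf: (-rf[1], rf[0]))
    return [r for r, _ in ranked[:m]]


def propensity_distance(
    generated: PropensityProfile,
    reference: PropensityProfile,
    focus: Sequence[str] | None = None,
) -> float:
    """L1 distance Σ |f_gen(a) − f_ref(a)| over the focus residues.

    With ``focus=None`` the union of both alphabets is used.
    """
    if focus is None:
        focus = sorted(set(generated.frequencies) | set(reference.frequencies))
    return float(sum(abs(generated.get(a) - reference.get(a)) for a in focus))


def grid_calibrate(
    model,
    tokenizer,
    grid: GridSpec,
    reference: PropensityProfile,
    seed: int = 0,
    n_focus: int = 7,
    max_new_tokens: int = 250,
) -> pd.DataFrame:
    """Sweep the decoding grid and rank cells by propensity distance.

    For each cell, ``samples_per_cell`` sequences are sampled with seeds
    derived deterministically from ``seed`` and the cell index, truncated
    (budget-exhausted) generations are filtered out, and the survivors'
    pooled profile is scored against the reference's ``n_focus`` most common
    residues.  Cells whose generations were all truncated are flagged
    (``n_sequences`` 0, distances NaN) rather than dropped.  Rows are sorted
    ascending by focus distance; ties break on (penalty, top_k, top_p).
    """
    provider = model if hasattr(model, "next_token_logits") and not hasattr(model, "params") else LMProvider(model, tokenizer)
    if hasattr(provider, "tokenizer") and provider.tokenizer is None:
        provider.tokenizer = tokenizer
    focus = top_common_residues(reference, n_focus)
    rows = []
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(grid.n_cells * grid.samples_per_cell)
    i = 0
    for pen, k, p in grid.cells():
        results = []
        for _ in range(grid.samples_per_cell):
            cfg = DecodingConfig(
                strategy="sample",
                top_k=int(k),
                top_p=float(p),
                repetition_penalty=float(pen),
                max_new_tokens=max_new_tokens,
                seed=int(cell_seeds[i] % (2**31)),
            )
            i += 1
            results.append(sample_decode(provider, (), cfg))
        kept = filter_truncated(results)
        if kept:
            prof = propensity_profile(kept)
            d_focus = propensity_distance(prof, reference, focus)
            d_full = propensity_distance(prof, reference, None)
        else:
            d_focus = d_full = float("nan")
        rows.append(
            {
                "penalty": float(pen),
                "top_k": int(k),
                "top_p": float(p),
                "distance_focus": d_focus,
                "distance_full": d_full,
                "n_sequences": len(kept),
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        by=["distance_focus", "penalty", "top_k", "top_p"], na_position="last"
    ).reset_index(drop=True)
    return frame
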