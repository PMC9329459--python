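"""Sequence-level evaluation statistics.

Three independent batteries used to judge generated sequence sets against
natural and random controls:

* **Homology**: classify profile-search hits against the HSSP curve — the
  length-dependent identity boundary below which sequence similarity (the
  "twilight zone") no longer implies homology — and select each query's best
  hit (longest above-curve alignment, identity tie-break).
* **Disorder**: aggregate per-residue disorder scores (IUPred-style output)
  into an ordered-content percentage.
* **Secondary structure**: aggregate per-residue three-state predictions
  (PSIPRED-style .ss2 output) into helix/sheet/coil percentages over
  confidently predicted residues.

Running the upstream predictors themselves is out of scope; their outputs
are parsed from documented plain-text dialects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentHit",
    "HSSPVerdict",
    "HSSPCurve",
    "hssp_threshold",
    "select_best_hit",
    "dataset_hssp_summary",
    "parse_hit_table",
    "write_hit_table",
    "read_iupred",
    "ordered_fraction",
    "read_ss2",
    "ss_content",
]

HIT_COLUMNS = ["query", "target", "prob", "identity", "aln_length", "qstart", "qend"]


@dataclass(frozen=True)
class AlignmentHit:
    """One profile-search alignment summary row."""

    query_id: str
    target_id: str
    identity: float  # percent
    aln_length: int  # residues
    probability: float  # percent
    qstart: int = 1
    qend: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be a percentage in [0, 100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if not (0.0 <= self.probability <= 100.0):
            raise ValueError("probability must be a percentage in [0, 100]")
        if self.qend is None:
            object.__setattr__(self, "qend", self.qstart + self.aln_length - 1)
        if self.qstart > self.qend:
            raise ValueError("qstart must be <= qend")


@dataclass(frozen=True)
class HSSPVerdict:
    """A query's selected hit and its position relative to the HSSP curve."""

    hit: AlignmentHit | None
    above_curve: bool
    threshold_at_length: float


@dataclass(frozen=True)
class HSSPCurve:
    """Two-parameter twilight-zone boundary t(L) = max(A·L^B, plateau).

    Defaults A=290.15, B=−0.562, plateau 24.8% give the classic curve: steep
    identity requirements for short alignments decaying to a constant ~25%
    plateau for long ones.  The max form keeps the curve monotone
    non-increasing and exactly continuous at the crossover (L ≈ 80).
    Alternative twilight-zone parameterizations can be swapped in.
    """

    amplitude: float = 290.15
    exponent: float = -0.562
    plateau: float = 24.8

    def threshold(self, aln_length: int) -> float:
        if aln_length < 1:
            raise ValueError("alignment length must be >= 1")
        return max(self.amplitude * aln_length**self.exponent, self.plateau)


_DEFAULT_CURVE = HSSPCurve()


def hssp_threshold(aln_length: int, curve: HSSPCurve = _DEFAULT_CURVE) -> float:
    """Percent identity required at a given alignment length to call two
    sequences confidently related; monotone non-increasing in length."""
    return curve.threshold(aln_length)


def select_best_hit(
    hits: Sequence[AlignmentHit], curve: HSSPCurve = _DEFAULT_CURVE
) -> HSSPVerdict:
    """Pick a query's representative hit relative to the HSSP curve.

    Hits strictly above the curve are candidates; among them the longest
    alignment wins, ties broken by higher identity.  If nothing clears the
    curve, the hit closest to it (max identity − threshold) is reported with
    ``above_curve=False``.  An empty hit list yields a no-hit verdict.
    """
    if not hits:
        return HSSPVerdict(hit=None, above_curve=False, threshold_at_length=math.nan)
    above = [h for h in hits if h.identity > curve.threshold(h.aln_length)]
    if above:
        best = max(above, key=lambda h: (h.aln_length, h.identity))
        return HSSPVerdict(
            hit=best, above_curve=True, threshold_at_length=curve.threshold(best.aln_length)
        )
    best = max(hits, key=lambda h: h.identity - curve.threshold(h.aln_length))
    return HSSPVerdict(
        hit=best, above_curve=False, threshold_at_length=curve.threshold(best.aln_length)
    )


def dataset_hssp_summary(
    verdicts: Sequence[HSSPVerdict],
) -> tuple[float, float | None, float | None]:
    """(fraction of queries above the curve, identity mean, identity sd).

    The fraction is over *all* queries — a query without any hit counts as
    below the curve.  Moments are over queries with a hit; if none has one
    they are reported as None.
    """
    if not verdicts:
        raise ValueError("verdicts must be non-empty")
    frac = sum(1 for v in verdicts if v.above_curve) / len(verdicts)
    idents = [v.hit.identity for v in verdicts if v.hit is not None]
    if not idents:
        return frac, None, None
    arr = np.asarray(idents, dtype=float)
    return frac, float(arr.mean()), float(arr.std(ddof=0))


# ---------------------------------------------------------------------------
# normalized hit-table I/O
# ---------------------------------------------------------------------------


def parse_hit_table(path: str | PathLike) -> list[AlignmentHit]:
    """Read the normalized tab-separated hit table.

    Columns: query, target, prob, identity, aln_length, qstart, qend (header
    required).  Identities and probabilities are percentages.  A malformed
    row raises with its line number; rows are never silently skipped.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    if header != HIT_COLUMNS:
        raise ValueError(
            f"line 1: expected header {HIT_COLUMNS!r}, got {header!r}"
        )
    hits = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(HIT_COLUMNS):
            raise ValueError(f"line {lineno}: expected {len(HIT_COLUMNS)} fields, got {len(fields)}")
        try:
            hits.append(
                AlignmentHit(
                    query_id=fields[0],
                    target_id=fields[1],
                    probability=float(fields[2]),
                    identity=float(fields[3]),
                    aln_length=int(fields[4]),
                    qstart=int(fields[5]),
                    qend=int(fields[6]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], path: str | PathLike) -> None:
    """Write hits in the normalized tab-separated dialect (round-trips
    through :func:`parse_hit_table`)."""
    frame = pd.DataFrame(
        [
            {
                "query": h.query_id,
                "target": h.target_id,
                "prob": h.probability,
                "identity": h.identity,
                "aln_length": h.aln_length,
                "qstart": h.qstart,
                "qend": h.qend,
            }
            for h in hits
        ],
        columns=HIT_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# disorder and secondary structure aggregation
# ---------------------------------------------------------------------------


def read_iupred(path: str | PathLike) -> np.ndarray:
    """Read an IUPred-style whitespace-separated (position, residue, score)
    file into a score array; '#' comment lines are ignored."""
    scores = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected (position, residue, score)")
            scores.append(float(fields[2]))
    return np.asarray(scores, dtype=float)


def ordered_fraction(scores: Sequence[float], cutoff: float = 0.5) -> float:
    """Percent of residues predicted ordered: disorder score below cutoff."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("scores must be non-empty")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("disorder scores must lie in [0, 1]")
    return float(100.0 * (arr < cutoff).sum() / arr.size)


def read_ss2(path: str | PathLike) -> list[tuple[str, int]]:
    """Read the normalized .ss2 dialect into (state, confidence) records.

    Columns: position, residue, state (H/E/C), then three per-state
    probabilities (coil, helix, strand).  The integer confidence 0-9 is
    floor(10 · max probability), capped at 9.  Comment/header lines starting
    with '#' are ignored.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: expected 6 columns in ss2 record")
            state = fields[2]
            if state not in ("H", "E", "C"):
                raise ValueError(f"line {lineno}: state must be H, E or C, got {state!r}")
            conf = min(int(10 * max(float(x) for x in fields[3:6])), 9)
            records.append((state, conf))
    return records


def ss_content(
    ss2_records: Sequence[tuple[str, int]], min_conf: int = 5
) -> tuple[float, float, float] | None:
    """(helix %, sheet %, coil %) over residues with confidence ≥ min_conf.

    Returns None (not zeros) when no residue reaches the confidence floor.
    """
    if not ss2_records:
        raise ValueError("ss2_records must be non-empty")
    qualifying = [(s, c) for s, c in ss2_records if c >= min_conf]
    if not qualifying:
        return None
    n = len(qualifying)
    helix = 100.0 * sum(1 for s, _ in qualifying if s == "H") / n
    sheet = 100.0 * sum(1 for s, _ in qualifying if s == "E") / n
    coil = 100.0 * sum(1 for s, _ in qualifying if s == "C") / n
    return helix, sheet, coil
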