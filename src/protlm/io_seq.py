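"""Sequence I/O and dataset construction.

FASTA reading/writing, seeded train/validation splitting, and the three
evaluation datasets used throughout the toolkit: model-generated sequences,
a length-matched natural subsample, and a random-residue control set built
from the 25-letter residue alphabet seen in large sequence databases
(20 standard amino acids plus the IUPAC codes B, O, U, X, Z).
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Source",
    "SequenceRecord",
    "DatasetSplit",
    "LengthSpec",
    "FastaFormatError",
    "MatchingFailureError",
    "DEFAULT_ALPHABET",
    "read_fasta",
    "write_fasta",
    "split_dataset",
    "make_random_dataset",
    "length_matched_subsample",
    "filter_truncated",
    "write_manifest",
]

#: The 25 residue symbols observed in UniRef-scale databases: the 20 standard
#: amino acids plus B, O, U, X and Z, in alphabetical order (every uppercase
#: letter except J).
DEFAULT_ALPHABET = "ABCDEFGHIKLMNOPQRSTUVWXYZ"


class Source(str, enum.Enum):
    """Provenance label of a sequence record."""

    NATURAL = "natural"
    GENERATED = "generated"
    RANDOM = "random"


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein sequence with an identifier and provenance."""

    id: str
    sequence: str
    source: Source = Source.NATURAL

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DatasetSplit:
    """A disjoint, exhaustive train/validation partition."""

    train: list[SequenceRecord]
    validation: list[SequenceRecord]
    seed: int
    validation_fraction: float


@dataclass(frozen=True)
class LengthSpec:
    """Bounds and moments of a sequence-length distribution (residues).

    Lengths are drawn from a normal distribution with the given mean and
    standard deviation, truncated by resampling to [min_len, max_len].
    The defaults mirror a uniform-ish coverage of the 5-267 residue window:
    mean at the midpoint and sd at one sixth of the range.
    """

    min_len: int = 5
    max_len: int = 267
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")
        if self.mean is None:
            object.__setattr__(self, "mean", (self.min_len + self.max_len) / 2)
        if self.sd is None:
            object.__setattr__(self, "sd", (self.max_len - self.min_len) / 6)
        if not (self.min_len <= self.mean <= self.max_len):
            raise ValueError("mean must lie within [min_len, max_len]")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def sample_lengths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` integer lengths by truncated-normal resampling."""
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean, self.sd, size=max(n - filled, 16))
            draw = np.rint(draw).astype(np.int64)
            ok = draw[(draw >= self.min_len) & (draw <= self.max_len)]
            take = min(len(ok), n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input, naming the offending line."""


class MatchingFailureError(RuntimeError):
    """Raised when no length-matched subsample is found within the budget."""

    def __init__(self, message: str, best_mean: float, best_sd: float):
        super().__init__(message)
        self.best_mean = best_mean
        self.best_sd = best_sd


def read_fasta(path: str | PathLike | TextIO, source: Source = Source.NATURAL) -> list[SequenceRecord]:
    """Read a FASTA file into records, preserving order.

    Multi-line bodies are joined and whitespace stripped.  A body line before
    any header, or a header with an empty body, is a :class:`FastaFormatError`
    naming the line number.  An empty file yields an empty list.

    The strict line-number error contract is why this parser is hand-rolled
    rather than delegated to Bio.SeqIO.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()

    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    body: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(body)
        if not seq:
            raise FastaFormatError(
                f"line {header_line}: header {header!r} has an empty body"
            )
        records.append(SequenceRecord(id=header, sequence=seq, source=source))

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0] if line[1:].split() else line[1:]
            header_line = lineno
            body = []
        else:
            if header is None:
                raise FastaFormatError(
                    f"line {lineno}: sequence data before any '>' header"
                )
            body.append("".join(line.split()))
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | PathLike | TextIO) -> None:
    """Write records as 60-column-wrapped FASTA (via Bio.SeqIO)."""
    bio = (
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    )
    if hasattr(path, "write"):
        SeqIO.write(bio, path, "fasta")
    else:
        with open(path, "w") as fh:
            SeqIO.write(bio, fh, "fasta")


def fasta_string(records: Iterable[SequenceRecord]) -> str:
    """Render records as a FASTA-formatted string."""
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()


def write_manifest(records: Iterable[SequenceRecord], path: str | PathLike | TextIO) -> None:
    """Write a tab-separated dataset manifest of (id, length, source)."""
    rows = "".join(f"{r.id}\t{len(r)}\t{r.source.value}\n" for r in records)
    if hasattr(path, "write"):
        path.write("id\tlength\tsource\n" + rows)
    else:
        with open(path, "w") as fh:
            fh.write("id\tlength\tsource\n" + rows)


def split_dataset(
    records: Sequence[SequenceRecord],
    validation_fraction: float = 0.1,
    seed: int = 0,
) -> DatasetSplit:
    """Randomly hold out a validation fraction of the dataset.

    The validation set size is ``floor(validation_fraction * N)``, but at
    least 1 and at most N-1 so both halves are non-empty.  The same seed
    always produces the identical partition.
    """
    if not (0.0 < validation_fraction < 1.0):
        raise ValueError("validation_fraction must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_val = min(max(int(math.floor(validation_fraction * n)), 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val_idx = set(perm[:n_val].tolist())
    train = [records[i] for i in range(n) if i not in val_idx]
    validation = [records[i] for i in sorted(val_idx)]
    return DatasetSplit(
        train=train,
        validation=validation,
        seed=seed,
        validation_fraction=validation_fraction,
    )


def make_random_dataset(
    n: int,
    alphabet: str = DEFAULT_ALPHABET,
    length_spec: LengthSpec | None = None,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Build the random control set by concatenating alphabet symbols.

    Each sequence's length is drawn from the (truncated normal) length
    distribution; residues are drawn uniformly from the alphabet.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(set(alphabet)) != len(alphabet):
        raise ValueError("alphabet contains duplicate symbols")
    spec = length_spec or LengthSpec()
    rng = np.random.default_rng(seed)
    lengths = spec.sample_lengths(n, rng)
    symbols = np.frombuffer(alphabet.encode("ascii"), dtype="S1")
    records = []
    for i, L in enumerate(lengths):
        idx = rng.integers(0, len(alphabet), size=int(L))
        seq = b"".join(symbols[idx]).decode("ascii")
        records.append(SequenceRecord(id=f"random_{i:05d}", sequence=seq, source=Source.RANDOM))
    return records


def length_matched_subsample(
    pool: Sequence[SequenceRecord],
    reference: Sequence[SequenceRecord],
    n: int,
    tolerance: float = 2.0,
    seed: int = 0,
    max_tries: int = 10_000,
) -> list[SequenceRecord]:
    """Select ``n`` pool records whose length mean and sd match a reference.

    Seeded rejection sampling over random n-subsets: the first subset whose
    length mean and standard deviation are both within ``tolerance`` residues
    of the reference's is returned.  If no subset qualifies within
    ``max_tries`` draws, a :class:`MatchingFailureError` reports the closest
    moments achieved.
    """
    if len(pool) < n:
        raise ValueError(f"pool of {len(pool)} cannot supply n={n}")
    if not reference:
        raise ValueError("reference must be non-empty")
    ref_lengths = np.array([len(r) for r in reference], dtype=float)
    ref_mean = float(ref_lengths.mean())
    ref_sd = float(ref_lengths.std(ddof=0))
    pool_lengths = np.array([len(r) for r in pool], dtype=float)

    rng = np.random.default_rng(seed)
    best_score = math.inf
    best = (math.nan, math.nan)
    for _ in range(max_tries):
        idx = rng.choice(len(pool), size=n, replace=False)
        m = float(pool_lengths[idx].mean())
        s = float(pool_lengths[idx].std(ddof=0))
        dm, ds = abs(m - ref_mean), abs(s - ref_sd)
        if dm <= tolerance and ds <= tolerance:
            return [pool[i] for i in sorted(idx.tolist())]
        score = max(dm, ds)
        if score < best_score:
            best_score = score
            best = (m, s)
    raise MatchingFailureError(
        f"no subsample matched mean {ref_mean:.1f} / sd {ref_sd:.1f} within "
        f"±{tolerance} after {max_tries} tries; best attempt had mean "
        f"{best[0]:.1f} / sd {best[1]:.1f}",
        best_mean=best[0],
        best_sd=best[1],
    )


def filter_truncated(generated: Iterable) -> list[SequenceRecord]:
    """Keep only EOS-terminated generations, as ``generated`` records.

    Sequences whose emission was cut by the token budget (``terminated``
    False) are discarded, mirroring the removal of window-context-truncated
    samples when assembling a generated evaluation set.
    """
    out = []
    for i, g in enumerate(generated):
        if g.terminated and g.sequence:
            out.append(
                SequenceRecord(
                    id=f"generated_{i:05d}",
                    sequence=g.sequence,
                    source=Source.GENERATED,
                )
            )
    return out
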