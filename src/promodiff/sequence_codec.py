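"""Promoter dataset containers, encodings and strength normalization.

A promoter here is a fixed-length DNA sequence taken immediately upstream of a
transcription start site (TSS), optionally labelled with an experimentally
measured expression strength (e.g. from dRNA-seq).  This module provides:

* :class:`PromoterRecord` / :class:`PromoterDataset` — the unit of exchange
  between every other module;
* one-hot encoding/decoding over the fixed channel order ``(A, T, C, G)``,
  the representation the diffusion generator operates on;
* the three integer token streams consumed by the strength predictor:
  single-nucleotide tokens (0–3), overlapping dinucleotide tokens (4–23, the
  last position padded with a sentinel "0" partner giving codes 20–23) and
  positional indices (0…L−1);
* strength preprocessing: a base-10 log transform followed by min–max
  normalization to [0, 1], with invertible parameters;
* CSV/TSV and FASTA readers/writers and a seeded train/test split.

Coordinate convention: 0-based index ``i`` in a length-L sequence corresponds
to TSS-relative position ``i − L`` (index L−1 is position −1, the base just
upstream of the TSS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "ALPHABET",
    "NUCLEOTIDE_TO_INDEX",
    "DINUCLEOTIDE_BASE",
    "PAD_BASE",
    "PromoterRecord",
    "PromoterDataset",
    "NormalizationParams",
    "read_promoter_table",
    "write_promoter_table",
    "write_fasta",
    "one_hot_encode",
    "one_hot_encode_batch",
    "one_hot_decode",
    "encode_sequence_tokens",
    "encode_dinucleotide_tokens",
    "encode_position_tokens",
    "log_transform",
    "minmax_normalize",
    "minmax_denormalize",
    "split_dataset",
    "tss_position",
]


class ValidationError(ValueError):
    """Input data violates a contract (alphabet, lengths, strengths …)."""


class ConfigurationError(ValueError):
    """A parameter or config value is out of its allowed range."""


ALPHABET = "ATCG"
NUCLEOTIDE_TO_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: First dinucleotide code: pair (A, A).  Codes run row-major over
#: (A,T,C,G) × (A,T,C,G), i.e. AA=4, AT=5, AC=6, AG=7, TA=8, …, GG=19.
DINUCLEOTIDE_BASE = 4
#: Codes 20–23 encode the padded final pair (A0, T0, C0, G0).
PAD_BASE = 20
#: Total token vocabulary for the combined single/dinucleotide streams.
TOKEN_VOCABULARY = 24


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter sequence with an optional positive strength label."""

    id: str
    sequence: str
    strength: float | None = None

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence, self.id)
        if self.strength is not None:
            if not math.isfinite(self.strength) or self.strength <= 0:
                raise ValidationError(
                    f"record {self.id!r}: strength must be finite and > 0, "
                    f"got {self.strength!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _validate_sequence(sequence: str, record_id: str) -> None:
    if not sequence:
        raise ValidationError(f"record {record_id!r}: empty sequence")
    bad = set(sequence) - set(ALPHABET)
    if bad:
        raise ValidationError(
            f"record {record_id!r}: sequence contains characters outside "
            f"{{A,T,C,G}}: {sorted(bad)}"
        )


@dataclass(frozen=True)
class PromoterDataset:
    """An ordered, uniform-length collection of :class:`PromoterRecord`."""

    records: tuple[PromoterRecord, ...]
    sequence_length: int = field(init=False)

    def __init__(self, records: Iterable[PromoterRecord]):
        records = tuple(records)
        if not records:
            raise ValidationError("dataset must contain at least one record")
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            offenders = sorted(
                r.id for r in records if len(r) != len(records[0])
            )[:10]
            raise ValidationError(
                f"sequences have mixed lengths {sorted(lengths)}; "
                f"offending ids include {offenders}"
            )
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})[:10]
            raise ValidationError(f"duplicate record ids: {dupes}")
        object.__setattr__(self, "records", records)
        object.__setattr__(self, "sequence_length", len(records[0]))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PromoterRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PromoterRecord:
        return self.records[i]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def strengths(self) -> np.ndarray:
        missing = [r.id for r in self.records if r.strength is None]
        if missing:
            raise ValidationError(
                f"records without strength labels: {missing[:10]}"
            )
        return np.array([r.strength for r in self.records], dtype=float)

    @property
    def has_strengths(self) -> bool:
        return all(r.strength is not None for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sequence": self.sequences,
                "strength": [r.strength for r in self.records],
            }
        )


def tss_position(index: int, length: int) -> int:
    """Map a 0-based sequence index to its TSS-relative (negative) position."""
    if not 0 <= index < length:
        raise ValidationError(f"index {index} outside [0, {length})")
    return index - length


# ---------------------------------------------------------------------------
# file I/O


def read_promoter_table(
    path: str | Path,
    seq_column: str = "sequence",
    strength_column: str | None = "strength",
    id_column: str | None = "id",
    strict_alphabet: bool = True,
) -> PromoterDataset:
    """Read a promoter dataset from CSV/TSV (header row) or FASTA.

    FASTA input yields sequence-only records.  For tabular input the strength
    column is optional; set ``strength_column=None`` to ignore it.  With
    ``strict_alphabet=False`` records containing non-ACGT characters are
    dropped instead of raising.
    """
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        raw = [(rec.id, str(rec.seq).upper(), None) for rec in SeqIO.parse(str(path), "fasta")]
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        frame = pd.read_csv(path, sep=sep)
        if seq_column not in frame.columns:
            raise ConfigurationError(
                f"column {seq_column!r} not in {list(frame.columns)}"
            )
        has_strength = strength_column is not None and strength_column in frame.columns
        if strength_column is not None and not has_strength:
            # Tables without labels are fine (generation task); only error if
            # the caller named a column that plainly should exist.
            if strength_column != "strength":
                raise ConfigurationError(
                    f"column {strength_column!r} not in {list(frame.columns)}"
                )
        ids = (
            frame[id_column].astype(str)
            if id_column is not None and id_column in frame.columns
            else pd.Series([f"seq_{i}" for i in range(len(frame))])
        )
        raw = [
            (
                str(ids.iloc[i]),
                str(frame[seq_column].iloc[i]).upper(),
                float(frame[strength_column].iloc[i]) if has_strength else None,
            )
            for i in range(len(frame))
        ]
    records = []
    for rec_id, seq, strength in raw:
        try:
            records.append(PromoterRecord(rec_id, seq, strength))
        except ValidationError:
            if strict_alphabet:
                raise
    if not records:
        raise ValidationError(f"no valid records in {path}")
    return PromoterDataset(records)


def write_promoter_table(dataset: PromoterDataset, path: str | Path) -> None:
    frame = dataset.to_frame()
    if not dataset.has_strengths:
        frame = frame.drop(columns=["strength"])
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    frame.to_csv(path, sep=sep, index=False)


def write_fasta(sequences: Sequence[str] | PromoterDataset, path: str | Path) -> None:
    if isinstance(sequences, PromoterDataset):
        records = [
            SeqRecord(Seq(r.sequence), id=r.id, description="")
            for r in sequences
        ]
    else:
        records = [
            SeqRecord(Seq(s), id=f"seq_{i}", description="")
            for i, s in enumerate(sequences)
        ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# encodings


def one_hot_encode(sequence: str | PromoterRecord) -> np.ndarray:
    """Encode a sequence as an L×4 binary matrix, channel order (A, T, C, G)."""
    if isinstance(sequence, PromoterRecord):
        sequence = sequence.sequence
    _validate_sequence(sequence, "<anonymous>")
    idx = np.fromiter((NUCLEOTIDE_TO_INDEX[b] for b in sequence), dtype=np.intp)
    out = np.zeros((len(sequence), 4))
    out[np.arange(len(sequence)), idx] = 1.0
    return out


def one_hot_encode_batch(sequences: Sequence[str]) -> np.ndarray:
    """Stack one-hot matrices of equal-length sequences into (m, L, 4)."""
    return np.stack([one_hot_encode(s) for s in sequences])


def one_hot_decode(matrix: np.ndarray) -> str:
    """Decode an L×4 real matrix to a sequence by per-row argmax.

    Ties break toward the lowest channel index (A before T before C before G),
    so decoding is deterministic on arbitrary real-valued matrices such as
    diffusion-model outputs.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise ValidationError(f"expected an L×4 matrix, got shape {matrix.shape}")
    return "".join(ALPHABET[i] for i in matrix.argmax(axis=1))


def encode_sequence_tokens(sequence: str) -> np.ndarray:
    """Map nucleotides to integers: A→0, T→1, C→2, G→3."""
    _validate_sequence(sequence, "<anonymous>")
    return np.fromiter((NUCLEOTIDE_TO_INDEX[b] for b in sequence), dtype=np.int64)


def encode_dinucleotide_tokens(sequence: str) -> np.ndarray:
    """Overlapping dinucleotide tokens, padded at the end.

    Token ``i`` encodes the pair ``(s[i], s[i+1])`` via the row-major map
    AA=4, AT=5, AC=6, AG=7, TA=8, …, GG=19.  The final position has no
    successor; it is padded with a sentinel partner, giving A0=20, T0=21,
    C0=22, G0=23.  Output length equals the sequence length so the three
    predictor input streams stay aligned.
    """
    codes = encode_sequence_tokens(sequence)
    out = np.empty(len(codes), dtype=np.int64)
    out[:-1] = DINUCLEOTIDE_BASE + 4 * codes[:-1] + codes[1:]
    out[-1] = PAD_BASE + codes[-1]
    return out


def encode_position_tokens(length: int) -> np.ndarray:
    """Positional indices 0 … L−1 (fed to a learned embedding downstream)."""
    if length < 1:
        raise ValidationError(f"length must be ≥ 1, got {length}")
    return np.arange(length, dtype=np.int64)


# ---------------------------------------------------------------------------
# strength preprocessing


@dataclass(frozen=True)
class NormalizationParams:
    """Min/max of the log10-transformed strengths, for invertible scaling."""

    log_min: float
    log_max: float

    def __post_init__(self) -> None:
        if not self.log_max > self.log_min:
            raise ValidationError(
                f"degenerate normalization range [{self.log_min}, {self.log_max}]"
            )


def log_transform(
    strengths: Sequence[float] | np.ndarray, pseudocount: float = 0.0
) -> np.ndarray:
    """Base-10 logarithm of strengths; strengths must be positive.

    Raw dRNA-seq strengths are right-skewed, so the log compresses the
    dynamic range before min–max scaling.  A pseudocount may be added first
    for data containing zeros (disabled by default).
    """
    x = np.asarray(strengths, dtype=float) + pseudocount
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise ValidationError(
            f"nonpositive strength at indices {bad[:10].tolist()} "
            "(enable a pseudocount to admit zeros)"
        )
    return np.log10(x)


def minmax_normalize(
    log_values: Sequence[float] | np.ndarray,
    params: NormalizationParams | None = None,
) -> tuple[np.ndarray, NormalizationParams]:
    """Scale log-strengths to [0, 1]: (x − min) / (max − min).

    When ``params`` is given (e.g. fitted on a training split) they are reused
    and values outside the training range may fall outside [0, 1].
    """
    x = np.asarray(log_values, dtype=float)
    if params is None:
        if x.size < 2 or np.isclose(x.min(), x.max()):
            raise ValidationError(
                "min-max normalization needs at least two distinct values"
            )
        params = NormalizationParams(float(x.min()), float(x.max()))
    return (x - params.log_min) / (params.log_max - params.log_min), params


def minmax_denormalize(
    normalized: Sequence[float] | np.ndarray, params: NormalizationParams
) -> np.ndarray:
    """Invert :func:`minmax_normalize` back to the log10 scale."""
    x = np.asarray(normalized, dtype=float)
    return x * (params.log_max - params.log_min) + params.log_min


def normalize_strengths(
    strengths: Sequence[float] | np.ndarray,
    params: NormalizationParams | None = None,
    pseudocount: float = 0.0,
) -> tuple[np.ndarray, NormalizationParams]:
    """Compose the log transform and min–max scaling (raw → [0, 1])."""
    return minmax_normalize(log_transform(strengths, pseudocount), params)


def denormalize_strengths(
    normalized: Sequence[float] | np.ndarray, params: NormalizationParams
) -> np.ndarray:
    """Invert :func:`normalize_strengths` (normalized → raw strength)."""
    return 10.0 ** minmax_denormalize(normalized, params)


# ---------------------------------------------------------------------------
# splitting


def split_dataset(
    dataset: PromoterDataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[PromoterDataset, PromoterDataset]:
    """Disjoint, exhaustive, seeded train/test partition (default 4:1)."""
    if not 0.0 < test_fraction < 1.0:
        raise ConfigurationError(
            f"test_fraction must be in (0, 1), got {test_fraction}"
        )
    n = len(dataset)
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [r for i, r in enumerate(dataset) if i not in test_idx]
    test = [r for i, r in enumerate(dataset) if i in test_idx]
    return PromoterDataset(train), PromoterDataset(test)
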