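"""Generation-quality statistics for synthetic promoter sets.

Whether a generative model has captured the composition of a natural promoter
corpus is judged here on sequence statistics alone:

* **k-mer spectra** — sliding a window of length k with step 1 over every
  sequence, the frequency of each k-mer is its count divided by the total
  window count ``m·(n−k+1)`` (m sequences of length n);
* **cross-set k-mer PCC** — Pearson correlation between two spectra densified
  over all 4^k possible k-mers (absent k-mers enter as zeros, so rare words
  pull the correlation down as they should);
* **positional profiles** — the fraction of sequences carrying a given k-mer
  at each start position, which localizes elements such as the −10 TATAAT box;
* **sequence-logo matrices** — per-position base probabilities and Shannon
  information content in bits (0–2 for DNA), with letter heights p·IC.

All statistics are returned as plain arrays/DataFrames; plotting is a thin
optional layer on top (see :func:`plot_logo`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence_codec import ALPHABET, ValidationError

__all__ = [
    "pcc",
    "KmerSpectrum",
    "kmer_spectrum",
    "all_kmers",
    "kmer_pcc",
    "kmer_pcc_trajectory",
    "PositionalProfile",
    "positional_profile",
    "top_kmers",
    "LogoMatrix",
    "logo_matrix",
]


def pcc(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Pearson correlation coefficient between two equal-length samples.

    Computed as the ratio of the sample covariance to the product of the
    sample standard deviations.  Degenerate (constant) inputs raise rather
    than silently returning 0, since a vanishing variance makes the
    coefficient undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("PCC needs at least two observations")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx**2).sum() * (dy**2).sum())
    if denom == 0.0:
        raise ValidationError("PCC undefined for constant input")
    return float((dx * dy).sum() / denom)


# ---------------------------------------------------------------------------
# k-mer spectra


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers over (A, T, C, G) in lexicographic channel order."""
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


@dataclass(frozen=True)
class KmerSpectrum:
    """Sliding-window k-mer frequencies over a sequence set."""

    k: int
    frequencies: dict[str, float]

    def densify(self) -> np.ndarray:
        """Frequency vector over all 4^k k-mers, zeros included."""
        return np.array([self.frequencies.get(w, 0.0) for w in all_kmers(self.k)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"kmer": all_kmers(self.k), "frequency": self.densify()}
        )


def _check_uniform(sequences: Sequence[str]) -> int:
    if not sequences:
        raise ValidationError("empty sequence set")
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise ValidationError(f"sequences have mixed lengths {sorted(lengths)}")
    return lengths.pop()


def kmer_spectrum(sequences: Sequence[str], k: int) -> KmerSpectrum:
    """Count every length-k window (step 1) and normalize by m·(n−k+1)."""
    n = _check_uniform(sequences)
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside [1, {n}]")
    counts: dict[str, int] = {}
    for seq in sequences:
        for i in range(n - k + 1):
            word = seq[i : i + k]
            counts[word] = counts.get(word, 0) + 1
    total = len(sequences) * (n - k + 1)
    return KmerSpectrum(k, {w: c / total for w, c in counts.items()})


def kmer_pcc(set_a: Sequence[str], set_b: Sequence[str], k: int) -> float:
    """PCC between the densified k-mer spectra of two sequence sets.

    Sets may have different sequence lengths; frequencies are normalized per
    set, so the comparison is composition-based, not count-based.
    """
    fa = kmer_spectrum(set_a, k).densify()
    fb = kmer_spectrum(set_b, k).densify()
    return pcc(fa, fb)


def kmer_pcc_trajectory(
    sample_at_checkpoint: Callable[[int, int, int], list[str]],
    checkpoints: Sequence[int],
    natural: Sequence[str],
    ks: Iterable[int] = (2, 3, 4, 5, 6),
    samples_per_checkpoint: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """k-mer PCC between sampled and natural sequences across training.

    ``sample_at_checkpoint(epoch, count, seed)`` draws sequences from the
    generator state saved at that epoch (see the diffusion module's training
    log).  Returns a tidy table with one row per (epoch, k).
    """
    if not checkpoints:
        raise ValidationError("no checkpoints to evaluate")
    ks = list(ks)
    rows = []
    for i, epoch in enumerate(checkpoints):
        samples = sample_at_checkpoint(epoch, samples_per_checkpoint, seed + i)
        for k in ks:
            rows.append(
                {"epoch": epoch, "k": k, "pcc": kmer_pcc(samples, natural, k)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# positional statistics


@dataclass(frozen=True)
class PositionalProfile:
    """Per-start-position occurrence fraction of one k-mer."""

    kmer: str
    values: np.ndarray  # length n − k + 1, entries in [0, 1]

    def peak(self) -> int:
        """Start index of the maximal occurrence fraction."""
        return int(self.values.argmax())

    def to_frame(self) -> pd.DataFrame:
        n_starts = len(self.values)
        return pd.DataFrame(
            {
                "kmer": self.kmer,
                "start": np.arange(n_starts),
                "frequency": self.values,
            }
        )


def positional_profile(sequences: Sequence[str], kmer: str) -> PositionalProfile:
    """Fraction of sequences carrying ``kmer`` at each start position."""
    n = _check_uniform(sequences)
    k = len(kmer)
    if not 1 <= k <= n:
        raise ValidationError(f"k-mer length {k} outside [1, {n}]")
    counts = np.zeros(n - k + 1)
    for seq in sequences:
        for i in range(n - k + 1):
            if seq[i : i + k] == kmer:
                counts[i] += 1
    return PositionalProfile(kmer, counts / len(sequences))


def top_kmers(sequences: Sequence[str], k: int = 6, count: int = 6) -> list[str]:
    """The ``count`` most frequent k-mers of a set, by total occurrence."""
    spectrum = kmer_spectrum(sequences, k)
    ranked = sorted(
        spectrum.frequencies.items(), key=lambda kv: (-kv[1], kv[0])
    )
    return [w for w, _ in ranked[:count]]


# ---------------------------------------------------------------------------
# sequence logos


@dataclass(frozen=True)
class LogoMatrix:
    """Per-position base probabilities, information content and letter heights."""

    probabilities: np.ndarray  # (L, 4), rows sum to 1; channels (A, T, C, G)
    information: np.ndarray  # (L,), bits in [0, 2]

    @property
    def heights(self) -> np.ndarray:
        return self.probabilities * self.information[:, None]

    def to_frame(self) -> pd.DataFrame:
        length = self.probabilities.shape[0]
        rows = []
        for pos in range(length):
            for ch, base in enumerate(ALPHABET):
                rows.append(
                    {
                        "position": pos,
                        "base": base,
                        "probability": self.probabilities[pos, ch],
                        "height": self.heights[pos, ch],
                    }
                )
        return pd.DataFrame(rows)


def logo_matrix(sequences: Sequence[str]) -> LogoMatrix:
    """Base probabilities and Shannon information content per position.

    IC(position) = 2 + Σ_b p_b·log2(p_b) bits, with 0·log2(0) taken as 0; a
    fully conserved column scores 2 bits, a uniform column 0.  No small-sample
    correction is applied (the sets this package evaluates are large).
    """
    n = _check_uniform(sequences)
    m = len(sequences)
    counts = np.zeros((n, 4))
    index = {b: i for i, b in enumerate(ALPHABET)}
    for seq in sequences:
        for pos, base in enumerate(seq):
            counts[pos, index[base]] += 1
    probs = counts / m
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return LogoMatrix(probs, np.clip(info, 0.0, 2.0))


def plot_logo(logo: LogoMatrix, ax=None, tss_relative: bool = True):
    """Render a letter-height bar logo with matplotlib (optional layer)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.25 * len(logo.information), 2.0))
    length = logo.probabilities.shape[0]
    x = np.arange(length) - length if tss_relative else np.arange(length)
    colors = {"A": "#2ca02c", "T": "#d62728", "C": "#1f77b4", "G": "#ff7f0e"}
    bottom = np.zeros(length)
    order = np.argsort(logo.heights, axis=1)
    for rank in range(4):
        chans = order[:, rank]
        h = logo.heights[np.arange(length), chans]
        ax.bar(
            x,
            h,
            bottom=bottom,
            width=0.9,
            color=[colors[ALPHABET[c]] for c in chans],
        )
        bottom += h
    ax.set_xlabel("position relative to TSS")
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    return ax
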