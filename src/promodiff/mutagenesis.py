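"""In-silico saturation mutagenesis driven by a trained strength predictor.

Each selected test promoter is mutated at every position to each of the three
alternative bases, and the predicted strength change
``Δ = predict(mutant) − predict(original)`` is recorded on the predictor's
normalized training scale (raw-scale deltas are available via a flag).
Positions are reported in TSS-relative coordinates (index i of a length-L
sequence ↔ position i − L, so the base next to the TSS is −1).

Mutations fall into two classes:

* **within_group** — swaps inside a pairing group: A↔T or C↔G;
* **cross_group** — substitutions crossing between the {A, T} and {C, G}
  groups.

Per-position summaries give the mean |Δ| per class (the sensitivity profile
in which the −10/−35 elements should stand out for a predictor that has
learned them) and box statistics (median, quartiles, 1.5×IQR whiskers) per
(ref, alt) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .predictor import TrainedPredictor
from .sequence_codec import (
    ALPHABET,
    ConfigurationError,
    PromoterDataset,
    ValidationError,
)

__all__ = [
    "MutationRecord",
    "classify_mutation",
    "saturation_mutagenesis",
    "PositionSummary",
    "position_summaries",
    "region_contrast",
    "records_to_frame",
]

_GROUPS = {"A": "AT", "T": "AT", "C": "CG", "G": "CG"}


def classify_mutation(ref_base: str, alt_base: str) -> str:
    """"within_group" for A↔T and C↔G, "cross_group" otherwise."""
    for base in (ref_base, alt_base):
        if base not in _GROUPS:
            raise ValidationError(f"invalid base {base!r}")
    if ref_base == alt_base:
        raise ValidationError(f"ref and alt are both {ref_base!r}")
    return "within_group" if _GROUPS[ref_base] == _GROUPS[alt_base] else "cross_group"


@dataclass(frozen=True)
class MutationRecord:
    """One single-base substitution and its predicted strength change."""

    sequence_id: str
    index: int  # 0-based position in the sequence
    tss_position: int  # index − L, negative
    ref_base: str
    alt_base: str
    mutation_class: str
    delta: float


def saturation_mutagenesis(
    test: PromoterDataset,
    model: TrainedPredictor,
    sample_size: int = 200,
    seed: int = 0,
    scale: str = "normalized",
) -> list[MutationRecord]:
    """Score all single-base substitutions of a random test subsample.

    Exactly ``sample_size × L × 3`` records are produced.  All mutants are
    scored in one batched prediction pass, so the cost is one forward pass
    over ``sample_size × (3L + 1)`` sequences.
    """
    if sample_size < 1 or sample_size > len(test):
        raise ConfigurationError(
            f"sample_size must be in [1, {len(test)}], got {sample_size}"
        )
    if test.sequence_length != model.sequence_length:
        raise ValidationError(
            f"dataset length {test.sequence_length} does not match model "
            f"length {model.sequence_length}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(test), size=sample_size, replace=False)
    L = test.sequence_length

    originals = [test[i] for i in chosen]
    mutants: list[str] = []
    meta: list[tuple[str, int, str, str]] = []
    for rec in originals:
        seq = rec.sequence
        for pos in range(L):
            ref = seq[pos]
            for alt in ALPHABET:
                if alt == ref:
                    continue
                mutants.append(seq[:pos] + alt + seq[pos + 1 :])
                meta.append((rec.id, pos, ref, alt))

    base_pred = model.predict([r.sequence for r in originals], scale=scale)
    base_by_id = {r.id: p for r, p in zip(originals, base_pred)}
    mut_pred = model.predict(mutants, scale=scale)

    return [
        MutationRecord(
            sequence_id=rec_id,
            index=pos,
            tss_position=pos - L,
            ref_base=ref,
            alt_base=alt,
            mutation_class=classify_mutation(ref, alt),
            delta=float(p - base_by_id[rec_id]),
        )
        for (rec_id, pos, ref, alt), p in zip(meta, mut_pred)
    ]


def records_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass(frozen=True)
class PositionSummary:
    """Per-(position, class) mean |Δ| plus per-(ref, alt) box statistics."""

    tss_position: int
    mutation_class: str
    mean_abs_delta: float
    pair_stats: dict[tuple[str, str], dict[str, float]]


def _box_stats(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    in_lo = values[values >= q1 - 1.5 * iqr]
    in_hi = values[values <= q3 + 1.5 * iqr]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(in_lo.min()) if in_lo.size else float(q1),
        "whisker_high": float(in_hi.max()) if in_hi.size else float(q3),
        "n": int(values.size),
    }


def position_summaries(records: Sequence[MutationRecord]) -> list[PositionSummary]:
    """Group deltas by (TSS position, mutation class); order-invariant."""
    if not records:
        raise ValidationError("no mutation records to summarize")
    frame = records_to_frame(records)
    out: list[PositionSummary] = []
    for (pos, mclass), group in sorted(
        frame.groupby(["tss_position", "mutation_class"]),
        key=lambda kv: (kv[0][0], kv[0][1]),
    ):
        pair_stats = {
            (ref, alt): _box_stats(sub["delta"].to_numpy())
            for (ref, alt), sub in group.groupby(["ref_base", "alt_base"])
        }
        out.append(
            PositionSummary(
                tss_position=int(pos),
                mutation_class=str(mclass),
                mean_abs_delta=float(group["delta"].abs().mean()),
                pair_stats=pair_stats,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[PositionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tss_position": [s.tss_position for s in summaries],
            "mutation_class": [s.mutation_class for s in summaries],
            "mean_abs_delta": [s.mean_abs_delta for s in summaries],
        }
    )


def region_contrast(
    summaries: Sequence[PositionSummary],
    regions: Sequence[tuple[int, int]],
) -> pd.DataFrame:
    """Mean of per-position mean |Δ| inside each TSS-relative region vs outside.

    ``regions`` are inclusive (start, end) intervals in TSS coordinates, e.g.
    ``[(-12, -7), (-36, -31)]`` for the −10 and −35 elements.  Returns one row
    per (region, mutation class) with the in-region and complement means.
    """
    frame = summaries_to_frame(list(summaries))
    positions = frame["tss_position"].to_numpy()
    lo, hi = positions.min(), positions.max()
    rows = []
    region_list = list(regions)
    for start, end in region_list:
        if start > end or start < lo or end > hi:
            raise ConfigurationError(
                f"region [{start}, {end}] malformed or outside [{lo}, {hi}]"
            )
    for start, end in region_list:
        inside = (frame["tss_position"] >= start) & (frame["tss_position"] <= end)
        for mclass, group in frame.groupby("mutation_class"):
            sel = inside[group.index]
            rows.append(
                {
                    "region_start": start,
                    "region_end": end,
                    "mutation_class": mclass,
                    "region_mean_abs_delta": float(
                        group.loc[sel, "mean_abs_delta"].mean()
                    ),
                    "background_mean_abs_delta": float(
                        group.loc[~sel, "mean_abs_delta"].mean()
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_start",
            "region_end",
            "mutation_class",
            "region_mean_abs_delta",
            "background_mean_abs_delta",
        ],
    )
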