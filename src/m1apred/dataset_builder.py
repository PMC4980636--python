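"""Benchmark-dataset construction: redundancy reduction and balanced sampling.

The benchmark recipe for m1A windows is: collect positive windows, drop
near-duplicates above an 80% identity threshold, then repeatedly draw
balanced negative sets from the (much larger) pool of unmodified-adenosine
windows so that model quality can be shown to be insensitive to the
particular negative draw.

Because all windows share one length and are anchored on the center
adenosine, sequence identity is computed position-wise (Hamming-based,
ungapped): ``identity = matching positions / length``.  Redundancy
reduction is greedy and order-deterministic — a record is kept iff its
identity to every previously kept record is <= the threshold (strictly
*more than* the threshold is removed, so identity exactly 0.80 survives an
0.80 threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ContaminationError, ParameterError, SamplingError
from .sequence_io import (
    DEFAULT_WINDOW_LENGTH,
    SequenceRecord,
    WindowDataset,
    validate_window,
)


class ClassImbalanceWarning(UserWarning):
    """Positive and negative class sizes differ in an assembled dataset."""


def _as_matrix(records: list[SequenceRecord]) -> np.ndarray:
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ParameterError(
            f"records must share one length for position-wise identity; "
            f"found lengths {sorted(lengths)}"
        )
    return np.frombuffer(
        "".join(r.seq for r in records).encode(), dtype="S1"
    ).reshape(len(records), -1)


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Ungapped position-wise identity between two equal-length windows."""
    if len(a.seq) != len(b.seq):
        raise ParameterError(
            f"cannot compare windows of lengths {len(a.seq)} and {len(b.seq)}"
        )
    matches = sum(x == y for x, y in zip(a.seq, b.seq))
    return matches / len(a.seq)


def reduce_redundancy(
    records: list[SequenceRecord], threshold: float = 0.8
) -> list[SequenceRecord]:
    """Greedy redundancy reduction at a position-wise identity threshold.

    Records are scanned in input order; one is retained iff its identity to
    every previously retained record is <= ``threshold``.  Retained records
    come back in their original order, so the first occurrence of a cluster
    acts as its representative.  Idempotent.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError(f"threshold must lie in (0, 1], got {threshold}")
    if not records:
        return []
    mat = _as_matrix(records)
    length = mat.shape[1]
    kept_rows: list[int] = []
    for i in range(len(records)):
        if kept_rows:
            identities = (mat[kept_rows] == mat[i]).sum(axis=1) / length
            if (identities > threshold).any():
                continue
        kept_rows.append(i)
    return [records[i] for i in kept_rows]


@dataclass(frozen=True)
class SamplingPlan:
    """How many balanced negative sets to draw, and how reproducibly.

    Each repeat ``i`` samples ``n_negatives`` records without replacement
    using the derived seed ``seed + i``, so all repeats are reproducible
    from one configuration value.
    """

    n_negatives: int
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_negatives <= 0:
            raise ParameterError("n_negatives must be positive")
        if self.n_repeats <= 0:
            raise ParameterError("n_repeats must be positive")


def sample_negatives(
    pool: list[SequenceRecord], plan: SamplingPlan
) -> list[list[SequenceRecord]]:
    """Draw ``plan.n_repeats`` balanced negative sets from the pool.

    Each repeat is an independent uniform sample without replacement of
    size ``plan.n_negatives``; sampled records keep their pool order.
    Deterministic given (pool, plan).
    """
    if plan.n_negatives > len(pool):
        raise SamplingError(
            f"cannot sample {plan.n_negatives} negatives from a pool of "
            f"{len(pool)}"
        )
    repeats = []
    for i in range(plan.n_repeats):
        rng = np.random.default_rng(plan.seed + i)
        idx = rng.choice(len(pool), size=plan.n_negatives, replace=False)
        repeats.append([pool[j] for j in sorted(idx)])
    return repeats


def assemble_dataset(
    positives: list[SequenceRecord],
    negatives: list[SequenceRecord],
    tag: str = "",
    window_length: int = DEFAULT_WINDOW_LENGTH,
) -> WindowDataset:
    """Combine labeled positive and negative windows into one dataset.

    Every window is validated (length, center adenosine).  Identical
    sequences occurring in both classes raise :class:`ContaminationError`;
    unequal class sizes emit a :class:`ClassImbalanceWarning` but proceed.
    """
    for rec in positives + negatives:
        validate_window(rec, window_length)
    overlap = {r.seq for r in positives} & {r.seq for r in negatives}
    if overlap:
        offenders = [
            r.id for r in positives + negatives if r.seq in overlap
        ]
        raise ContaminationError(
            f"{len(overlap)} sequence(s) appear in both classes; "
            f"offending record ids: {offenders}"
        )
    if len(positives) != len(negatives):
        warnings.warn(
            f"class imbalance: {len(positives)} positives vs "
            f"{len(negatives)} negatives",
            ClassImbalanceWarning,
            stacklevel=2,
        )
    records = [r.with_label("positive") for r in positives] + [
        r.with_label("negative") for r in negatives
    ]
    return WindowDataset(records=records, window_length=window_length, tag=tag)


def dataset_manifest(
    dataset: WindowDataset, repeat_index: int | None = None
) -> pd.DataFrame:
    """Tabular manifest (id, label, tag, repeat index) for TSV export."""
    return pd.DataFrame(
        {
            "id": [r.id for r in dataset.records],
            "label": [r.label for r in dataset.records],
            "tag": dataset.tag,
            "repeat": repeat_index if repeat_index is not None else pd.NA,
        }
    )
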