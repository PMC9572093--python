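"""Activity records and rank-ordered rational train/test splitting.

The splitting strategy sorts all records in ascending activity (log k7) and
transfers every ``step``-th rank, starting at ``start_offset``, to the test
set — a 5:1 split when step = 6.  The offset is an explicit parameter: which
rank is transferred first determines the resulting set sizes (e.g. 148
records split with offset 1 give 123/25, while 123 records with offset 6
give 103/20).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class ActivityRecord:
    """One compound with its measured activity (log10 k7, L mol^-1 s^-1)."""

    id: str
    logk7: float
    structure: object = None  # MolecularGraph or SMILES string; opaque here

    def __post_init__(self) -> None:
        if not np.isfinite(self.logk7):
            raise ValueError(f"non-finite logk7 for record {self.id!r}")


@dataclass
class SplitResult:
    train: list[ActivityRecord]
    test: list[ActivityRecord]
    start_offset: int
    step: int


def rational_split(
    records: Sequence[ActivityRecord], step: int = 6, start_offset: int = 1
) -> SplitResult:
    """Ascending-activity rank split: ranks offset, offset+step, ... go to test.

    Ties in activity are broken by id so the split is deterministic.
    """
    if step < 2:
        raise ValueError(f"step must be >= 2, got {step}")
    if not 1 <= start_offset <= step:
        raise ValueError(f"start_offset must be in [1, {step}], got {start_offset}")
    ordered = sorted(records, key=lambda r: (r.logk7, r.id))
    if len(ordered) < step:
        warnings.warn(f"fewer records ({len(ordered)}) than step ({step}); all assigned to train")
        return SplitResult(train=list(ordered), test=[], start_offset=start_offset, step=step)
    test_ranks = set(range(start_offset, len(ordered) + 1, step))
    train, test = [], []
    for rank, rec in enumerate(ordered, start=1):
        (test if rank in test_ranks else train).append(rec)
    return SplitResult(train=train, test=test, start_offset=start_offset, step=step)


def _band_percentages(values: np.ndarray, center: float, bands: Sequence[float]) -> dict[float, float]:
    return {
        b: 100.0 * float(np.mean(np.abs(values - center) <= b)) for b in bands
    }


def split_report(
    s: SplitResult, bands: Sequence[float] = (0.5, 1.0, 1.5, 2.0)
) -> dict:
    """Summary of a split: sizes, means, ranges, and the distribution of the
    test activities around the test mean and around the train mean (percent
    of test records within +-band)."""
    if not s.train or not s.test:
        raise ValueError("split_report requires non-empty train and test sets")
    y_train = np.array([r.logk7 for r in s.train])
    y_test = np.array([r.logk7 for r in s.test])
    return {
        "train": {
            "n": len(s.train),
            "mean": float(y_train.mean()),
            "range": float(y_train.max() - y_train.min()),
        },
        "test": {
            "n": len(s.test),
            "mean": float(y_test.mean()),
            "range": float(y_test.max() - y_test.min()),
        },
        "test_about_test_mean": _band_percentages(y_test, float(y_test.mean()), bands),
        "test_about_train_mean": _band_percentages(y_test, float(y_train.mean()), bands),
    }
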