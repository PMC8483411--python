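"""Three-class pIC50 activity labeling and dataset preparation.

Kinase bioactivity training data clusters around pIC50 ≈ 5 (10 µM), which
makes regression at the potent tail hard; binning into three classes turns
the problem into classification:

* ``inactive``: pIC50 < 5
* ``weak``:     5 <= pIC50 < 6
* ``potent``:   pIC50 >= 6

Boundary membership matters (5 is weak, 6 is potent) and is pinned by
tests.  The module also provides the hold-out split used to evaluate
models trained on such labels; the downstream models themselves are out of
scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "ActivityRecord",
    "pic50_class",
    "class_distribution",
    "holdout_split",
    "read_activities",
]

CLASS_LABELS = ("inactive", "weak", "potent")


@dataclass(frozen=True)
class ActivityRecord:
    compound: str
    target: str
    pic50: float

    def __post_init__(self):
        if not math.isfinite(self.pic50):
            raise ValueError(f"pIC50 must be finite, got {self.pic50}")


def pic50_class(pic50: float) -> str:
    """Class label for one pIC50 value (total over the finite reals)."""
    if not math.isfinite(pic50):
        raise ValueError(f"pIC50 must be finite, got {pic50}")
    if pic50 < 5:
        return "inactive"
    if pic50 < 6:
        return "weak"
    return "potent"


def class_distribution(
    records: Iterable[ActivityRecord | float], bins: int = 20
) -> dict:
    """Counts per class plus a pIC50 histogram summary.

    Accepts records or bare pIC50 values; counts always sum to the record
    count.
    """
    values = [r.pic50 if isinstance(r, ActivityRecord) else float(r) for r in records]
    counts = {label: 0 for label in CLASS_LABELS}
    for v in values:
        counts[pic50_class(v)] += 1
    if values:
        hist, edges = np.histogram(values, bins=bins)
        histogram = {"counts": hist.tolist(), "edges": edges.tolist()}
    else:
        histogram = {"counts": [], "edges": []}
    return {"counts": counts, "n": len(values), "histogram": histogram}


def holdout_split(
    records: Sequence[ActivityRecord],
    test_fraction: float = 0.1,
    seed: int = 0,
    stratify: bool = False,
    group_by_compound: bool = False,
) -> tuple[list[ActivityRecord], list[ActivityRecord]]:
    """Deterministic train/test partition (disjoint and exhaustive).

    ``stratify`` samples the test fraction within each activity class;
    ``group_by_compound`` keeps all records of a compound on one side, so a
    structure never appears in both train and test.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    records = list(records)
    n = len(records)
    if group_by_compound:
        compounds = sorted({r.compound for r in records})
        k = max(1, round(test_fraction * len(compounds))) if compounds else 0
        test_compounds = set(
            rng.choice(compounds, size=k, replace=False)
        ) if compounds else set()
        test = [r for r in records if r.compound in test_compounds]
        train = [r for r in records if r.compound not in test_compounds]
        return train, test
    if stratify:
        test_idx: set[int] = set()
        by_class: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            by_class.setdefault(pic50_class(r.pic50), []).append(i)
        for label in sorted(by_class):
            idx = by_class[label]
            k = max(1, round(test_fraction * len(idx)))
            test_idx.update(rng.choice(idx, size=k, replace=False).tolist())
    else:
        k = max(1, round(test_fraction * n)) if n else 0
        test_idx = set(rng.choice(n, size=k, replace=False).tolist()) if n else set()
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


def read_activities(path) -> list[ActivityRecord]:
    """Read activity records from CSV with columns compound, target, pic50."""
    df = pd.read_csv(path)
    for col in ("compound", "target", "pic50"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [
        ActivityRecord(str(r.compound), str(r.target), float(r.pic50))
        for r in df.itertuples()
    ]
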