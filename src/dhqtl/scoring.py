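"""Head-splitting severity scoring for cabbage.

Each plant is graded 0-5 from the number of split layers and the
relative split area S.  S compares the largest split's area (arc length
a x width b) to half the head's surface proxy (height c x half the
largest circumference d):

    S [%] = (a * b) / (c * d / 2) * 100

A line's head-splitting index is the grade total expressed as a
percentage of the maximum attainable (n plants x grade 5), and lines are
binned into five resistance categories on that index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SplitMeasurement",
    "LineScore",
    "GRADE_MAX",
    "split_area_ratio",
    "assign_grade",
    "head_splitting_index",
    "classify_resistance",
    "head_shape_index",
    "score_lines",
    "CATEGORIES",
]

GRADE_MAX = 5

#: resistance categories and the (lo, hi] index bands that define them;
#: the lowest band is closed at 0
CATEGORIES: tuple[tuple[str, float, float], ...] = (
    ("highly resistant", 0.0, 5.0),
    ("resistant", 5.0, 15.0),
    ("moderately resistant", 15.0, 35.0),
    ("susceptible", 35.0, 50.0),
    ("highly susceptible", 50.0, 100.0),
)


@dataclass(frozen=True)
class SplitMeasurement:
    """One plant's split geometry (cm) and split-layer count."""

    arc_length: float
    split_width: float
    head_height: float
    head_circumference: float
    split_layers: int

    def __post_init__(self) -> None:
        if min(self.arc_length, self.split_width, self.head_height,
               self.head_circumference) < 0:
            raise ValueError("lengths must be non-negative")
        if self.split_layers < 0:
            raise ValueError("layer count must be non-negative")
        if self.split_layers == 0 and (self.arc_length > 0 or self.split_width > 0):
            raise ValueError("an unsplit head cannot have a split area")


@dataclass(frozen=True)
class LineScore:
    """Per-line grades, head-splitting index (percent) and category."""

    line: str
    grades: tuple
    head_splitting_index: float
    category: str
    n_plants: int


def split_area_ratio(m: SplitMeasurement) -> float:
    """Relative split area S (percent) of one measured head."""
    s1 = m.arc_length * m.split_width
    s2 = m.head_height * m.head_circumference / 2.0
    if s2 == 0:
        if s1 > 0:
            raise ValueError("split area with zero head area: S undefined")
        return 0.0
    return s1 / s2 * 100.0


def assign_grade(layers: int, s: float) -> int:
    """Grade a head 0-5 from its split-layer count and relative area S.

    The layer count dominates; S >= 50 promotes the 2, 3-5 and 6-10
    layer classes by one grade.  Beyond 10 layers the grade is 5
    regardless of S.
    """
    if layers < 0:
        raise ValueError("layer count must be non-negative")
    if layers == 0:
        return 0
    if layers == 1:
        return 1
    severe = s >= 50
    if layers == 2:
        return 3 if severe else 2
    if layers <= 5:
        return 4 if severe else 3
    if layers <= 10:
        return 5 if severe else 4
    return 5


def grade_measurement(m: SplitMeasurement) -> int:
    return assign_grade(m.split_layers, split_area_ratio(m))


def head_splitting_index(grades) -> float:
    """Line-level index: sum of grades over n * 5, as a percentage."""
    grades = np.asarray(list(grades))
    if grades.size == 0:
        raise ValueError("no grades: cannot form an index")
    if np.any((grades < 0) | (grades > GRADE_MAX)):
        raise ValueError("grades must lie in 0..5")
    return float(grades.sum() / (grades.size * GRADE_MAX) * 100.0)


def classify_resistance(index: float) -> str:
    """Resistance category for a head-splitting index in [0, 100].

    Bands are half-open on the left -- [0, 5], (5, 15], (15, 35],
    (35, 50], (50, 100] -- so every attainable index classifies.
    """
    if not 0 <= index <= 100:
        raise ValueError("index must lie in [0, 100]")
    for name, lo, hi in CATEGORIES:
        if index <= hi:
            return name
    return CATEGORIES[-1][0]  # pragma: no cover


def head_shape_index(hvd: float, htd: float) -> float:
    """Head shape index: vertical over transverse diameter."""
    if htd <= 0:
        raise ValueError("transverse diameter must be positive")
    return hvd / htd


def score_lines(measurements: pd.DataFrame) -> pd.DataFrame:
    """Score a per-plant measurement table into per-line indices.

    Expects columns ``line, arc_length, split_width, head_height,
    head_circumference, split_layers`` (extra columns are ignored).  The
    index denominator is the number of observed plants per line; the
    output records that count so short lines are visible.
    """
    required = {"line", "arc_length", "split_width", "head_height",
                "head_circumference", "split_layers"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")
    rows = []
    for line, sub in measurements.groupby("line", sort=False):
        grades = [
            grade_measurement(
                SplitMeasurement(
                    r.arc_length, r.split_width, r.head_height,
                    r.head_circumference, int(r.split_layers),
                )
            )
            for r in sub.itertuples()
        ]
        idx = head_splitting_index(grades)
        rows.append((line, len(grades), idx, classify_resistance(idx)))
    return pd.DataFrame(rows, columns=["line", "n_plants", "index", "category"])
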