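"""Genetic-map utilities for doubled-haploid (DH) populations.

A DH line carries one of two fully homozygous genotypes at every locus,
coded ``'a'`` (first parent) or ``'b'`` (second parent), with ``'-'`` for
missing or ambiguous calls.  This module provides the map container, the
Kosambi map function and its inverse, the DH recombination-fraction
estimator, the 1:1 segregation-distortion test and map summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "kosambi_cm",
    "inverse_kosambi",
    "haldane_cm",
    "recomb_fraction_dh",
    "distortion_test",
    "distortion_scan",
    "map_summary",
    "physical_density_mbp",
]

#: recombination fractions are capped just under 1/2 so the Kosambi
#: transform stays finite
R_CAP = 0.4999

VALID_CODES = frozenset("ab-")


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker positions on one or more linkage groups.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``marker``, ``group``, ``cm``.  Positions must be
        non-decreasing within a group and marker names unique.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"marker", "group", "cm"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if self.table["marker"].duplicated().any():
            dups = self.table.loc[self.table["marker"].duplicated(), "marker"]
            raise ValueError(f"duplicate marker names: {sorted(set(dups))}")
        for grp, sub in self.table.groupby("group", sort=False):
            pos = sub["cm"].to_numpy(float)
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions decrease within group {grp!r}")

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def groups(self) -> list:
        return list(dict.fromkeys(self.table["group"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def positions(self, group) -> np.ndarray:
        return self.table.loc[self.table["group"] == group, "cm"].to_numpy(float)

    def group_markers(self, group) -> list[str]:
        return self.table.loc[self.table["group"] == group, "marker"].tolist()

    @classmethod
    def from_records(cls, records) -> "GeneticMap":
        return cls(pd.DataFrame(records, columns=["marker", "group", "cm"]))


@dataclass(frozen=True)
class GenotypeMatrix:
    """Lines x markers DH genotype calls over {'a', 'b', '-'}.

    Stored as a DataFrame of single-character strings; the index is the
    line identifier and the columns are marker names.  Heterozygous codes
    are rejected: no heterozygous loci exist in a DH population.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        values = self.frame.to_numpy(str)
        bad = sorted(set(values.ravel()) - VALID_CODES)
        if bad:
            raise ValueError(
                f"illegal genotype codes {bad}: a DH population has no "
                "heterozygous loci; expected only 'a', 'b' or '-'"
            )

    @property
    def lines(self) -> list:
        return self.frame.index.tolist()

    @property
    def markers(self) -> list[str]:
        return self.frame.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def column(self, marker: str) -> np.ndarray:
        return self.frame[marker].to_numpy(str)

    def numeric(self) -> np.ndarray:
        """Return +1 for 'a', -1 for 'b', NaN for missing."""
        values = self.frame.to_numpy(str)
        out = np.full(values.shape, np.nan)
        out[values == "a"] = 1.0
        out[values == "b"] = -1.0
        return out


def kosambi_cm(r) -> np.ndarray | float:
    """Map a recombination fraction to Kosambi centimorgans.

    d = 25 * ln((1 + 2r) / (1 - 2r)); defined for 0 <= r < 0.5.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def inverse_kosambi(d) -> np.ndarray | float:
    """Map a distance in cM back to a recombination fraction.

    r = tanh(d / 50) / 2; approaches 1/2 as d grows without bound.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    # tanh saturates in floats; keep r strictly below 1/2
    r = np.minimum(0.5 * np.tanh(d / 50.0), np.nextafter(0.5, 0.0))
    return float(r) if r.ndim == 0 else r


def haldane_cm(r) -> np.ndarray | float:
    """Haldane (no-interference) map distance, for comparison only."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1 - 2 * r)
    return float(d) if d.ndim == 0 else d


def recomb_fraction_dh(g1, g2) -> tuple[float, int]:
    """Estimate the recombination fraction between two DH marker columns.

    r-hat is the fraction of informative lines (both calls non-missing)
    whose alleles differ, truncated to [0, 0.4999] so that downstream map
    conversions stay finite.

    Returns ``(r_hat, n_informative)``.
    """
    g1 = np.asarray(g1, dtype=str)
    g2 = np.asarray(g2, dtype=str)
    if g1.shape != g2.shape:
        raise ValueError("marker columns differ in length")
    informative = (g1 != "-") & (g2 != "-")
    n_inf = int(informative.sum())
    if n_inf < 2:
        raise ValueError("fewer than 2 informative lines")
    recomb = int((g1[informative] != g2[informative]).sum())
    r_hat = min(recomb / n_inf, R_CAP)
    return r_hat, n_inf


def distortion_test(counts_a: int, counts_b: int, alpha: float = 0.01):
    """Chi-square test of a marker's fit to the 1:1 DH segregation ratio.

    chi2 = (n_a - n_b)^2 / (n_a + n_b) on 1 df, equivalent to the Pearson
    statistic with expected counts (n/2, n/2).  A marker is flagged
    distorted at p <= alpha (0.01 by default); the skew direction names
    the over-represented parental allele.
    """
    n_a, n_b = int(counts_a), int(counts_b)
    n = n_a + n_b
    if n <= 0:
        raise ValueError("no observations")
    chi2 = (n_a - n_b) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    if n_a > n_b:
        direction = "a"
    elif n_b > n_a:
        direction = "b"
    else:
        direction = "none"
    return {
        "chi2": float(chi2),
        "p": p,
        "direction": direction,
        "distorted": p <= alpha,
    }


def distortion_scan(genotypes: GenotypeMatrix, alpha: float = 0.01) -> pd.DataFrame:
    """Run the 1:1 distortion test on every marker of a genotype matrix."""
    rows = []
    for marker in genotypes.markers:
        col = genotypes.column(marker)
        res = distortion_test(int((col == "a").sum()), int((col == "b").sum()), alpha)
        res["marker"] = marker
        rows.append(res)
    return pd.DataFrame(rows)[["marker", "chi2", "p", "direction", "distorted"]]


def map_summary(gmap: GeneticMap) -> dict:
    """Summarise a genetic map the way mapping studies conventionally do.

    The mean marker interval is reported under two conventions: total map
    length divided by the marker count (``mean_interval_per_marker``, the
    convention behind headline "average distance" figures) and divided by
    the interval count, i.e. markers minus groups
    (``mean_interval_per_interval``).
    """
    if gmap.n_markers == 0:
        raise ValueError("empty map")
    per_group = []
    intervals = []
    for grp in gmap.groups:
        pos = gmap.positions(grp)
        length = float(pos[-1] - pos[0]) if len(pos) else 0.0
        per_group.append(
            {"group": grp, "length_cm": length, "n_markers": len(pos)}
        )
        if len(pos) > 1:
            intervals.extend(np.diff(pos).tolist())
    total = float(sum(g["length_cm"] for g in per_group))
    n_mark = gmap.n_markers
    n_groups = len(per_group)
    out = {
        "total_length_cm": total,
        "n_markers": n_mark,
        "n_groups": n_groups,
        "per_group": pd.DataFrame(per_group),
        "mean_interval_per_marker": total / n_mark,
        "mean_interval_per_interval": (
            total / (n_mark - n_groups) if n_mark > n_groups else float("nan")
        ),
        "min_interval": float(min(intervals)) if intervals else float("nan"),
        "max_interval": float(max(intervals)) if intervals else float("nan"),
    }
    return out


def physical_density_mbp(genome_size_mbp: float, n_markers: int) -> float:
    """Average physical distance between mapped markers, in Mbp."""
    if n_markers <= 0:
        raise ValueError("marker count must be positive")
    return genome_size_mbp / n_markers
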