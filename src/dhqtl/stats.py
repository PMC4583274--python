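"""Descriptive statistics, replicated-design ANOVA and trait correlations.

The ANOVA reproduces the block-in-replication field design: DH lines are
divided into blocks, and the blocks are laid out in a randomized
complete block design with replicates.  Its decomposition is

    y ~ block + line(block) + replication + block x replication + error

and the error mean square estimates the plant/plot-level environmental
variance that the segregation analysis takes as input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TraitSummary",
    "AnovaTable",
    "describe",
    "line_means",
    "assign_blocks",
    "anova_block_in_rep",
    "combined_years_anova",
    "correlation_matrix",
]


@dataclass(frozen=True)
class TraitSummary:
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    skewness: float
    kurtosis: float  # excess

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


@dataclass(frozen=True)
class AnovaTable:
    """Per-source df/SS/MS/F with the error mean square exposed."""

    table: pd.DataFrame  # index: source; columns: df, ss, ms, F, p

    @property
    def error_ms(self) -> float:
        return float(self.table.loc["error", "ms"])

    @property
    def sigma2_hat(self) -> float:
        """The environmental-variance estimate (error mean square)."""
        return self.error_ms

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.2f}")


def describe(values) -> TraitSummary:
    """Sample moments with bias-adjusted skewness and excess kurtosis.

    Requires n >= 4 (the kurtosis bias adjustment) and non-constant
    data (third/fourth standardised moments are undefined at SD 0).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("constant sample: skewness/kurtosis undefined")
    return TraitSummary(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=sd,
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        skewness=float(sps.skew(x, bias=False)),
        kurtosis=float(sps.kurtosis(x, fisher=True, bias=False)),
    )


def line_means(phenotypes: pd.DataFrame, value: str = "value") -> pd.Series:
    """Per-line trait means (the QTL-scan and segregation input)."""
    return phenotypes.groupby("line")[value].mean()


def assign_blocks(lines, n_blocks: int, seed: int | None = None) -> dict:
    """Randomly split lines into blocks of near-equal size."""
    lines = list(lines)
    if n_blocks < 1 or n_blocks > len(lines):
        raise ValueError("block count must lie in 1..n_lines")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(lines))
    return {lines[i]: int(j % n_blocks) for j, i in enumerate(order)}


def anova_block_in_rep(
    records: pd.DataFrame,
    value: str = "value",
) -> AnovaTable:
    """Fixed-effects ANOVA of the block-in-replication design.

    ``records`` needs columns ``line``, ``block``, ``rep`` and the value
    column.  Sources: block, line (nested in block), replication,
    block x replication, error; F for every non-error source is taken
    against the error mean square.  The input is aggregated to one value
    per (line, rep) cell (plot means) before decomposition.
    """
    for col in ("line", "block", "rep", value):
        if col not in records.columns:
            raise ValueError(f"records lack column {col!r}")
    if records["rep"].nunique() < 2:
        raise ValueError("need >= 2 replicates for an error stratum")
    cell = (
        records.groupby(["block", "line", "rep"], sort=True)[value]
        .mean()
        .reset_index()
    )
    y = cell[value].to_numpy(float)
    n = y.size
    grand = y.mean()
    total_ss = float(((y - grand) ** 2).sum())

    def group_ss(keys) -> tuple[float, int]:
        g = cell.groupby(keys, sort=False)[value]
        means = g.transform("mean").to_numpy(float)
        return float(((means - grand) ** 2).sum()), g.ngroups

    ss_block, n_block = group_ss(["block"])
    ss_block_line, n_line_tot = group_ss(["block", "line"])
    ss_line = ss_block_line - ss_block  # lines nested in blocks
    ss_rep, n_rep = group_ss(["rep"])
    ss_block_rep_cells, n_br = group_ss(["block", "rep"])
    ss_block_rep = ss_block_rep_cells - ss_block - ss_rep
    ss_error = total_ss - ss_block - ss_line - ss_rep - ss_block_rep

    df_block = n_block - 1
    df_line = n_line_tot - n_block
    df_rep = n_rep - 1
    df_block_rep = df_block * df_rep
    df_total = n - 1
    df_error = df_total - df_block - df_line - df_rep - df_block_rep
    if df_error <= 0:
        raise ValueError("no residual degrees of freedom")

    rows = {
        "block": (df_block, ss_block),
        "line": (df_line, ss_line),
        "replication": (df_rep, ss_rep),
        "block x rep": (df_block_rep, ss_block_rep),
        "error": (df_error, ss_error),
        "corrected total": (df_total, total_ss),
    }
    ms_error = ss_error / df_error
    out = []
    for src, (df, ss) in rows.items():
        ms = ss / df if df > 0 else np.nan
        if src in ("error", "corrected total") or not ms_error > 0:
            f = p = np.nan
        else:
            f = ms / ms_error
            p = sps.f.sf(f, df, df_error)
        out.append((src, df, ss, ms if src != "corrected total" else np.nan, f, p))
    table = pd.DataFrame(
        out, columns=["source", "df", "ss", "ms", "F", "p"]
    ).set_index("source")
    return AnovaTable(table)


def combined_years_anova(year_line_means: pd.DataFrame, value: str = "value") -> AnovaTable:
    """Two-way year + line decomposition of line-by-year means.

    ``year_line_means`` needs columns ``year``, ``line`` and the value
    column, one row per (year, line); only lines present in every year
    are used.  The year x line interaction is the error stratum.
    """
    for col in ("year", "line", value):
        if col not in year_line_means.columns:
            raise ValueError(f"table lacks column {col!r}")
    wide = year_line_means.pivot_table(index="line", columns="year", values=value).dropna()
    if wide.shape[0] < 2:
        raise ValueError("need >= 2 lines present in every year")
    y = wide.to_numpy(float)
    n_lines, n_years = y.shape
    grand = y.mean()
    ss_year = n_lines * float(((y.mean(axis=0) - grand) ** 2).sum())
    ss_line = n_years * float(((y.mean(axis=1) - grand) ** 2).sum())
    total_ss = float(((y - grand) ** 2).sum())
    ss_error = total_ss - ss_year - ss_line
    df_year, df_line = n_years - 1, n_lines - 1
    df_error = df_year * df_line
    df_total = n_lines * n_years - 1
    ms_error = ss_error / df_error
    rows = []
    for src, df, ss in (
        ("year", df_year, ss_year),
        ("line", df_line, ss_line),
        ("error", df_error, ss_error),
        ("corrected total", df_total, total_ss),
    ):
        ms = ss / df if src != "corrected total" else np.nan
        if src in ("error", "corrected total") or not ms_error > 0:
            f = p = np.nan
        else:
            f = ms / ms_error
            p = sps.f.sf(f, df, df_error)
        rows.append((src, df, ss, ms, f, p))
    table = pd.DataFrame(rows, columns=["source", "df", "ss", "ms", "F", "p"]).set_index("source")
    return AnovaTable(table)


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_matrix(traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-tailed p and star codes.

    Returns ``(r, p, stars)`` DataFrames.  Pairs are computed on
    complete observations; a zero-variance trait yields NaN for its
    pairs.  Significance: ``*`` p < 0.05, ``**`` p < 0.01.
    """
    cols = traits.columns
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            sub = traits[[cols[i], cols[j]]].dropna()
            if len(sub) < 3 or sub.iloc[:, 0].std() == 0 or sub.iloc[:, 1].std() == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sps.pearsonr(sub.iloc[:, 0], sub.iloc[:, 1])
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    stars = p.map(_stars)
    return r, p, stars
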