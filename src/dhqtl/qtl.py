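"""QTL detection in doubled-haploid populations.

Implements the scan family used in biparental QTL studies:

* single-marker regression (the LOD backbone),
* interval mapping (IM): at each grid position the putative QTL
  genotype probabilities are computed from the flanking markers under a
  no-interference Markov model with inverse-Kosambi recombination
  fractions, and a two-component normal mixture is maximised by EM,
* MQM-style cofactor scans: interval mapping on phenotype residuals
  after regression on selected marker cofactors, with cofactors near
  the evaluated position excluded,
* ICIM-style scans: stepwise marker selection with entry/removal
  p-values, then interval mapping on the phenotype adjusted by all
  selected markers except those flanking the current interval,
* permutation thresholds: genome-wide maximum LOD of label-shuffled
  phenotypes, with the empirical (1 - alpha) quantile as threshold.

The model-object surface follows statsmodels::

    scan = QtlScan(line_means, genotypes, gmap)
    res = scan.fit(method="icim")          # QtlScanResults
    res.hits, res.profile, res.summary()
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .linkage import GeneticMap, GenotypeMatrix, inverse_kosambi

__all__ = [
    "ScanOptions",
    "QtlScan",
    "QtlScanResults",
    "single_marker_lod",
    "interval_mapping",
    "cofactor_scan",
    "icim_scan",
    "permutation_threshold",
    "find_hits",
    "name_hits",
    "name_and_report",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class ScanOptions:
    """Scan settings; defaults follow the reference study's analysis."""

    step: float = 1.0
    lod_threshold: float = 3.28
    p_in: float = 0.001
    p_out: float = 0.002
    n_permutations: int = 1000
    alpha: float = 0.05
    cofactor_window_cm: float = 10.0
    min_peak_separation_cm: float = 20.0
    em_tol: float = 1e-6
    em_max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not 0 < self.p_in < self.p_out < 1:
            raise ValueError("need 0 < p_in < p_out < 1")


# ----------------------------------------------------------- primitives

def single_marker_lod(y, marker_column) -> tuple[float, float, float]:
    """LOD, additive effect and R^2 of a single-marker regression.

    Lines with a missing call are dropped.  The additive effect is half
    the 'b'-class mean minus half the 'a'-class mean, i.e. positive when
    the second parent's allele raises the trait.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(marker_column)
    if g.dtype.kind in "SUO":
        x = np.where(g == "a", 1.0, np.where(g == "b", -1.0, np.nan))
    else:
        x = np.asarray(g, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 informative lines")
    if np.all(x == x[0]):
        raise ValueError("monomorphic marker")
    xc = x - x.mean()
    yc = y - y.mean()
    beta = float((xc @ yc) / (xc @ xc))
    rss0 = float(yc @ yc)
    rss1 = float(((yc - beta * xc) ** 2).sum())
    if rss0 == 0:
        return 0.0, 0.0, 0.0
    lod = (n / 2.0) * math.log10(rss0 / max(rss1, 1e-300))
    r2 = 1.0 - rss1 / rss0
    return lod, -beta, r2


def _numeric_imputed(genotypes: GenotypeMatrix) -> np.ndarray:
    """+/-1 coding with missing calls set to the marker mean."""
    x = genotypes.numeric()
    means = np.nanmean(x, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(x))
    x[idx] = means[idx[1]]
    return x


def _marker_scan_max_lod(x_imp: np.ndarray, y: np.ndarray) -> float:
    """Genome-wide max single-marker LOD, fully vectorised."""
    n = y.size
    xc = x_imp - x_imp.mean(axis=0)
    yc = y - y.mean()
    ss_x = (xc**2).sum(axis=0)
    ss_y = float(yc @ yc)
    ok = (ss_x > 0) & (ss_y > 0)
    r2 = np.zeros(x_imp.shape[1])
    r2[ok] = (xc[:, ok].T @ yc) ** 2 / (ss_x[ok] * ss_y)
    return float((-(n / 2.0) * np.log10(np.clip(1 - r2, 1e-300, None))).max())


# ------------------------------------------- QTL genotype probabilities

def _group_state(genotypes: GenotypeMatrix, gmap: GeneticMap, group) -> np.ndarray:
    """Numeric group genotypes: 1 = 'a', 0 = 'b', -1 = missing."""
    codes = genotypes.frame[gmap.group_markers(group)].to_numpy(str)
    return np.where(codes == "a", 1, np.where(codes == "b", 0, -1))


def _priors_from_state(state: np.ndarray, pos: np.ndarray, t: float) -> np.ndarray:
    """P(QTL genotype = 'a') per line at map position ``t``.

    Flanking information comes from the nearest non-missing marker on
    each side (Markov property, no interference); a line with no
    informative marker on a side uses the single-sided transition, and
    with none at all gets probability 1/2.
    """
    n, m = state.shape
    if (state >= 0).all():
        j = int(np.searchsorted(pos, t))
        if j < m and pos[j] == t:
            return state[:, j].astype(float)
        li, ri = j - 1, j
        rl = inverse_kosambi(t - pos[li])
        rr = inverse_kosambi(pos[ri] - t)
        gl, gr = state[:, li], state[:, ri]
        wa = np.where(gl == 1, 1 - rl, rl) * np.where(gr == 1, 1 - rr, rr)
        wb = np.where(gl == 1, rl, 1 - rl) * np.where(gr == 1, rr, 1 - rr)
        return wa / (wa + wb)
    p = np.full(n, 0.5)
    left_idx = np.where(pos <= t)[0][::-1]
    right_idx = np.where(pos >= t)[0]
    for i in range(n):
        li = next((j for j in left_idx if state[i, j] >= 0), None)
        ri = next((j for j in right_idx if state[i, j] >= 0), None)
        if li is not None and ri is not None and li == ri:
            p[i] = float(state[i, li])
            continue
        w_a = w_b = 1.0
        if li is not None:
            r = inverse_kosambi(t - pos[li])
            w_a *= (1 - r) if state[i, li] == 1 else r
            w_b *= r if state[i, li] == 1 else (1 - r)
        if ri is not None:
            r = inverse_kosambi(pos[ri] - t)
            w_a *= (1 - r) if state[i, ri] == 1 else r
            w_b *= r if state[i, ri] == 1 else (1 - r)
        if li is not None or ri is not None:
            p[i] = w_a / (w_a + w_b)
    return p


def _qtl_priors(
    gmap: GeneticMap, genotypes: GenotypeMatrix, group, position: float
) -> np.ndarray:
    """QTL genotype probabilities at one position (see _priors_from_state)."""
    return _priors_from_state(
        _group_state(genotypes, gmap, group), gmap.positions(group), float(position)
    )


def _scan_positions(
    genotypes: GenotypeMatrix, gmap: GeneticMap, step: float
) -> list[tuple[object, float, np.ndarray]]:
    """Precompute (group, position, priors) for the whole scan grid."""
    out = []
    for grp in gmap.groups:
        pos = gmap.positions(grp)
        state = _group_state(genotypes, gmap, grp)
        for t in _grid(pos, step):
            out.append((grp, float(t), _priors_from_state(state, pos, float(t))))
    return out


def _mixture_lod(y: np.ndarray, prior_a: np.ndarray, tol: float,
                 max_iter: int) -> tuple[float, float, float]:
    """EM over a two-component normal mixture with per-line priors.

    Returns (LOD, additive effect, R^2) against the single-normal null.
    At a fully genotyped marker the priors are 0/1 and the fit reduces
    to the two-group regression exactly.
    """
    n = y.size
    var0 = float(np.var(y))
    if var0 <= 0:
        return 0.0, 0.0, 0.0
    l0 = -0.5 * n * (math.log(2 * math.pi * var0) + 1.0)
    wa = prior_a.copy()
    # initial means from prior-weighted class averages
    sa, sb = wa.sum(), (1 - wa).sum()
    mu_a = float((wa @ y) / sa) if sa > 0 else float(y.mean())
    mu_b = float(((1 - wa) @ y) / sb) if sb > 0 else float(y.mean())
    sigma2 = var0
    loglik = -np.inf
    for _ in range(max_iter):
        pa = prior_a * np.exp(-((y - mu_a) ** 2) / (2 * sigma2))
        pb = (1 - prior_a) * np.exp(-((y - mu_b) ** 2) / (2 * sigma2))
        denom = pa + pb
        denom[denom == 0] = 1e-300
        new_loglik = float(np.log(denom).sum()) - 0.5 * n * math.log(2 * math.pi * sigma2)
        wa = pa / denom
        if new_loglik - loglik < tol and loglik > -np.inf:
            loglik = new_loglik
            break
        loglik = new_loglik
        sa, sb = wa.sum(), (1 - wa).sum()
        if sa > 1e-12:
            mu_a = float((wa @ y) / sa)
        if sb > 1e-12:
            mu_b = float(((1 - wa) @ y) / sb)
        sigma2 = float((wa @ (y - mu_a) ** 2 + (1 - wa) @ (y - mu_b) ** 2) / n)
        sigma2 = max(sigma2, 1e-12 * var0)
    lod = max((loglik - l0) / LN10, 0.0)
    r2 = max(1.0 - sigma2 / var0, 0.0)
    return lod, (mu_b - mu_a) / 2.0, r2


def _grid(pos: np.ndarray, step: float) -> np.ndarray:
    """Scan grid: regular steps from the first to last marker, plus the
    marker positions themselves."""
    grid = np.arange(pos[0], pos[-1] + 1e-9, step)
    return np.unique(np.concatenate([grid, pos]))


# ------------------------------------------------------------- profiles

def interval_mapping(
    y,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    options: ScanOptions | None = None,
) -> pd.DataFrame:
    """Interval-mapping LOD profile over the whole map.

    Returns a DataFrame with columns ``group, cm, lod, add, r2``.
    """
    options = options or ScanOptions()
    y = np.asarray(y, dtype=float)
    positions = _scan_positions(genotypes, gmap, options.step)
    return _profile_from_priors(y, positions, options)


def _profile_from_priors(y: np.ndarray, positions, options: ScanOptions) -> pd.DataFrame:
    rows = []
    for grp, t, prior in positions:
        lod, add, r2 = _mixture_lod(y, prior, options.em_tol, options.em_max_iter)
        rows.append((grp, t, lod, add, r2))
    return pd.DataFrame(rows, columns=["group", "cm", "lod", "add", "r2"])


def _regress_out(y: np.ndarray, x_cols: np.ndarray) -> np.ndarray:
    """Residuals of y on the given columns (with intercept)."""
    if x_cols.size == 0:
        return y - y.mean()
    design = np.column_stack([np.ones(y.size), x_cols])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def cofactor_scan(
    y,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    cofactors,
    options: ScanOptions | None = None,
) -> pd.DataFrame:
    """MQM-style scan: IM on residuals after cofactor regression.

    Cofactors lying within ``cofactor_window_cm`` of the evaluated
    position (same group) are dropped from the regression for that
    position, so a QTL is not absorbed by its own linked cofactor.
    With an empty cofactor list this reduces to plain interval mapping.
    """
    options = options or ScanOptions()
    y = np.asarray(y, dtype=float)
    cofactors = list(cofactors)
    unknown = set(cofactors) - set(gmap.markers)
    if unknown:
        raise ValueError(f"cofactors not on the map: {sorted(unknown)}")
    if len(cofactors) >= len(gmap.markers):
        raise ValueError("all markers selected as cofactors")
    if not cofactors:
        return interval_mapping(y, genotypes, gmap, options)
    marker_pos = gmap.table.set_index("marker")
    x_imp = _numeric_imputed(genotypes)
    col_of = {m: i for i, m in enumerate(genotypes.markers)}
    var_y = float(np.var(y))
    residual_cache: dict[frozenset, np.ndarray] = {}
    rows = []
    for grp, t, prior in _scan_positions(genotypes, gmap, options.step):
        active = frozenset(
            m for m in cofactors
            if not (
                marker_pos.loc[m, "group"] == grp
                and abs(float(marker_pos.loc[m, "cm"]) - t)
                <= options.cofactor_window_cm
            )
        )
        if active not in residual_cache:
            cols = x_imp[:, [col_of[m] for m in sorted(active)]]
            residual_cache[active] = _regress_out(y, cols) + y.mean()
        resid = residual_cache[active]
        lod, add, r2 = _mixture_lod(resid, prior, options.em_tol,
                                    options.em_max_iter)
        # report PVE against the total phenotypic variance, not the
        # cofactor-adjusted one
        r2 *= np.var(resid) / var_y
        rows.append((grp, t, lod, add, r2))
    return pd.DataFrame(rows, columns=["group", "cm", "lod", "add", "r2"])


# ---------------------------------------------------- stepwise selection

def _stepwise_select(y: np.ndarray, x_imp: np.ndarray, p_in: float,
                     p_out: float, max_terms: int | None = None) -> list[int]:
    """Forward-entry / backward-removal marker selection by partial F.

    A marker enters when its addition p-value is below ``p_in``; after
    each entry, included markers whose removal p-value exceeds
    ``p_out`` are dropped.
    """
    n, m = x_imp.shape
    selected: list[int] = []
    max_terms = max_terms if max_terms is not None else max(1, n // 5)

    def fit_rss(cols: list[int]) -> float:
        design = np.column_stack([np.ones(n)] + [x_imp[:, c] for c in cols])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        return float(resid @ resid)

    rss_current = fit_rss(selected)
    while len(selected) < max_terms:
        best_p, best_j, best_rss = 1.0, None, None
        df2 = n - len(selected) - 2
        if df2 <= 0:
            break
        for j in range(m):
            if j in selected:
                continue
            rss_new = fit_rss(selected + [j])
            if rss_new >= rss_current or rss_new <= 0:
                continue
            f = (rss_current - rss_new) / (rss_new / df2)
            p = float(sps.f.sf(f, 1, df2))
            if p < best_p:
                best_p, best_j, best_rss = p, j, rss_new
        if best_j is None or best_p >= p_in:
            break
        selected.append(best_j)
        rss_current = best_rss
        # backward pass
        removed = True
        while removed and len(selected) > 1:
            removed = False
            df2 = n - len(selected) - 1
            for j in list(selected):
                rest = [c for c in selected if c != j]
                rss_rest = fit_rss(rest)
                f = (rss_rest - rss_current) / (rss_current / df2)
                p = float(sps.f.sf(f, 1, df2))
                if p > p_out:
                    selected.remove(j)
                    rss_current = rss_rest
                    removed = True
                    break
    return selected


def icim_scan(
    y,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    options: ScanOptions | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inclusive composite interval mapping.

    Step 1 selects background markers by stepwise regression
    (entry ``p_in``, removal ``p_out``).  Step 2 scans each interval by
    interval mapping on the phenotype adjusted by all selected markers
    except the two flanking the interval, using the step-1 coefficients.
    Returns ``(profile, hits)``; selecting zero markers degrades
    gracefully to plain IM.
    """
    options = options or ScanOptions()
    y = np.asarray(y, dtype=float)
    x_imp = _numeric_imputed(genotypes)
    col_of = {m: i for i, m in enumerate(genotypes.markers)}
    var_y = float(np.var(y))
    sel = _stepwise_select(y, x_imp, options.p_in, options.p_out)
    if not sel:
        profile = interval_mapping(y, genotypes, gmap, options)
        hits = find_hits(profile, gmap, options)
        return profile, hits
    design = np.column_stack([np.ones(y.size)] + [x_imp[:, c] for c in sel])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    coefs = dict(zip(sel, beta[1:]))
    group_info = {
        grp: (gmap.positions(grp), gmap.group_markers(grp)) for grp in gmap.groups
    }
    rows = []
    for grp, t, prior in _scan_positions(genotypes, gmap, options.step):
        pos, markers = group_info[grp]
        # flanking markers of the current interval keep their signal
        left = int(np.searchsorted(pos, t, side="right")) - 1
        left = min(max(left, 0), len(pos) - 1)
        right = min(left + 1, len(pos) - 1)
        flank = {col_of[markers[left]], col_of[markers[right]]}
        adj = y.copy()
        for c, b in coefs.items():
            if c not in flank:
                adj = adj - b * (x_imp[:, c] - x_imp[:, c].mean())
        lod, add, r2 = _mixture_lod(adj - adj.mean() + y.mean(), prior,
                                    options.em_tol, options.em_max_iter)
        # PVE relative to total phenotypic variance (Table-5 convention)
        r2 *= np.var(adj) / var_y
        rows.append((grp, t, lod, add, r2))
    profile = pd.DataFrame(rows, columns=["group", "cm", "lod", "add", "r2"])
    hits = find_hits(profile, gmap, options)
    return profile, hits


# ----------------------------------------------------------- thresholds

def permutation_threshold(
    y,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap | None = None,
    options: ScanOptions | None = None,
    method: str = "marker",
) -> float:
    """Genome-wide LOD threshold by phenotype permutation.

    Phenotype labels are shuffled against the intact genotypes; the
    genome-wide maximum LOD of each permutation is recorded and the
    empirical (1 - alpha) quantile returned.  ``method='marker'``
    (default) evaluates the maximum over marker positions by vectorised
    single-marker regression; ``method='im'`` runs the full
    interval-mapping grid per permutation (much slower).
    """
    options = options or ScanOptions()
    if options.n_permutations < 100:
        raise ValueError("need >= 100 permutations for a stable quantile")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(options.seed)
    x_imp = _numeric_imputed(genotypes)
    if method == "im":
        if gmap is None:
            raise ValueError("method='im' needs the genetic map")
        positions = _scan_positions(genotypes, gmap, options.step)
    elif method != "marker":
        raise ValueError("method must be 'marker' or 'im'")
    maxima = np.empty(options.n_permutations)
    for b in range(options.n_permutations):
        yp = rng.permutation(y)
        if method == "marker":
            maxima[b] = _marker_scan_max_lod(x_imp, yp)
        else:
            profile = _profile_from_priors(yp, positions, options)
            maxima[b] = float(profile["lod"].max())
    return float(np.quantile(maxima, 1.0 - options.alpha))


# ----------------------------------------------------- hits & reporting

def _flanking_markers(gmap: GeneticMap, group, position: float) -> tuple[str, str]:
    """Markers bracketing a position; a peak on a marker takes its
    neighbours on both sides."""
    pos = gmap.positions(group)
    markers = gmap.group_markers(group)
    m = len(pos)
    j = int(np.searchsorted(pos, position))
    if j < m and pos[j] == position:
        return markers[max(j - 1, 0)], markers[min(j + 1, m - 1)]
    return markers[max(j - 1, 0)], markers[min(j, m - 1)]


def find_hits(
    profile: pd.DataFrame,
    gmap: GeneticMap,
    options: ScanOptions | None = None,
) -> pd.DataFrame:
    """Extract QTL hits from a LOD profile.

    Local maxima above ``lod_threshold`` are kept greedily by LOD with
    a minimum separation of ``min_peak_separation_cm`` within a group;
    each hit carries its 1-LOD support interval and flanking markers.
    """
    options = options or ScanOptions()
    hits = []
    for grp, sub in profile.groupby("group", sort=False):
        sub = sub.sort_values("cm").reset_index(drop=True)
        lod = sub["lod"].to_numpy()
        cm = sub["cm"].to_numpy()
        above = lod >= options.lod_threshold
        order = np.argsort(lod)[::-1]
        chosen: list[int] = []
        for i in order:
            if not above[i]:
                continue
            left_nb = max(i - 1, 0)
            right_nb = min(i + 1, len(lod) - 1)
            if lod[i] < lod[left_nb] or lod[i] < lod[right_nb]:
                continue  # not a local maximum
            if any(abs(cm[i] - cm[j]) < options.min_peak_separation_cm for j in chosen):
                continue
            chosen.append(i)
        for i in sorted(chosen, key=lambda j: cm[j]):
            drop = lod[i] - 1.0
            lo = cm[i]
            for j in range(i, -1, -1):
                if lod[j] < drop:
                    break
                lo = cm[j]
            hi = cm[i]
            for j in range(i, len(lod)):
                if lod[j] < drop:
                    break
                hi = cm[j]
            left_m, right_m = _flanking_markers(gmap, grp, float(cm[i]))
            hits.append(
                {
                    "group": grp, "cm": float(cm[i]), "lod": float(lod[i]),
                    "add": float(sub.loc[i, "add"]), "r2": float(sub.loc[i, "r2"]),
                    "support_lo": float(lo), "support_hi": float(hi),
                    "left_marker": left_m, "right_marker": right_m,
                }
            )
    cols = ["group", "cm", "lod", "add", "r2", "support_lo", "support_hi",
            "left_marker", "right_marker"]
    return pd.DataFrame(hits, columns=cols)


def _chrom_number(group) -> str:
    digits = "".join(ch for ch in str(group) if ch.isdigit())
    return digits or str(group)


def name_hits(hits: pd.DataFrame, trait: str = "Hsr") -> pd.DataFrame:
    """Assign conventional QTL names: trait + chromosome + ordinal.

    Hits on the same group are numbered by map position, e.g. two hits
    on C4 become ``Hsr 4.1`` and ``Hsr 4.2``.
    """
    out = hits.sort_values(["group", "cm"]).reset_index(drop=True).copy()
    out = out.drop(columns=["name"], errors="ignore")  # idempotent renaming
    names = []
    counter: dict[str, int] = {}
    for grp in out["group"]:
        num = _chrom_number(grp)
        counter[num] = counter.get(num, 0) + 1
        names.append(f"{trait} {num}.{counter[num]}")
    out.insert(0, "name", names)
    return out


def name_and_report(hits_by_key: dict, trait: str = "Hsr") -> pd.DataFrame:
    """Combine named hit tables across years/methods into one report.

    ``hits_by_key`` maps a label such as ``'2011 (ICIM)'`` to a hit
    DataFrame.  The report mirrors the conventional QTL table (name,
    linkage group, position, LOD, marker interval, R^2, additive
    effect) and appends a per-label total of R^2 (the summed PVE).
    """
    blocks = []
    for key, hits in hits_by_key.items():
        named = name_hits(hits, trait=trait)
        named.insert(0, "analysis", key)
        named["marker_interval"] = named["left_marker"] + "-" + named["right_marker"]
        blocks.append(named)
        total = pd.DataFrame(
            [{"analysis": key, "name": "total", "r2": named["r2"].sum()}]
        )
        blocks.append(total)
    if not blocks:
        return pd.DataFrame(
            columns=["analysis", "name", "group", "cm", "lod",
                     "marker_interval", "r2", "add"]
        )
    report = pd.concat(blocks, ignore_index=True)
    cols = ["analysis", "name", "group", "cm", "lod", "marker_interval", "r2", "add"]
    return report.reindex(columns=cols)


# ----------------------------------------------------------- model shape

class QtlScan:
    """Model object bundling phenotype, genotypes and map for scanning.

    Parameters
    ----------
    y : array-like or pandas.Series
        One value per line, aligned with the genotype matrix rows
        (a Series is re-indexed onto the genotype lines).
    genotypes, gmap : the DH genotype matrix and its genetic map.
    options : ScanOptions, optional.
    """

    def __init__(self, y, genotypes: GenotypeMatrix, gmap: GeneticMap,
                 options: ScanOptions | None = None):
        if isinstance(y, pd.Series):
            y = y.reindex(genotypes.lines).to_numpy()
        self.y = np.asarray(y, dtype=float)
        if self.y.size != genotypes.shape[0]:
            raise ValueError("phenotype length does not match genotype lines")
        if np.isnan(self.y).any():
            raise ValueError("missing line phenotypes are not supported")
        self.genotypes = genotypes
        self.gmap = gmap
        self.options = options or ScanOptions()

    def permutation_threshold(self, method: str = "marker", **overrides) -> float:
        opts = replace(self.options, **overrides) if overrides else self.options
        return permutation_threshold(self.y, self.genotypes, self.gmap, opts, method)

    def fit(self, method: str = "im", cofactors=None,
            trait: str = "Hsr") -> "QtlScanResults":
        """Run a scan; ``method`` is 'im', 'mqm' or 'icim'.

        For 'mqm' without explicit cofactors, the markers nearest the
        peaks of a preliminary IM scan (above threshold) are taken as
        cofactors, following the usual MQM workflow.
        """
        if method == "im":
            profile = interval_mapping(self.y, self.genotypes, self.gmap, self.options)
        elif method == "mqm":
            if cofactors is None:
                pre = interval_mapping(self.y, self.genotypes, self.gmap, self.options)
                peaks = find_hits(pre, self.gmap, self.options)
                cofactors = [
                    self._nearest_marker(r.group, r.cm) for r in peaks.itertuples()
                ]
            profile = cofactor_scan(self.y, self.genotypes, self.gmap,
                                    cofactors, self.options)
        elif method == "icim":
            profile, hits = icim_scan(self.y, self.genotypes, self.gmap, self.options)
            return QtlScanResults(self, method, profile,
                                  name_hits(hits, trait), cofactors=None)
        else:
            raise ValueError("method must be 'im', 'mqm' or 'icim'")
        hits = find_hits(profile, self.gmap, self.options)
        return QtlScanResults(self, method, profile, name_hits(hits, trait),
                              cofactors=cofactors)

    def _nearest_marker(self, group, position: float) -> str:
        pos = self.gmap.positions(group)
        markers = self.gmap.group_markers(group)
        return markers[int(np.argmin(np.abs(pos - position)))]


@dataclass
class QtlScanResults:
    """A completed scan: LOD profile, named hits and metadata."""

    model: QtlScan = field(repr=False)
    method: str = "im"
    profile: pd.DataFrame = field(default=None, repr=False)
    hits: pd.DataFrame = field(default=None, repr=False)
    cofactors: list | None = None

    @property
    def max_lod(self) -> float:
        return float(self.profile["lod"].max())

    @property
    def total_pve(self) -> float:
        """Summed per-hit R^2, in percent."""
        return float(self.hits["r2"].sum() * 100.0)

    def summary(self) -> str:
        lines = [
            f"QTL scan ({self.method.upper()}), threshold LOD "
            f"{self.model.options.lod_threshold}",
            f"  grid points: {len(self.profile)}, max LOD {self.max_lod:.2f}",
            f"  hits: {len(self.hits)}",
        ]
        if len(self.hits):
            show = self.hits.copy()
            show["r2_pct"] = show["r2"] * 100
            lines.append(
                show[["name", "group", "cm", "lod", "left_marker",
                      "right_marker", "r2_pct", "add"]]
                .to_string(index=False, float_format=lambda v: f"{v:.2f}")
            )
            lines.append(f"  combined PVE: {self.total_pve:.2f}%")
        return "\n".join(lines)
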