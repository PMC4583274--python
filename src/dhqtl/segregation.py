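"""Major-gene/polygene mixed-inheritance segregation analysis for DH lines.

A quantitative trait governed by *k* segregating major genes in a DH
population is a 2^k-component Gaussian mixture: each fully homozygous
genotype class occurs with Mendelian probability 1/2^k and contributes a
component whose mean is a linear function of the additive effects
(d_a, d_b, d_c) and their digenic/trigenic epistatic interactions
(i_ab, i_ac, i_bc, i_abc), while polygenes and environment inflate a
common within-component variance.

Fitting is by an iterated expectation / conditional-maximization (IECM)
scheme: the E-step computes posterior class memberships under the fixed
Mendelian proportions, and the CM-steps alternately update (1) the
constrained component means by generalized least squares against the
model's genotype design matrix and (2) the common within-component
variance, floored at the externally supplied environmental variance
(the replicated-design ANOVA error mean square).  Candidate genetic
models are ranked by AIC and vetted with a goodness-of-fit suite
(moment-based uniformity chi-square statistics U1/U2/U3 on the
probability-integral transform, the Cramer-von Mises statistic nW2 and
the Kolmogorov statistic Dn).

Usage follows the statsmodels convention::

    model = MixedInheritanceModel(y, sigma_e2=22.38)
    res = model.fit(ModelSpec(k=3, epistasis="full", polygenes=True))
    res.summary()
    sel = model.fit_catalog()       # all DH-applicable models, AIC table
    sel.best.genetic_params()
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ModelSpec",
    "MixedInheritanceModel",
    "MixtureResults",
    "ModelSelectionResults",
    "FitDiagnostics",
    "GeneticArchitecture",
    "enumerate_dh_models",
    "fit_mixture_iecm",
    "model_aic",
    "select_model",
    "goodness_of_fit",
    "estimate_first_order",
    "estimate_second_order",
    "NW2_CRITICAL",
]

#: Cramer-von Mises critical values used to pass/fail mixture fits
NW2_CRITICAL = {0.05: 0.461, 0.01: 0.743}

_EFFECT_NAMES = {
    1: ["m", "d_a"],
    2: ["m", "d_a", "d_b"],
    3: ["m", "d_a", "d_b", "d_c"],
}
_PAIR_NAMES = {(0, 1): "i_ab", (0, 2): "i_ac", (1, 2): "i_bc"}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate genetic model for a DH population.

    k major genes give 2^k mixture components in fixed 1/2^k
    proportions.  ``epistasis`` constrains the component means through
    the design matrix ('none': additive only; 'digenic': pairwise
    interactions; 'full': pairwise plus the three-way term).
    ``polygenes`` frees the within-component variance above the
    environmental floor; without polygenes it is pinned to sigma_e2.
    """

    k: int
    epistasis: str = "none"
    polygenes: bool = True

    def __post_init__(self) -> None:
        if self.k not in (0, 1, 2, 3):
            raise ValueError("k must be 0..3 for DH analysis")
        if self.epistasis not in ("none", "digenic", "full"):
            raise ValueError("epistasis must be none|digenic|full")
        if self.k == 0 and self.epistasis != "none":
            raise ValueError("no epistasis without major genes")
        if self.k == 1 and self.epistasis != "none":
            raise ValueError("epistasis needs >= 2 major genes")
        if self.k == 2 and self.epistasis == "full":
            raise ValueError("trigenic epistasis needs 3 major genes")

    @property
    def n_components(self) -> int:
        return 2 ** self.k

    @property
    def param_names(self) -> list[str]:
        if self.k == 0:
            return ["m"]
        names = list(_EFFECT_NAMES[self.k])
        if self.epistasis in ("digenic", "full"):
            names += [
                _PAIR_NAMES[pair]
                for pair in itertools.combinations(range(self.k), 2)
            ]
        if self.epistasis == "full" and self.k == 3:
            names.append("i_abc")
        return names

    @property
    def n_mean_params(self) -> int:
        return len(self.param_names)

    @property
    def n_params(self) -> int:
        """Free parameters: mean-design columns, plus the within
        variance when polygenes are present."""
        return self.n_mean_params + (1 if self.polygenes else 0)

    @property
    def label(self) -> str:
        base = f"{self.k}MG" + ("" if self.epistasis == "none" else f"-{self.epistasis}")
        return base + ("+PG" if self.polygenes else "")

    @property
    def genotype_classes(self) -> np.ndarray:
        """2^k x k matrix of +/-1 genotype codes, '+' (P1 allele) first."""
        if self.k == 0:
            return np.zeros((1, 0))
        return np.array(list(itertools.product([1.0, -1.0], repeat=self.k)))

    def design_matrix(self) -> np.ndarray:
        """2^k x p design mapping effect vector to component means."""
        classes = self.genotype_classes
        cols = [np.ones(self.n_components)]
        for j in range(self.k):
            cols.append(classes[:, j])
        if self.epistasis in ("digenic", "full"):
            for a, b in itertools.combinations(range(self.k), 2):
                cols.append(classes[:, a] * classes[:, b])
        if self.epistasis == "full" and self.k == 3:
            cols.append(classes[:, 0] * classes[:, 1] * classes[:, 2])
        return np.column_stack(cols)


def enumerate_dh_models() -> list[ModelSpec]:
    """The DH-applicable genetic-model catalog.

    DH lines carry two genotype classes per locus in 1:1 proportion, so
    only the additive(-epistatic) major-gene models apply (no dominance,
    no 1:2:1 mixtures).  The catalog crosses k = 0..3 with the
    admissible epistasis options and polygene presence/absence; in the
    classical lettered catalog the single-normal polygene model is class
    C, 1/2/3-gene models without polygenes classes A/B/F, with polygenes
    classes D/E/G, and the 3-gene full-epistasis + polygene entry is the
    G-0 model.
    """
    specs = []
    for k in (0, 1, 2, 3):
        if k < 2:
            ep_options = ["none"]
        elif k == 2:
            ep_options = ["none", "digenic"]
        else:
            ep_options = ["none", "digenic", "full"]
        for ep in ep_options:
            for pg in (True, False):
                specs.append(ModelSpec(k=k, epistasis=ep, polygenes=pg))
    return specs


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit suite for one fitted mixture."""

    u1: float
    u1_p: float
    u2: float
    u2_p: float
    u3: float
    u3_p: float
    nw2: float
    nw2_pass_05: bool
    nw2_pass_01: bool
    dn: float
    dn_p: float

    def n_passed(self, alpha: float = 0.05) -> int:
        """How many of the five tests do NOT reject at ``alpha``."""
        passes = sum(p > alpha for p in (self.u1_p, self.u2_p, self.u3_p, self.dn_p))
        crit = NW2_CRITICAL.get(alpha, NW2_CRITICAL[0.05])
        return passes + (self.nw2 < crit)

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


@dataclass(frozen=True)
class GeneticArchitecture:
    """First- and second-order genetic parameters of the selected model."""

    first_order: dict
    sigma_p2: float
    sigma_mg2: float
    sigma_pg2: float
    sigma_e2: float
    h_mg2: float
    h_pg2: float

    def as_series(self) -> pd.Series:
        out = dict(self.first_order)
        out.update(
            sigma_p2=self.sigma_p2, sigma_mg2=self.sigma_mg2,
            sigma_pg2=self.sigma_pg2, sigma_e2=self.sigma_e2,
            h_mg2=self.h_mg2, h_pg2=self.h_pg2,
        )
        return pd.Series(out)


def _legendre_u_stats(u: np.ndarray) -> list[tuple[float, float]]:
    """First three orthonormal-polynomial uniformity statistics.

    For U(0,1) data the shifted Legendre polynomials p1..p3 have zero
    mean and unit variance, so (sum p_j(u) / sqrt(n))^2 is chi^2(1)
    under the null; the three statistics probe departures in the first
    three moments of the probability-integral transform.
    """
    n = u.size
    p1 = math.sqrt(3.0) * (2 * u - 1)
    p2 = math.sqrt(5.0) * (6 * u**2 - 6 * u + 1)
    p3 = math.sqrt(7.0) * (20 * u**3 - 30 * u**2 + 12 * u - 1)
    out = []
    for p in (p1, p2, p3):
        stat = float(p.sum() ** 2 / n)
        out.append((stat, float(sps.chi2.sf(stat, df=1))))
    return out


def goodness_of_fit(y, cdf) -> FitDiagnostics:
    """Test sample ``y`` against a fitted distribution function.

    ``cdf`` maps values to fitted probabilities.  Under a correct model
    the transforms u_i = F(y_i) are i.i.d. uniform; U1/U2/U3 are
    chi-square(1) moment statistics on the u_i, nW2 the Cramer-von Mises
    statistic (pass/fail against the 0.461 / 0.743 critical values) and
    Dn the Kolmogorov sup-distance with its asymptotic p-value.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 8:
        raise ValueError("goodness-of-fit withheld for n < 8")
    u = np.clip(np.asarray(cdf(y), dtype=float), 1e-12, 1 - 1e-12)
    (u1, p1), (u2, p2), (u3, p3) = _legendre_u_stats(u)
    us = np.sort(u)
    n = u.size
    i = np.arange(1, n + 1)
    nw2 = float(1.0 / (12 * n) + ((us - (2 * i - 1) / (2 * n)) ** 2).sum())
    dn = float(max((i / n - us).max(), (us - (i - 1) / n).max()))
    dn_p = float(sps.kstwobign.sf(math.sqrt(n) * dn))
    return FitDiagnostics(
        u1=u1, u1_p=p1, u2=u2, u2_p=p2, u3=u3, u3_p=p3,
        nw2=nw2,
        nw2_pass_05=nw2 < NW2_CRITICAL[0.05],
        nw2_pass_01=nw2 < NW2_CRITICAL[0.01],
        dn=dn, dn_p=dn_p,
    )


def estimate_first_order(
    component_means,
    model: ModelSpec,
    weights=None,
    permutation=None,
) -> dict:
    """Effect estimates from component means by (weighted) least squares.

    ``weights`` defaults to equal; for the saturated 3-gene
    full-epistasis design the solution is the orthogonal (Hadamard)
    transform of the means, so means generated from a parameter vector
    are recovered exactly.  ``permutation`` optionally reorders the
    supplied means into the canonical class order.
    """
    mu = np.asarray(component_means, dtype=float)
    if permutation is not None:
        mu = mu[np.asarray(permutation)]
    x = model.design_matrix()
    if mu.size != x.shape[0]:
        raise ValueError(f"expected {x.shape[0]} component means, got {mu.size}")
    w = np.ones(mu.size) if weights is None else np.asarray(weights, dtype=float)
    xtw = x.T * w
    gram = xtw @ x
    if np.linalg.matrix_rank(gram) < x.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design for columns {model.param_names}"
        )
    beta = np.linalg.solve(gram, xtw @ mu)
    est = dict(zip(model.param_names, beta.astype(float)))
    est["_residuals"] = (mu - x @ beta).astype(float)
    return est


def estimate_second_order(sigma_p2: float, sigma_w2: float, sigma_e2: float) -> dict:
    """Variance partition and heritabilities.

    sigma_pg2 = max(sigma_w2 - sigma_e2, 0); sigma_mg2 closes the
    partition sigma_p2 = sigma_mg2 + sigma_pg2 + sigma_e2; heritability
    percentages are each component over the phenotypic variance.
    """
    if sigma_p2 <= 0:
        raise ValueError("phenotypic variance must be positive")
    sigma_pg2 = max(sigma_w2 - sigma_e2, 0.0)
    sigma_mg2 = sigma_p2 - sigma_pg2 - sigma_e2
    return {
        "sigma_p2": float(sigma_p2),
        "sigma_mg2": float(sigma_mg2),
        "sigma_pg2": float(sigma_pg2),
        "sigma_e2": float(sigma_e2),
        "h_mg2": 100.0 * sigma_mg2 / sigma_p2,
        "h_pg2": 100.0 * sigma_pg2 / sigma_p2,
    }


def model_aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, -2 lnL + 2p."""
    return -2.0 * loglik + 2.0 * n_params


class MixedInheritanceModel:
    """Mixed major-gene/polygene model of one line-level trait sample.

    Parameters
    ----------
    y : array-like
        Line-level trait values (e.g. per-line head-splitting indices).
    sigma_e2 : float
        Environmental variance, taken from the replicated-design ANOVA
        error mean square; it floors the within-component variance and
        anchors the polygene/environment split.
    """

    def __init__(self, y, sigma_e2: float):
        self.y = np.asarray(y, dtype=float)
        if self.y.ndim != 1 or self.y.size < 2:
            raise ValueError("y must be a 1-d sample with n >= 2")
        if sigma_e2 < 0:
            raise ValueError("environmental variance must be non-negative")
        self.sigma_e2 = float(sigma_e2)

    @classmethod
    def from_dataframe(cls, phenotypes: pd.DataFrame, sigma_e2: float,
                       value: str = "value") -> "MixedInheritanceModel":
        """Build from a (line, rep, plant, value) table via line means."""
        return cls(phenotypes.groupby("line")[value].mean().to_numpy(), sigma_e2)

    # ---------------------------------------------------------- fitting
    def _initial_means(self, spec: ModelSpec, rng: np.random.Generator,
                       jitter: float) -> np.ndarray:
        """Quantile split of the sorted sample into 2^k groups."""
        c = spec.n_components
        chunks = np.array_split(np.sort(self.y)[::-1], c)
        mu = np.array([chunk.mean() for chunk in chunks])
        if jitter > 0:
            mu = mu + rng.normal(0.0, jitter, size=c)
        return mu

    def _em(self, spec: ModelSpec, mu0: np.ndarray, tol: float,
            max_iter: int) -> dict:
        y = self.y
        n = y.size
        c = spec.n_components
        x = spec.design_matrix()
        log_pi = -math.log(c)
        # project the initial means onto the constrained space
        beta = np.linalg.lstsq(x, mu0, rcond=None)[0]
        mu = x @ beta
        sigma2 = max(float(np.var(y)), self.sigma_e2, 1e-12)
        if not spec.polygenes:
            sigma2 = max(self.sigma_e2, 1e-12)
        loglik = -np.inf
        path = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E-step: posterior membership under fixed 1/2^k proportions
            logphi = (
                log_pi
                - 0.5 * math.log(2 * math.pi * sigma2)
                - (y[:, None] - mu[None, :]) ** 2 / (2 * sigma2)
            )
            m = logphi.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(logphi - m).sum(axis=1))
            new_loglik = float(lse.sum())
            w = np.exp(logphi - lse[:, None])
            path.append(new_loglik)
            if new_loglik - loglik < tol and it > 1:
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik
            # CM-step 1: constrained means by GLS with component masses
            n_c = w.sum(axis=0)
            if np.any(n_c < 1e-10):
                # a component lost all posterior mass; signal a restart
                return {"loglik": -np.inf, "beta": beta, "mu": mu,
                        "sigma2": sigma2, "iters": it, "converged": False,
                        "path": path, "empty": True}
            ybar_c = (w * y[:, None]).sum(axis=0) / n_c
            xtw = x.T * n_c
            beta = np.linalg.solve(xtw @ x, xtw @ ybar_c)
            mu = x @ beta
            # CM-step 2: common within variance, floored at sigma_e2
            if spec.polygenes:
                sigma2 = float((w * (y[:, None] - mu[None, :]) ** 2).sum() / n)
                sigma2 = max(sigma2, self.sigma_e2, 1e-12)
        return {"loglik": loglik, "beta": beta, "mu": mu, "sigma2": sigma2,
                "iters": it, "converged": converged, "path": path,
                "empty": False}

    def fit(self, spec: ModelSpec | None = None, *, tol: float = 1e-8,
            max_iter: int = 2000, n_restarts: int = 10,
            seed: int = 0) -> "MixtureResults":
        """Fit one genetic model by IECM; restarts keep the best fit.

        Non-convergence within ``max_iter`` is flagged on the result,
        not raised.  Restarts jitter the quantile-split initial means;
        a run whose components empty out is discarded in favour of the
        next restart.
        """
        spec = spec or ModelSpec(k=3, epistasis="full", polygenes=True)
        rng = np.random.default_rng(seed)
        scale = max(float(np.std(self.y)), 1e-6)
        best = None
        for restart in range(max(1, n_restarts)):
            jitter = 0.0 if restart == 0 else 0.5 * scale
            mu0 = self._initial_means(spec, rng, jitter)
            out = self._em(spec, mu0, tol, max_iter)
            if out["empty"]:
                continue
            if best is None or out["loglik"] > best["loglik"]:
                best = out
        if best is None:  # every restart collapsed; refit unjittered anyway
            best = self._em(spec, self._initial_means(spec, rng, 0.0), tol, max_iter)
        return MixtureResults(self, spec, best)

    def fit_catalog(self, specs=None, **fit_kw) -> "ModelSelectionResults":
        """Fit every catalog model and rank by AIC."""
        specs = list(specs) if specs is not None else enumerate_dh_models()
        fits = [self.fit(spec, **fit_kw) for spec in specs]
        return select_model(fits)


class MixtureResults:
    """A fitted constrained Gaussian mixture (one genetic model)."""

    def __init__(self, model: MixedInheritanceModel, spec: ModelSpec, out: dict):
        self.model = model
        self.spec = spec
        self.beta = out["beta"]
        self.means = out["mu"]
        self.sigma_w2 = out["sigma2"]
        self.loglik = out["loglik"]
        self.n_iter = out["iters"]
        self.converged = out["converged"]
        self.loglik_path = list(out["path"])
        self.aic = model_aic(self.loglik, spec.n_params)
        self._diag = None

    @property
    def mixing_proportions(self) -> np.ndarray:
        c = self.spec.n_components
        return np.full(c, 1.0 / c)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        sd = math.sqrt(max(self.sigma_w2, 1e-300))
        comp = sps.norm.cdf((x[..., None] - self.means) / sd)
        return comp.mean(axis=-1)

    def diagnostics(self) -> FitDiagnostics:
        if self._diag is None:
            self._diag = goodness_of_fit(self.model.y, self.cdf)
        return self._diag

    def first_order(self, weights=None, permutation=None) -> dict:
        return estimate_first_order(self.means, self.spec, weights, permutation)

    def second_order(self) -> dict:
        sigma_p2 = float(np.var(self.model.y, ddof=1))
        sigma_w2 = self.sigma_w2 if self.spec.polygenes else self.model.sigma_e2
        return estimate_second_order(sigma_p2, sigma_w2, self.model.sigma_e2)

    def genetic_params(self) -> GeneticArchitecture:
        """First- and second-order parameters of this fit."""
        first = {k: v for k, v in self.first_order().items() if k != "_residuals"}
        second = self.second_order()
        return GeneticArchitecture(
            first_order=first,
            sigma_p2=second["sigma_p2"],
            sigma_mg2=second["sigma_mg2"],
            sigma_pg2=second["sigma_pg2"],
            sigma_e2=second["sigma_e2"],
            h_mg2=second["h_mg2"],
            h_pg2=second["h_pg2"],
        )

    def summary(self) -> str:
        lines = [
            f"Mixed-inheritance mixture fit: {self.spec.label}",
            f"  components        {self.spec.n_components} (proportions fixed at "
            f"1/{self.spec.n_components})",
            f"  n                 {self.model.y.size}",
            f"  log-likelihood    {self.loglik:.4f}",
            f"  AIC               {self.aic:.4f}  (p = {self.spec.n_params})",
            f"  sigma_w^2         {self.sigma_w2:.4f} (floor sigma_e^2 = "
            f"{self.model.sigma_e2:.4f})",
            f"  converged         {self.converged} in {self.n_iter} iterations",
            "  component means   " + ", ".join(f"{m:.3f}" for m in self.means),
        ]
        first = self.first_order()
        eff = ", ".join(f"{k}={v:.3f}" for k, v in first.items() if k != "_residuals")
        lines.append("  effects           " + eff)
        return "\n".join(lines)


@dataclass
class ModelSelectionResults:
    """AIC ranking of candidate genetic models with the selected best."""

    fits: list = field(repr=False)
    table: pd.DataFrame = field(repr=False)
    best: MixtureResults = field(repr=False)

    def summary(self) -> str:
        return (
            "Genetic-model selection (AIC ascending)\n"
            + self.table.to_string(index=False,
                                   float_format=lambda v: f"{v:.3f}")
            + f"\nselected: {self.best.spec.label}"
        )


def select_model(fits, aic_window: float = 2.0) -> ModelSelectionResults:
    """Rank fits by AIC; near-ties resolved by goodness of fit.

    Within ``aic_window`` of the minimum AIC, candidates are re-ranked
    by goodness-of-fit passes, i.e. the fewest significant test
    statistics (more passes is better), then by AIC, with parameter
    count and label breaking exact ties -- a deterministic order.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need >= 2 candidate fits to select among")
    rows = []
    for f in fits:
        try:
            passes = f.diagnostics().n_passed()
        except ValueError:
            passes = -1
        rows.append(
            {
                "model": f.spec.label, "k": f.spec.k,
                "epistasis": f.spec.epistasis, "polygenes": f.spec.polygenes,
                "n_params": f.spec.n_params, "loglik": f.loglik,
                "aic": f.aic, "gof_passes": passes,
            }
        )
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    aic_min = min(f.aic for f in fits)
    candidates = [f for f in fits if f.aic - aic_min <= aic_window]

    def diag_passes(f):
        try:
            return f.diagnostics().n_passed()
        except ValueError:
            return -1

    best = min(
        candidates,
        key=lambda f: (-diag_passes(f), f.aic, f.spec.n_params, f.spec.label),
    )
    return ModelSelectionResults(fits=fits, table=table, best=best)


def fit_mixture_iecm(y, model: ModelSpec, sigma_e2: float, **options) -> MixtureResults:
    """Functional wrapper: fit one genetic model to a trait sample."""
    return MixedInheritanceModel(y, sigma_e2).fit(model, **options)
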