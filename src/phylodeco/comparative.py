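"""Phylogenetically structured trait-environment analyses.

Implements the comparative toolkit used to relate morphology to elevation,
precipitation and temperature across a clade with one observation per
species:

* phylogenetically structured PCA (pPCA): eigenanalysis of the evolutionary
  covariance matrix R = (X - 1a)' C^-1 (X - 1a) / (n - 1), where a is the
  GLS ancestral mean and C the phylogenetic covariance;
* a phylogenetic mixed model (PMM) y = X beta + b + e fit by maximum
  likelihood, with b ~ N(0, sigma2_b * C-tilde) under the phylogenetic
  random effect ("P"; C-tilde is C scaled to unit maximum diagonal) or
  iid by species ("NP"; with one observation per species this collapses to
  OLS because the species and residual variances are confounded);
* backward elimination on AIC over fixed-effect terms respecting
  marginality, with k-fold cross-validation to flag overfitting;
* a boundary likelihood-ratio choice between the P and NP random effects
  (reference mixture 0.5*chi2_0 + 0.5*chi2_1, choose P iff p < 0.5);
* likelihood-based total and partial R2 (R2 = 1 - exp(-(2/n) * delta-logL));
* Benjamini-Yekutieli FDR adjustment (via statsmodels).

All fits use ML (not REML) so AIC comparisons across fixed-effect
structures are valid.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular
from statsmodels.stats.multitest import multipletests

from .trees import PhyloCov, PhyloTree, phylo_vcv

__all__ = [
    "standardize",
    "PPCAResult",
    "ppca",
    "pca",
    "MixedModelFit",
    "fit_pmm",
    "backward_eliminate",
    "kfold_cv",
    "choose_random_effect",
    "r2_lik",
    "by_adjust",
    "build_design",
]


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def standardize(table: pd.DataFrame, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Z-score the given columns (all numeric columns by default).

    Uses the sample standard deviation (ddof=1). Zero-variance columns
    raise, naming the offending trait.
    """
    out = table.copy()
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    for c in cols:
        sd = out[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"trait {c!r} has zero variance; cannot standardize")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


# ---------------------------------------------------------------------------
# pPCA / PCA
# ---------------------------------------------------------------------------


@dataclass
class PPCAResult:
    ancestral_mean: np.ndarray
    evolutionary_cov: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray          # columns are PC axes
    scores: np.ndarray            # rows follow the species order
    percent_variance: np.ndarray
    species: List[str]
    variables: List[str]


def _ppca_core(X: np.ndarray, Cinv: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    one = np.ones((X.shape[0], 1))
    denom = float((one.T @ Cinv @ one).item())
    a = (one.T @ Cinv @ X) / denom          # GLS ancestral mean, shape (1, p)
    Xc = X - a
    R = Xc.T @ Cinv @ Xc / (X.shape[0] - 1)
    return a.ravel(), R


def ppca(
    table: pd.DataFrame,
    tree: Optional[PhyloTree] = None,
    cov: Optional[PhyloCov] = None,
) -> PPCAResult:
    """Phylogenetically structured PCA.

    The ancestral mean a = (1'C^-1 1)^-1 1'C^-1 X replaces the sample mean,
    the evolutionary covariance R = (X-1a)' C^-1 (X-1a)/(n-1) replaces the
    sample covariance, and scores are (X - 1a) V in the original (not
    GLS-rotated) space. With ``tree=None`` and ``cov=None`` this is
    ordinary PCA (C = I).
    """
    species = list(table.index)
    variables = list(table.columns)
    X = table.to_numpy(dtype=float)
    n = X.shape[0]
    if cov is None and tree is not None:
        cov = phylo_vcv(tree)
    if cov is not None:
        C = cov.reorder(species).matrix
        try:
            Cinv = np.linalg.inv(C)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "phylogenetic covariance is singular; jitter zero-length branches"
            ) from exc
    else:
        Cinv = np.eye(n)
    a, R = _ppca_core(X, Cinv)
    lam, V = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    # sign convention: largest-magnitude loading of each axis positive
    for j in range(V.shape[1]):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    scores = (X - a) @ V
    total = lam.sum()
    pct = 100.0 * lam / total if total > 0 else np.zeros_like(lam)
    return PPCAResult(a, R, lam, V, scores, pct, species, variables)


def pca(table: pd.DataFrame) -> PPCAResult:
    """Ordinary (non-phylogenetic) PCA: pPCA with C = I."""
    return ppca(table, tree=None, cov=None)


# ---------------------------------------------------------------------------
# phylogenetic mixed model
# ---------------------------------------------------------------------------


@dataclass
class MixedModelFit:
    terms: List[str]
    beta: np.ndarray
    beta_cov: np.ndarray
    sigma2_b: float
    sigma2_e: float
    random: str                    # 'P' or 'NP'
    loglik: float
    aic: float
    converged: bool
    n: int
    species: List[str]
    y: np.ndarray = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)
    Ctilde: Optional[np.ndarray] = field(repr=False, default=None)

    @property
    def k_params(self) -> int:
        # fixed effects + variance components actually free
        return len(self.beta) + (2 if self.random == "P" else 1)


def build_design(
    table: pd.DataFrame,
    terms: Sequence[str],
) -> Tuple[np.ndarray, List[str]]:
    """Design matrix with intercept from ':'-separated interaction terms.

    ``terms=["elev", "prec", "elev:prec"]`` yields columns
    [1, elev, prec, elev*prec] in table row order.
    """
    n = len(table)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for t in terms:
        parts = t.split(":")
        col = np.ones(n)
        for p in parts:
            if p not in table.columns:
                raise KeyError(f"covariate {p!r} not in table")
            col = col * table[p].to_numpy(dtype=float)
        cols.append(col)
        names.append(t)
    X = np.column_stack(cols)
    return X, names


def _mll_profile(h: float, y: np.ndarray, X: np.ndarray, Ct: np.ndarray):
    """Profile log-likelihood over the mixing proportion h in [0, 1].

    V0 = h*Ctilde + (1-h)*I; beta and the total variance are profiled out.
    Returns (loglik, beta, sigma2_total, beta_cov_unit) where the actual
    beta covariance is sigma2 * beta_cov_unit.
    """
    n = len(y)
    V0 = h * Ct + (1.0 - h) * np.eye(n)
    try:
        L = np.linalg.cholesky(V0)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, None
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, None
    beta = XtX_inv @ Xw.T @ yw
    r = yw - Xw @ beta
    rss = float(r @ r)
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    ll = -0.5 * n * (math.log(2 * math.pi) + 1 + math.log(sigma2)) - 0.5 * logdet
    return ll, beta, sigma2, XtX_inv


def fit_pmm(
    y: np.ndarray,
    X: np.ndarray,
    tree: Optional[PhyloTree] = None,
    random: str = "P",
    cov: Optional[PhyloCov] = None,
    species: Optional[Sequence[str]] = None,
    terms: Optional[Sequence[str]] = None,
) -> MixedModelFit:
    """ML fit of y = X beta + b + e.

    Under ``random="P"``, b ~ N(0, sigma2_b * C-tilde) with C-tilde the
    phylogenetic covariance scaled to unit maximum diagonal (so sigma2_b is
    on the same scale as sigma2_e); e ~ N(0, sigma2_e I). beta is profiled
    by GLS at each variance point and the mixing proportion
    h = sigma2_b / (sigma2_b + sigma2_e) is optimized on [0, 1].

    Under ``random="NP"`` (iid species effect) with one observation per
    species, sigma2_b and sigma2_e are confounded; the fit collapses to a
    single residual variance, i.e. OLS, with sigma2_b reported as 0.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("y and X have incompatible shapes")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    species = list(species) if species is not None else [f"t{i}" for i in range(n)]
    terms = list(terms) if terms is not None else [f"x{j}" for j in range(X.shape[1])]

    if random == "NP":
        ll, beta, s2, bcov_unit = _mll_profile(0.0, y, X, np.zeros((n, n)))
        k = X.shape[1] + 1
        return MixedModelFit(terms, beta, s2 * bcov_unit, 0.0, s2, "NP",
                             ll, 2 * k - 2 * ll, True, n, species,
                             y=y, X=X, Ctilde=None)
    if random != "P":
        raise ValueError("random must be 'P' or 'NP'")

    if cov is None:
        if tree is None:
            raise ValueError("the P random effect needs a tree or covariance")
        cov = phylo_vcv(tree)
    Ct = cov.reorder(species).matrix if species is not None and cov.taxa != list(species) else cov.matrix
    Ct = Ct / float(np.max(np.diag(Ct)))

    neg = lambda h: -_mll_profile(h, y, X, Ct)[0]
    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    converged = bool(res.success)
    h = float(res.x)
    # the bounded optimizer can stall just inside the boundary; compare ends
    for cand in (0.0, 1.0 - 1e-12, h):
        if -neg(cand) > -neg(h) + 1e-12:
            h = cand
    ll, beta, s2, bcov_unit = _mll_profile(h, y, X, Ct)
    if not converged:
        warnings.warn("phylogenetic mixed-model optimizer did not report convergence")
    k = X.shape[1] + 2
    return MixedModelFit(terms, beta, s2 * bcov_unit, h * s2, (1 - h) * s2, "P",
                         ll, 2 * k - 2 * ll, converged, n, species,
                         y=y, X=X, Ctilde=Ct)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def _contains(inter: str, main: str) -> bool:
    return main != inter and set(main.split(":")) <= set(inter.split(":"))


def full_interaction_terms(covariates: Sequence[str]) -> List[str]:
    """All main effects and interactions of the given covariates."""
    out: List[str] = []
    for k in range(1, len(covariates) + 1):
        for combo in itertools.combinations(covariates, k):
            out.append(":".join(combo))
    return out


def backward_eliminate(
    table: pd.DataFrame,
    response: str,
    covariates: Sequence[str] = ("elev", "prec", "temp"),
    tree: Optional[PhyloTree] = None,
    cov: Optional[PhyloCov] = None,
    random: str = "P",
) -> MixedModelFit:
    """AIC backward elimination from the full interaction model.

    At each step the removable term (one not contained in any remaining
    interaction) whose removal lowers AIC the most is dropped; the search
    stops when no removal lowers AIC. The selected fit's AIC is never
    above the full model's.
    """
    terms = full_interaction_terms(covariates)
    n = len(table)
    if n <= len(terms) + 1:
        raise ValueError(
            f"full interaction model has {len(terms) + 1} fixed parameters "
            f"but only n={n} species; reduce the covariate set"
        )
    if n < len(terms) + 4:
        warnings.warn(
            "full interaction model is near-saturated at this sample size; "
            "use cross-validation to assess overfitting"
        )
    y = table[response].to_numpy(dtype=float)
    species = list(table.index)

    def fit(tms: List[str]) -> MixedModelFit:
        X, names = build_design(table, tms)
        f = fit_pmm(y, X, tree=tree, cov=cov, random=random, species=species,
                    terms=names)
        return f

    current = list(terms)
    best = fit(current)
    improved = True
    while improved and current:
        improved = False
        removable = [t for t in current if not any(_contains(u, t) for u in current)]
        candidates = []
        for t in removable:
            trial = [u for u in current if u != t]
            candidates.append((fit(trial), trial))
        if not candidates:
            break
        cand_best, cand_terms = min(candidates, key=lambda c: c[0].aic)
        if cand_best.aic < best.aic:
            best, current = cand_best, cand_terms
            improved = True
    return best


def kfold_cv(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    k: int = 3,
    tree: Optional[PhyloTree] = None,
    cov: Optional[PhyloCov] = None,
    random: str = "P",
    seed: int = 0,
) -> float:
    """Mean squared prediction error under k-fold cross-validation.

    Species are partitioned into k folds by a seeded shuffle. Held-out
    species are predicted from fixed effects, plus (under the P random
    effect) the conditional Brownian-motion expectation of their random
    effect given the training species.
    """
    n = len(table)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of species n={n}")
    if cov is None and tree is not None:
        cov = phylo_vcv(tree)
    species = list(table.index)
    y = table[response].to_numpy(dtype=float)
    X, names = build_design(table, terms)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, k)
    Cfull = cov.reorder(species).matrix if cov is not None else None
    if Cfull is not None:
        Cfull = Cfull / float(np.max(np.diag(Cfull)))
    sse = 0.0
    for fold in folds:
        test = np.zeros(n, bool)
        test[fold] = True
        train = ~test
        sub = table.loc[train]
        subcov = None
        if Cfull is not None:
            subcov = PhyloCov([species[i] for i in np.where(train)[0]],
                              Cfull[np.ix_(train, train)])
        f = fit_pmm(y[train], X[train], cov=subcov, random=random,
                    species=list(sub.index), terms=names)
        pred = X[test] @ f.beta
        if random == "P" and Cfull is not None and f.sigma2_b > 0:
            Vtr = f.sigma2_b * Cfull[np.ix_(train, train)] + f.sigma2_e * np.eye(train.sum())
            Cte = f.sigma2_b * Cfull[np.ix_(test, train)]
            resid = y[train] - X[train] @ f.beta
            pred = pred + Cte @ np.linalg.solve(Vtr, resid)
        sse += float(np.sum((y[test] - pred) ** 2))
    return sse / n


def choose_random_effect(fit_p: MixedModelFit, fit_np: MixedModelFit,
                         cutoff: float = 0.5) -> Tuple[str, float]:
    """Boundary LRT between the P and NP random effects.

    The test statistic LR = 2(logL_P - logL_NP) is referred to the mixture
    0.5*chi2_0 + 0.5*chi2_1, giving p = 0.5 * P(chi2_1 >= LR) (p = 0.5
    exactly at LR = 0). The phylogenetic random effect is chosen iff
    p < cutoff.
    """
    if fit_p.terms != fit_np.terms:
        raise ValueError("fits must share identical fixed effects")
    lr = max(0.0, 2.0 * (fit_p.loglik - fit_np.loglik))
    p = 0.5 * float(stats.chi2.sf(lr, df=1)) if lr > 0 else 0.5
    return ("P" if p < cutoff else "NP"), p


# ---------------------------------------------------------------------------
# R2 and FDR
# ---------------------------------------------------------------------------


def r2_lik(full: MixedModelFit, reduced: MixedModelFit) -> float:
    """Likelihood-based R2: 1 - exp(-(2/n) (logL_full - logL_reduced)).

    Total R2 compares against the intercept-only, no-random-effect model;
    partial R2 for a term compares against the full model refit without it.
    """
    if full.n != reduced.n:
        raise ValueError("fits use different sample sizes")
    diff = full.loglik - reduced.loglik
    if diff < -1e-8:
        raise ValueError(
            "reduced model has higher likelihood than full model; "
            "models are not nested or a fit failed to converge"
        )
    return 1.0 - math.exp(-2.0 * max(diff, 0.0) / full.n)


def by_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up FDR adjustment (order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]
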