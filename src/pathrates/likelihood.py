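"""Inverse-gamma marginal likelihood, model fitting and model comparison.

The model: each gene i of a pathway evolves on the same fixed calibrated
tree by BM or OU diffusion, with its own evolutionary rate sigma^2_i drawn
from an inverse-gamma distribution with shape alpha and scale beta,

    p(s) = beta^alpha / Gamma(alpha) * s^(-alpha-1) * exp(-beta / s).

Working on contrasts y (expression minus a reference species) removes the
unknown ancestral mean, so one gene's contrasts are N(0, sigma^2 V') with
V' the contrast covariance.  Because the inverse gamma is conjugate to a
Gaussian variance, the rate integrates out in closed form; per gene with
m contrasts and quadratic form q = y' V'^-1 y,

    log f(y) = log Gamma(alpha + m/2) - log Gamma(alpha)
             + alpha log beta - (m/2) log(2 pi) - (1/2) log|V'|
             - (alpha + m/2) log(beta + q/2),

a multivariate-t-like heavy-tailed density.  Genes are treated as
independent (a composite likelihood when columns are mean-centered), so
the pathway log-likelihood is the sum over genes.

Candidate models per pathway: one equal-rates BM model (free alpha,
beta), one shifted-BM model per candidate subtree (plus the multiplier
r), and one phylogeny-wide OU model (plus the constraint theta).  Fits
are compared with AIC = 2k - 2 loglik and Akaike weights
w_i = exp(-(AIC_i - AIC_min)/2), normalized to sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import digamma, gammaln

from .errors import DataError, FitError
from .tree import (
    CalibratedTree,
    CovarianceMatrix,
    bm_shift_components,
    contrast_values,
    enumerate_shift_models,
    _ou_values_and_grad,
)

logger = logging.getLogger("pathrates")

EQUAL_RATES = "equal-rates"
SHIFT = "shift"
OU = "ou"

#: box constraints for the optimized parameters (natural scale)
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (1e-2, 1e3),
    "beta": (1e-4, 1e4),
    "r": (1e-3, 1e3),
    "theta": (1e-4, 1e3),
}

#: number of best grid points polished by the bounded quasi-Newton search
N_POLISH = 4


def _grid3(lo: float, hi: float) -> np.ndarray:
    """Three log-spaced interior points (geometric quartiles) of a box."""
    llo, lhi = np.log(lo), np.log(hi)
    return np.exp(llo + (lhi - llo) * np.array([0.25, 0.5, 0.75]))


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class InverseGammaRates:
    """Shape/scale of the inverse-gamma distribution of per-gene rates.

    The distribution has mean beta/(alpha-1) for alpha > 1 and variance
    beta^2 / ((alpha-1)^2 (alpha-2)) for alpha > 2; no mass at zero, so
    no gene is ever exactly frozen.
    """

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise DataError("inverse-gamma parameters must be positive")

    @property
    def mean(self) -> float:
        if self.alpha <= 1:
            return float("nan")
        return self.beta / (self.alpha - 1)

    @property
    def variance(self) -> float:
        if self.alpha <= 2:
            return float("nan")
        return self.beta**2 / ((self.alpha - 1) ** 2 * (self.alpha - 2))


@dataclass(frozen=True)
class ModelSpec:
    """A candidate evolutionary model for one pathway.

    ``family`` is one of ``"equal-rates"`` (BM, same rate law on every
    branch; k = 2 free parameters alpha, beta), ``"shift"`` (BM with a
    subtree rate multiplier r; k = 3) or ``"ou"`` (phylogeny-wide
    Ornstein-Uhlenbeck constraint theta; k = 3).
    """

    family: str
    shift_clade: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.family not in (EQUAL_RATES, SHIFT, OU):
            raise DataError(f"unknown model family {self.family!r}")
        if (self.family == SHIFT) != (self.shift_clade is not None):
            raise DataError("shift_clade is required exactly for shift models")
        if self.shift_clade is not None:
            object.__setattr__(self, "shift_clade", tuple(self.shift_clade))

    @property
    def k(self) -> int:
        return 2 if self.family == EQUAL_RATES else 3

    @property
    def name(self) -> str:
        if self.family == EQUAL_RATES:
            return "equal rates"
        if self.family == OU:
            return "Ornstein-Uhlenbeck"
        return " and ".join(self.shift_clade) + " shift"


@dataclass
class FitResult:
    """Maximum-likelihood fit of one candidate model."""

    spec: ModelSpec
    params: dict[str, float]
    loglik: float
    converged: bool
    n_genes_used: int

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik


@dataclass
class ModelComparison:
    """All candidate fits with their Akaike weights."""

    fits: list[FitResult]
    weights: np.ndarray
    best_index: int

    @property
    def best(self) -> FitResult:
        return self.fits[self.best_index]

    def weight_of(self, name: str) -> float:
        for fit, w in zip(self.fits, self.weights):
            if fit.spec.name == name:
                return float(w)
        raise KeyError(name)


@dataclass
class ContrastMatrix:
    """Genes x (n-1) matrix of reference-subtracted log expression.

    Columns are the non-reference species in tree tip order; when
    ``centered``, each column has mean zero across the retained genes.
    """

    values: np.ndarray
    columns: tuple[str, ...]
    ref: str
    centered: bool
    gene_ids: tuple[str, ...]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


# ----------------------------------------------------------------------
def make_contrasts(
    expr: pd.DataFrame, ref: str, center: bool = True
) -> ContrastMatrix:
    """Form contrasts Y_ij = X_ij - X_i,ref, dropping incomplete genes.

    Parameters
    ----------
    expr : DataFrame
        Genes x species log expression; NaN marks missing values.  Genes
        with any missing species are dropped before contrasting.
    ref : str
        Reference species (a column of ``expr``).
    center : bool
        Subtract each contrast column's mean across genes.  This guards
        against coherent drift shared by co-regulated genes.
    """
    if ref not in expr.columns:
        raise DataError(f"reference species {ref!r} not in expression columns")
    if expr.shape[1] < 2:
        raise DataError("need at least 2 species to form contrasts")
    complete = expr.dropna(axis=0, how="any")
    dropped = expr.shape[0] - complete.shape[0]
    if dropped:
        logger.warning("make_contrasts: dropped %d gene(s) with missing values", dropped)
    if center and complete.shape[0] < 2:
        raise DataError("centering requires at least 2 complete genes")
    others = [c for c in expr.columns if c != ref]
    values = complete[others].to_numpy(dtype=float) - complete[[ref]].to_numpy(
        dtype=float
    )
    if center:
        values = values - values.mean(axis=0, keepdims=True)
    return ContrastMatrix(
        values=values,
        columns=tuple(others),
        ref=ref,
        centered=center,
        gene_ids=tuple(complete.index.astype(str)),
    )


# ----------------------------------------------------------------------
def _as_matrix(V) -> np.ndarray:
    if isinstance(V, CovarianceMatrix):
        return V.values
    return np.asarray(V, dtype=float)


def ig_marginal_loglik(Y, Vprime, rates: InverseGammaRates | None = None,
                       *, alpha: float | None = None, beta: float | None = None) -> float:
    """Closed-form marginal log-likelihood of contrast data.

    Sums over genes the log density obtained by integrating the zero-mean
    Gaussian N(y; 0, sigma^2 V') against InvGamma(sigma^2; alpha, beta).
    ``Y`` may be a :class:`ContrastMatrix` or a (genes x m) array;
    ``Vprime`` a contrast-space :class:`~pathrates.tree.CovarianceMatrix`
    or an (m x m) array.
    """
    if rates is not None:
        alpha, beta = rates.alpha, rates.beta
    if alpha is None or beta is None:
        raise DataError("provide InverseGammaRates or alpha and beta")
    Ymat = Y.values if isinstance(Y, ContrastMatrix) else np.atleast_2d(np.asarray(Y, float))
    Vp = _as_matrix(Vprime)
    if Ymat.shape[1] != Vp.shape[0]:
        raise DataError("contrast and covariance dimensions disagree")
    ll, _ = _loglik_terms(Ymat, Vp, float(alpha), float(beta))
    if not np.isfinite(ll):
        raise FitError("non-finite marginal log-likelihood")
    return ll


def _loglik_terms(Ymat, Vp, alpha, beta):
    """(log-likelihood, per-gene quadratic forms) with PD failure -> FitError."""
    try:
        L = linalg.cholesky(Vp, lower=True)
    except linalg.LinAlgError as exc:
        raise FitError("contrast covariance is not positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    half = linalg.solve_triangular(L, Ymat.T, lower=True)
    q = np.sum(half * half, axis=0)
    G, m = Ymat.shape
    c = alpha + m / 2.0
    ll = (
        G * (gammaln(c) - gammaln(alpha) + alpha * np.log(beta) - m / 2.0 * np.log(2 * np.pi))
        - G / 2.0 * logdet
        - c * np.sum(np.log(beta + q / 2.0))
    )
    return float(ll), q


def _nll_and_grad(x, Ymat, cov_fn):
    """Negative log-likelihood and gradient in log-parameter space.

    ``x`` holds (log alpha, log beta[, log p]) where p is r or theta;
    ``cov_fn(p)`` returns (V', dV'/dp) or (V', None) for 2-parameter
    models.
    """
    alpha, beta = np.exp(x[0]), np.exp(x[1])
    extra = np.exp(x[2]) if len(x) > 2 else None
    Vp, dVp = cov_fn(extra)
    G, m = Ymat.shape
    try:
        L = linalg.cholesky(Vp, lower=True)
    except linalg.LinAlgError:
        return 1e12, np.zeros_like(x)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Vinv_Yt = linalg.cho_solve((L, True), Ymat.T)  # m x G
    q = np.sum(Ymat.T * Vinv_Yt, axis=0)
    c = alpha + m / 2.0
    t = beta + q / 2.0
    logt = np.log(t)
    ll = (
        G * (gammaln(c) - gammaln(alpha) + alpha * np.log(beta) - m / 2.0 * np.log(2 * np.pi))
        - G / 2.0 * logdet
        - c * np.sum(logt)
    )
    d_alpha = G * (digamma(c) - digamma(alpha) + np.log(beta)) - np.sum(logt)
    d_beta = G * alpha / beta - c * np.sum(1.0 / t)
    grad = [d_alpha * alpha, d_beta * beta]  # chain rule to log scale
    if extra is not None:
        Vinv_dV = linalg.cho_solve((L, True), dVp)
        tr = np.trace(Vinv_dV)
        # s_g' dV s_g with s_g = V'^-1 y_g
        sdvs = np.sum(Vinv_Yt * (dVp @ Vinv_Yt), axis=0)
        d_p = -G / 2.0 * tr + c / 2.0 * np.sum(sdvs / t)
        grad.append(d_p * extra)
    if not np.isfinite(ll):
        return 1e12, np.zeros_like(x)
    return -ll, -np.asarray(grad)


def candidate_models(tree: CalibratedTree) -> list[ModelSpec]:
    """The full candidate set for one pathway: equal-rates BM, one shifted
    BM per candidate subtree, and phylogeny-wide OU."""
    specs = [ModelSpec(EQUAL_RATES)]
    specs += [ModelSpec(SHIFT, shift_clade=c) for c in enumerate_shift_models(tree)]
    specs.append(ModelSpec(OU))
    return specs


def _model_cov_fn(tree: CalibratedTree, spec: ModelSpec, ref: str) -> Callable:
    ref_idx = tree.tip_index(ref)
    if spec.family == EQUAL_RATES:
        C = contrast_values(tree.shared_times(), ref_idx)
        return lambda p: (C, None)
    if spec.family == SHIFT:
        base, scaled = bm_shift_components(tree, spec.shift_clade)
        Cb = contrast_values(base, ref_idx)
        Cs = contrast_values(scaled, ref_idx)
        return lambda r: (Cb + r * Cs, Cs)
    # OU: covariance and its theta-derivative share the contrast transform
    def ou_fn(theta):
        V, dV = _ou_values_and_grad(tree, theta)
        return contrast_values(V, ref_idx), contrast_values(dV, ref_idx)

    return ou_fn


def fit_model(
    Y: ContrastMatrix,
    tree: CalibratedTree,
    spec: ModelSpec,
    *,
    n_polish: int = N_POLISH,
) -> FitResult:
    """Maximize the marginal log-likelihood of one candidate model.

    The search runs over log-transformed parameters inside fixed box
    bounds.  The objective is evaluated on a deterministic 3x3(x3)
    log-grid of starting points, and a bounded L-BFGS-B quasi-Newton
    search with analytic gradients is polished from the best ``n_polish``
    grid points; the best polished optimum is reported.  The achieved
    log-likelihood is therefore >= the value at every grid point.
    """
    Ymat = Y.values
    if Ymat.shape[0] < 2:
        raise FitError("model fitting requires at least 2 genes")
    if Ymat.shape[1] != tree.n_tips - 1:
        raise DataError("contrast matrix does not match the tree")
    col_scale = np.max(np.abs(Ymat), axis=0)
    if np.any(col_scale < 1e-12):
        raise FitError("degenerate contrasts: a column is identically zero")

    cov_fn = _model_cov_fn(tree, spec, Y.ref)
    param_names = ["alpha", "beta"]
    if spec.family == SHIFT:
        param_names.append("r")
    elif spec.family == OU:
        param_names.append("theta")
    bounds_nat = [PARAM_BOUNDS[p] for p in param_names]
    log_bounds = [(np.log(lo), np.log(hi)) for lo, hi in bounds_nat]
    axes = [np.log(_grid3(lo, hi)) for lo, hi in bounds_nat]
    grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(len(axes), -1).T

    values = np.array([_nll_and_grad(x, Ymat, cov_fn)[0] for x in grid])
    order = np.argsort(values, kind="stable")[: max(1, n_polish)]

    best = None
    any_converged = False
    for i in order:
        res = optimize.minimize(
            _nll_and_grad,
            grid[i],
            args=(Ymat, cov_fn),
            jac=True,
            method="L-BFGS-B",
            bounds=log_bounds,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise FitError(f"optimization failed for model {spec.name!r} at all starts")
    if not any_converged:
        logger.warning("fit_model: no start converged for model %r", spec.name)
    params = {p: float(np.exp(v)) for p, v in zip(param_names, best.x)}
    return FitResult(
        spec=spec,
        params=params,
        loglik=-float(best.fun),
        converged=any_converged,
        n_genes_used=Ymat.shape[0],
    )


def fit_all_models(
    Y: ContrastMatrix, tree: CalibratedTree, specs: Sequence[ModelSpec] | None = None
) -> list[FitResult]:
    """Fit every candidate model (see :func:`candidate_models`)."""
    if specs is None:
        specs = candidate_models(tree)
    return [fit_model(Y, tree, s) for s in specs]


def compare_models(fits: Sequence[FitResult]) -> ModelComparison:
    """Akaike weights over candidate fits of the same data.

    w_i = exp(-(AIC_i - AIC_min)/2), normalized.  Exact ties for the best
    model are broken by smaller parameter count, then declaration order.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise DataError("model comparison requires at least 2 fits")
    n_used = {f.n_genes_used for f in fits}
    if len(n_used) != 1:
        raise DataError(f"fits use different gene counts: {sorted(n_used)}")
    aic = np.array([f.aic for f in fits])
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    best = min(range(len(fits)), key=lambda i: (-w[i], fits[i].k, i))
    return ModelComparison(fits=fits, weights=w, best_index=best)


# ----------------------------------------------------------------------
def scan_pathways(
    expr: pd.DataFrame,
    genesets: Mapping[str, Sequence[str]],
    tree: CalibratedTree,
    ref: str,
    *,
    center: bool = True,
    min_genes: int = 10,
) -> pd.DataFrame:
    """Fit all candidate models to each gene set and tabulate the results.

    Per retained term: the term id, N (genes with complete data), the
    best model, its Akaike weight, and the fitted constraint (theta) or
    shift (r) parameter — empty for equal rates — plus one weight column
    per candidate model.  Terms with fewer than ``min_genes`` complete,
    resolvable genes are skipped.
    """
    if not genesets:
        raise DataError("empty gene-set collection")
    specs = candidate_models(tree)
    names = [s.name for s in specs]
    rows = []
    for term, genes in genesets.items():
        present = [g for g in genes if g in expr.index]
        sub = expr.loc[present].dropna(axis=0, how="any")
        n = sub.shape[0]
        if n < min_genes:
            logger.warning(
                "scan_pathways: term %s skipped (%d complete genes < %d)",
                term, n, min_genes,
            )
            continue
        Y = make_contrasts(sub, ref, center=center)
        try:
            fits = fit_all_models(Y, tree, specs)
        except FitError as exc:
            logger.warning("scan_pathways: term %s failed to fit: %s", term, exc)
            continue
        comp = compare_models(fits)
        best = comp.best
        if best.spec.family == SHIFT:
            param = best.params["r"]
        elif best.spec.family == OU:
            param = best.params["theta"]
        else:
            param = np.nan
        row = {
            "term": term,
            "n_genes": n,
            "best_model": best.spec.name,
            "best_waic": float(comp.weights[comp.best_index]),
            "parameter": param,
        }
        row.update({f"w[{nm}]": float(w) for nm, w in zip(names, comp.weights)})
        rows.append(row)
    if not rows:
        logger.warning("scan_pathways: no term passed the size filter")
        cols = ["term", "n_genes", "best_model", "best_waic", "parameter"]
        return pd.DataFrame(columns=cols + [f"w[{nm}]" for nm in names])
    return pd.DataFrame(rows)


def normalized_divergence(
    expr: pd.DataFrame, tree: CalibratedTree, ref: str
) -> pd.DataFrame:
    """Branch-length-normalized log fold-changes against the reference.

    For each non-reference species j and gene i, returns
    (X_ij - X_i,ref) / d(j, ref) with d the patristic distance on the
    tree.  Under phylogeny-wide stabilizing selection the most divergent
    species shows the narrowest normalized distribution.
    """
    if ref not in expr.columns:
        raise DataError(f"reference species {ref!r} not in expression columns")
    out = {}
    for sp in expr.columns:
        if sp == ref:
            continue
        d = tree.patristic_distance(sp, ref)
        if d <= 0:
            raise DataError(f"zero patristic distance between {sp!r} and {ref!r}")
        out[sp] = (expr[sp] - expr[ref]) / d
    return pd.DataFrame(out, index=expr.index)


def kernel_density(values: np.ndarray, grid: np.ndarray | None = None):
    """Gaussian kernel density summary of a divergence vector.

    Returns (grid, density); a convenience for plotting the normalized
    divergence distributions externally.
    """
    from scipy.stats import gaussian_kde

    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if grid is None:
        lo, hi = values.min(), values.max()
        pad = 0.25 * (hi - lo + 1e-12)
        grid = np.linspace(lo - pad, hi + pad, 256)
    return grid, gaussian_kde(values)(grid)
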