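"""Exploratory multidimensional graded response model estimation.

The graded response model (GRM) in slope--intercept form gives, for an
item with slope vector ``a`` and strictly decreasing intercepts
``d_1 > ... > d_{K-1}``, cumulative boundary probabilities

    P(X >= k + 1 | theta) = logistic(a . theta + d_k),

so the category probabilities are successive differences of logistic
curves.  Estimation is by marginal maximum likelihood with an EM
algorithm: the E-step computes posterior weights of the respondents over
a fixed quadrature grid of the latent trait space (tensor Gauss--Hermite
for up to three dimensions, scrambled quasi-Monte-Carlo nodes beyond);
the M-step maximizes each item's expected complete-data log-likelihood
with a quasi-Newton step under a log-decrement parametrization that keeps
the intercepts strictly ordered.  Exploratory fits are identified by an
echelon constraint (upper-triangular zeros in the leading slope rows) and
obliquely rotated (quartimin) afterwards to obtain a simple-structure
pattern and correlated traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import qmc
from scipy.special import ndtri

from .instrument import ResponseMatrix
from .rotation import oblimin_rotate

_LOGISTIC_SCALE = 1.702  # normal-ogive approximation constant
_PMIN = 1e-12


@dataclass
class ItemParameters:
    """Slope vector and strictly decreasing intercept vector of one item."""

    slopes: np.ndarray
    intercepts: np.ndarray

    def __post_init__(self) -> None:
        self.slopes = np.atleast_1d(np.asarray(self.slopes, float))
        self.intercepts = np.atleast_1d(np.asarray(self.intercepts, float))
        if self.intercepts.size > 1 and not (np.diff(self.intercepts) < 0).all():
            raise ValueError("intercepts must be strictly decreasing")
        if not (np.isfinite(self.slopes).all() and np.isfinite(self.intercepts).all()):
            raise ValueError("item parameters must be finite")

    @property
    def n_categories(self) -> int:
        return self.intercepts.size + 1


@dataclass
class QuadratureGrid:
    """Nodes and normalized weights over the latent trait space."""

    nodes: np.ndarray  # M x D
    weights: np.ndarray  # M, sums to 1
    kind: str = "gauss-hermite"

    def __post_init__(self) -> None:
        if self.nodes.ndim == 1:
            self.nodes = self.nodes[:, None]
        if self.nodes.shape[0] == 0:
            raise ValueError("empty quadrature grid")
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("quadrature weights must sum to 1")

    @property
    def log_weights(self) -> np.ndarray:
        return np.log(np.clip(self.weights, 1e-300, None))


def make_grid(
    n_dims: int,
    n_quadrature: int = 21,
    n_qmc_nodes: int = 2000,
    seed: int = 0,
) -> QuadratureGrid:
    """Tensor Gauss--Hermite grid for D <= 3, scrambled Sobol beyond."""
    if n_dims <= 3:
        per_dim = {1: n_quadrature, 2: min(n_quadrature, 15), 3: min(n_quadrature, 9)}[n_dims]
        x, w = np.polynomial.hermite_e.hermegauss(per_dim)
        w = w / w.sum()
        node_grids = np.meshgrid(*([x] * n_dims), indexing="ij")
        weight_grids = np.meshgrid(*([w] * n_dims), indexing="ij")
        nodes = np.stack([g.ravel() for g in node_grids], axis=1)
        ws = np.prod(np.stack([g.ravel() for g in weight_grids], axis=1), axis=1)
        return QuadratureGrid(nodes, ws / ws.sum(), "gauss-hermite")
    sampler = qmc.Sobol(d=n_dims, scramble=True, seed=seed)
    m = int(np.ceil(np.log2(max(2, n_qmc_nodes))))
    u = sampler.random_base2(m)[:n_qmc_nodes]
    nodes = ndtri(np.clip(u, 1e-12, 1 - 1e-12))
    weights = np.full(nodes.shape[0], 1.0 / nodes.shape[0])
    return QuadratureGrid(nodes, weights, "qmc-sobol")


# ----------------------------------------------------------------------
# category probabilities
# ----------------------------------------------------------------------

def category_probabilities(item: ItemParameters, theta: np.ndarray) -> np.ndarray:
    """GRM category probabilities at one trait vector.

    ``P(k) = logistic(a.theta + d_{k-1}) - logistic(a.theta + d_k)`` with
    the boundary conventions logistic(+inf) = 1, logistic(-inf) = 0.
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    z = float(item.slopes @ theta)
    cum = expit(z + item.intercepts)
    probs = np.diff(np.concatenate([[1.0], cum, [0.0]])) * -1.0
    return probs


def _prob_table(slopes: np.ndarray, intercepts: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """M x K category probability table for one item over grid nodes."""
    z = nodes @ slopes
    cum = expit(z[:, None] + intercepts[None, :])
    ones = np.ones((nodes.shape[0], 1))
    zeros = np.zeros((nodes.shape[0], 1))
    table = -np.diff(np.concatenate([ones, cum, zeros], axis=1), axis=1)
    return np.clip(table, _PMIN, 1.0)


# ----------------------------------------------------------------------
# likelihood plumbing
# ----------------------------------------------------------------------

def _onehot(data: ResponseMatrix) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse n x (sum K_j) indicator of observed responses.

    Missing entries contribute no nonzero, so both the per-respondent
    log-likelihood and the expected counts skip them automatically.
    """
    n, p = data.n, data.p
    offsets = np.concatenate([[0], np.cumsum(data.n_categories)])
    rows, cols = [], []
    for j in range(p):
        obs = np.nonzero(data.codes[:, j] >= 0)[0]
        rows.append(obs)
        cols.append(offsets[j] + data.codes[obs, j])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    M = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, int(offsets[-1]))
    )
    return M, offsets


def _log_prob_block(params: list[ItemParameters], nodes: np.ndarray) -> np.ndarray:
    """Concatenated log probability table, (sum K_j) x M."""
    blocks = [np.log(_prob_table(it.slopes, it.intercepts, nodes)).T for it in params]
    return np.concatenate(blocks, axis=0)


def marginal_loglik(
    data: ResponseMatrix,
    params: list[ItemParameters],
    grid: QuadratureGrid,
) -> float:
    """Marginal log-likelihood sum_i log sum_m w_m prod_j P(x_ij | theta_m)."""
    if data.n == 0:
        raise ValueError("empty response matrix")
    onehot, _ = _onehot(data)
    logp = _log_prob_block(params, grid.nodes)  # C x M
    L = onehot @ logp  # n x M
    return float(logsumexp(L + grid.log_weights[None, :], axis=1).sum())


# ----------------------------------------------------------------------
# M-step: per-item expected-complete-data maximization
# ----------------------------------------------------------------------

def _pack(a_free: np.ndarray, d: np.ndarray) -> np.ndarray:
    t = np.empty(a_free.size + d.size)
    t[: a_free.size] = a_free
    t[a_free.size] = d[0]
    if d.size > 1:
        t[a_free.size + 1 :] = np.log(np.clip(-np.diff(d), 1e-8, None))
    return t


def _unpack(t: np.ndarray, n_free: int, n_d: int) -> tuple[np.ndarray, np.ndarray]:
    a_free = t[:n_free]
    d = np.empty(n_d)
    d[0] = t[n_free]
    if n_d > 1:
        d[1:] = d[0] - np.cumsum(np.exp(t[n_free + 1 :]))
    return a_free, d


def _item_objective(
    t: np.ndarray,
    r: np.ndarray,
    nodes_free: np.ndarray,
    n_d: int,
) -> tuple[float, np.ndarray]:
    """Negative expected complete-data log-likelihood and its gradient."""
    n_free = nodes_free.shape[1]
    a_free, d = _unpack(t, n_free, n_d)
    z = nodes_free @ a_free
    S = expit(z[:, None] + d[None, :])  # M x (K-1)
    M = z.shape[0]
    K = n_d + 1
    P = np.empty((M, K))
    P[:, 0] = 1.0 - S[:, 0]
    if K > 2:
        P[:, 1:-1] = S[:, :-1] - S[:, 1:]
    P[:, -1] = S[:, -1]
    P = np.clip(P, _PMIN, 1.0)
    nll = -float(np.sum(r * np.log(P)))

    ratio = r / P  # M x K
    sprime = S * (1.0 - S)
    # dNLL/d(z + d_j): category j gains +S_j, category j-1 loses it
    g = -(ratio[:, 1:] - ratio[:, :-1]) * sprime  # M x (K-1)
    grad_d = g.sum(axis=0)
    grad_a = nodes_free.T @ g.sum(axis=1)
    grad_t = np.empty_like(t)
    grad_t[:n_free] = grad_a
    grad_t[n_free] = grad_d.sum()
    if n_d > 1:
        tails = np.cumsum(grad_d[::-1])[::-1]
        grad_t[n_free + 1 :] = -np.exp(t[n_free + 1 :]) * tails[1:]
    return nll, grad_t


def _maximize_item(
    r: np.ndarray,
    nodes: np.ndarray,
    a0: np.ndarray,
    d0: np.ndarray,
    free_mask: np.ndarray,
    maxiter: int,
) -> tuple[np.ndarray, np.ndarray]:
    nodes_free = nodes[:, free_mask]
    t0 = _pack(a0[free_mask], d0)
    res = minimize(
        _item_objective,
        t0,
        args=(r, nodes_free, d0.size),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter},
    )
    a_free, d = _unpack(res.x, int(free_mask.sum()), d0.size)
    a = np.zeros_like(a0)
    a[free_mask] = a_free
    return a, d


# ----------------------------------------------------------------------
# EM driver
# ----------------------------------------------------------------------

@dataclass
class EstimationOptions:
    tol: float = 1e-4              # absolute log-likelihood change
    param_tol: float = 1e-3        # max absolute parameter change
    max_cycles: int = 500
    n_quadrature: int = 21         # per-dimension Gauss-Hermite nodes (D<=3)
    n_qmc_nodes: int = 2000        # quasi-Monte-Carlo nodes (D>=4)
    mstep_maxiter: int = 25
    min_n: int = 50
    slope_bound: float = 25.0


@dataclass
class MIRTFit:
    params: list[ItemParameters]
    item_ids: list[str]
    loadings: np.ndarray
    communalities: np.ndarray
    trait_correlations: np.ndarray
    loglik: float
    n_params: int
    ics: dict[str, float]
    converged: bool
    n_used: int
    grid: QuadratureGrid
    loglik_history: list[float] = field(default_factory=list)
    rotation: np.ndarray | None = None
    excluded_items: list[str] = field(default_factory=list)

    @property
    def n_dims(self) -> int:
        return self.params[0].slopes.size if self.params else 0

    @property
    def slope_matrix(self) -> np.ndarray:
        return np.array([it.slopes for it in self.params])

    @property
    def rotated_slopes(self) -> np.ndarray:
        """Slopes in the obliquely rotated (simple-structure) metric."""
        if self.rotation is None or self.n_dims == 1:
            return self.slope_matrix
        return self.slope_matrix @ np.linalg.inv(self.rotation).T

    def parameter_table(self) -> pd.DataFrame:
        rows = []
        slopes = self.rotated_slopes
        for j, item in enumerate(self.item_ids):
            row = {"item": item}
            for q in range(self.n_dims):
                row[f"a{q + 1}"] = slopes[j, q]
            for k, dk in enumerate(self.params[j].intercepts):
                row[f"d{k + 1}"] = dk
            row["communality"] = self.communalities[j]
            rows.append(row)
        return pd.DataFrame(rows)


def _free_mask(j: int, n_dims: int) -> np.ndarray:
    """Echelon identification: item j has zero slopes on dimensions > j."""
    mask = np.ones(n_dims, dtype=bool)
    if j < n_dims - 1:
        mask[j + 1 :] = False
    return mask


def _start_values(
    data: ResponseMatrix,
    n_dims: int,
    start_dims: np.ndarray | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[np.ndarray]]:
    p = data.p
    slopes = np.zeros((p, n_dims))
    intercepts: list[np.ndarray] = []
    for j in range(p):
        # round-robin dominant dimensions (unless an a-priori map is given)
        # plus small jitter on the free cross-slopes to break the symmetric
        # saddle where unused dimensions receive no posterior information
        dim = min(int(start_dims[j]), n_dims - 1) if start_dims is not None else j % n_dims
        mask = _free_mask(j, n_dims)
        slopes[j, mask] = rng.uniform(-0.2, 0.2, size=int(mask.sum()))
        slopes[j, dim if mask[dim] else int(np.nonzero(mask)[0][-1])] = 1.0
        k = int(data.n_categories[j])
        obs = data.codes[:, j][data.codes[:, j] >= 0]
        counts = np.bincount(obs, minlength=k) + 0.5
        tail = 1.0 - np.cumsum(counts / counts.sum())[:-1]
        tail = np.clip(tail, 1e-3, 1 - 1e-3)
        d = np.log(tail / (1 - tail))
        d = np.minimum.accumulate(d) - 1e-6 * np.arange(k - 1)
        intercepts.append(d)
    return slopes, intercepts


def loadings_from_slopes(slopes: np.ndarray) -> np.ndarray:
    """Standardized factor loadings under the normal-ogive approximation."""
    an = slopes / _LOGISTIC_SCALE
    denom = np.sqrt(1.0 + np.sum(an**2, axis=1, keepdims=True))
    return an / denom


def fit_grm(
    data: ResponseMatrix,
    n_dims: int,
    options: EstimationOptions | None = None,
    seed: int = 0,
    start_dims: np.ndarray | None = None,
    start: MIRTFit | None = None,
    rotate: bool = True,
) -> MIRTFit:
    """Fit an exploratory multidimensional GRM by EM.

    ``start_dims`` optionally gives an a-priori dominant dimension per
    item for start values; ``start`` warm-starts from a previous fit on a
    superset of the items (used by stepwise abbreviation).
    """
    opts = options or EstimationOptions()
    if data.n < opts.min_n:
        raise ValueError(f"need at least {opts.min_n} respondents, got {data.n}")
    if not 1 <= n_dims <= data.p:
        raise ValueError("n_dims must be between 1 and the item count")

    # degenerate items: fewer than two observed categories
    excluded = []
    keep = []
    for j, item in enumerate(data.item_ids):
        obs = data.codes[:, j][data.codes[:, j] >= 0]
        if np.unique(obs).size < 2:
            excluded.append(item)
        else:
            keep.append(item)
    if excluded:
        warnings.warn(f"excluding degenerate items: {excluded}")
        data = data.subset_items(keep)
        if start_dims is not None:
            start_dims = None

    grid = make_grid(n_dims, opts.n_quadrature, opts.n_qmc_nodes, seed)
    p = data.p
    onehot, offsets = _onehot(data)
    onehot_T = onehot.T.tocsr()

    if start is not None:
        idx = [start.item_ids.index(i) for i in data.item_ids]
        slopes = start.slope_matrix[idx].copy()
        intercepts = [start.params[j].intercepts.copy() for j in idx]
    else:
        slopes, intercepts = _start_values(
            data, n_dims, start_dims, np.random.default_rng(seed)
        )

    loglik_prev = -np.inf
    history: list[float] = []
    converged = False
    logw = grid.log_weights

    for cycle in range(opts.max_cycles):
        params = [ItemParameters(slopes[j], intercepts[j]) for j in range(p)]
        logp = _log_prob_block(params, grid.nodes)  # C x M
        L = onehot @ logp + logw[None, :]  # n x M
        ll = float(logsumexp(L, axis=1).sum())
        history.append(ll)
        post = np.exp(L - logsumexp(L, axis=1, keepdims=True))  # n x M
        R = onehot_T @ post  # C x M expected counts per category/node

        max_delta = 0.0
        for j in range(p):
            r = R[offsets[j] : offsets[j + 1]].T  # M x K
            a_new, d_new = _maximize_item(
                r, grid.nodes, slopes[j], intercepts[j],
                _free_mask(j, n_dims), opts.mstep_maxiter,
            )
            a_new = np.clip(a_new, -opts.slope_bound, opts.slope_bound)
            max_delta = max(
                max_delta,
                float(np.max(np.abs(a_new - slopes[j]))),
                float(np.max(np.abs(d_new - intercepts[j]))),
            )
            slopes[j] = a_new
            intercepts[j] = d_new

        if cycle > 0 and abs(ll - loglik_prev) < opts.tol and max_delta < opts.param_tol:
            converged = True
            loglik_prev = ll
            break
        loglik_prev = ll

    params = [ItemParameters(slopes[j], intercepts[j]) for j in range(p)]
    logp = _log_prob_block(params, grid.nodes)
    final_ll = float(logsumexp(onehot @ logp + logw[None, :], axis=1).sum())
    history.append(final_ll)
    if not converged:
        warnings.warn(f"EM did not converge in {opts.max_cycles} cycles")

    q = sum(int(_free_mask(j, n_dims).sum()) for j in range(p)) + int(
        np.sum(data.n_categories - 1)
    )
    ics = information_criteria(final_ll, q, data.n)

    load_unrot = loadings_from_slopes(slopes)
    communal = np.sum(load_unrot**2, axis=1)
    if n_dims > 1 and rotate:
        load_rot, phi, T = oblimin_rotate(load_unrot)
        # put positively keyed factors first: flip columns loading negatively
        flips = np.sign(np.sum(load_rot, axis=0))
        flips[flips == 0] = 1.0
        load_rot = load_rot * flips[None, :]
        phi = phi * np.outer(flips, flips)
        T = T * flips[None, :]
    else:
        load_rot, phi, T = load_unrot, np.eye(n_dims), np.eye(n_dims)

    return MIRTFit(
        params=params,
        item_ids=list(data.item_ids),
        loadings=load_rot,
        communalities=communal,
        trait_correlations=phi,
        loglik=final_ll,
        n_params=q,
        ics=ics,
        converged=converged,
        n_used=data.n,
        grid=grid,
        loglik_history=history,
        rotation=T,
        excluded_items=excluded,
    )


# ----------------------------------------------------------------------
# information criteria and dimension selection
# ----------------------------------------------------------------------

def information_criteria(loglik: float, q: int, n: int) -> dict[str, float]:
    """AIC, BIC, AICc and SABIC from a maximized log-likelihood.

    AICc is undefined (NaN) when n <= q + 1.
    """
    aic = -2.0 * loglik + 2.0 * q
    bic = -2.0 * loglik + q * np.log(n)
    aicc = aic + 2.0 * q * (q + 1) / (n - q - 1) if n > q + 1 else float("nan")
    sabic = -2.0 * loglik + q * np.log((n + 2) / 24.0)
    return {"AIC": aic, "BIC": bic, "AICc": aicc, "SABIC": sabic}


def select_dimension_count(
    data: ResponseMatrix,
    candidates: list[int],
    options: EstimationOptions | None = None,
    seed: int = 0,
    criterion: str = "BIC",
    start_dims: np.ndarray | None = None,
) -> tuple[int, pd.DataFrame, dict[int, MIRTFit]]:
    """Fit each candidate dimensionality; pick the criterion minimizer.

    Smaller values of the information criteria indicate a better fit.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    rows = []
    fits: dict[int, MIRTFit] = {}
    for d in candidates:
        sd = None if start_dims is None else np.minimum(np.asarray(start_dims), d - 1)
        try:
            fit = fit_grm(data, d, options=options, seed=seed, start_dims=sd)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"fit with {d} dimensions failed: {exc}")
            continue
        fits[d] = fit
        rows.append({"n_dims": d, "loglik": fit.loglik, "n_params": fit.n_params, **fit.ics})
    if not rows:
        raise RuntimeError("all candidate fits failed")
    table = pd.DataFrame(rows).set_index("n_dims")
    chosen = int(table[criterion].idxmin())
    return chosen, table, fits
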