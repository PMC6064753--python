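"""Confirmatory factor analysis by weighted least squares.

Fits a simple-structure common-factor model to the sample covariance
matrix ``S`` by minimizing the weighted least-squares discrepancy

    F = (s - sigma(theta))' W^{-1} (s - sigma(theta)),

where ``s`` stacks the non-duplicated elements of ``S`` and ``W`` is the
asymptotically distribution-free (ADF) estimate of the covariance matrix
of the sample covariances (fourth-order moments).  When the ADF weight
matrix cannot be inverted reliably (more moment elements than
respondents), the fit falls back to its diagonal (DWLS) and the result
is flagged.  The test statistic is ``chi2 = (n - 1) * F_min``; fit
indices (RMSEA with 90% CI, SRMR, CFI, TLI) follow the standard
noncentrality formulas against an independence baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import ncx2

from .instrument import ResponseMatrix

THRESHOLDS = {
    "chi2_over_df": ("<", 2.0),
    "rmsea": ("<", 0.05),
    "srmr": ("<", 0.05),
    "cfi": (">", 0.95),
    "tli": (">", 0.95),
}


@dataclass(frozen=True)
class CFAModelSpec:
    """Simple-structure loading pattern: every item loads on one factor."""

    factor_of: dict[str, str]
    correlated_factors: bool = True

    @property
    def factors(self) -> tuple[str, ...]:
        seen: list[str] = []
        for f in self.factor_of.values():
            if f not in seen:
                seen.append(f)
        return tuple(seen)

    @property
    def n_factors(self) -> int:
        return len(self.factors)


@dataclass
class FitIndices:
    chi2: float
    df: int
    n: int
    chi2_over_df: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float
    cfi: float
    tli: float
    thresholds_passed: dict[str, bool] = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return all(self.thresholds_passed.values())


@dataclass
class CFAResult:
    loadings: np.ndarray  # p x f pattern (simple structure)
    factor_correlations: np.ndarray
    residual_variances: np.ndarray
    fit: FitIndices | None
    converged: bool
    admissible: bool
    estimator: str  # "wls-adf" or "dwls"
    item_ids: list[str]
    factors: tuple[str, ...]


def _vech(S: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(S.shape[0])
    return S[i, j]


def fit_indices(
    chi2: float,
    df: int,
    n: int,
    chi2_baseline: float,
    df_baseline: int,
    srmr: float = float("nan"),
) -> FitIndices:
    """Standard fit indices from the model and baseline chi-square values.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))) with a 90% CI obtained by
    inverting the noncentral chi-square; CFI and TLI compare against the
    independence baseline and are NaN when the baseline is degenerate.
    """
    if df <= 0 or df_baseline <= 0:
        raise ValueError("df and df_baseline must be positive")
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    ci = _rmsea_ci(chi2, df, n)
    denom = max(chi2_baseline - df_baseline, chi2 - df, 0.0)
    if chi2_baseline <= df_baseline:
        cfi = tli = float("nan")
    else:
        cfi = 1.0 - (max(chi2 - df, 0.0) / denom if denom > 0 else 0.0)
        rb = chi2_baseline / df_baseline
        tli = (rb - chi2 / df) / (rb - 1.0)
    out = FitIndices(
        chi2=chi2, df=df, n=n, chi2_over_df=chi2 / df, rmsea=rmsea,
        rmsea_ci=ci, srmr=srmr, cfi=cfi, tli=tli,
    )
    vals = {"chi2_over_df": out.chi2_over_df, "rmsea": rmsea, "srmr": srmr,
            "cfi": cfi, "tli": tli}
    out.thresholds_passed = {
        name: bool(v < lim) if op == "<" else bool(v > lim)
        for name, (op, lim) in THRESHOLDS.items()
        for v in [vals[name]]
        if not np.isnan(v)
    }
    return out


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Noncentrality-inversion confidence interval for RMSEA."""
    lo_q = (1 + level) / 2  # upper tail prob for lower bound
    hi_q = (1 - level) / 2

    def bound(q: float) -> float:
        # find nc with P(X_{df,nc} <= chi2) = q
        f = lambda nc: ncx2.cdf(chi2, df, nc) - q
        if f(0.0) < 0:
            return 0.0
        upper = max(chi2 * 2, df + 10.0)
        for _ in range(60):
            if f(upper) < 0:
                break
            upper *= 2
        else:
            return float("nan")
        nc = brentq(f, 0.0, upper)
        return float(np.sqrt(nc / (df * (n - 1))))

    return (bound(lo_q), bound(hi_q))


def _implied(loadings: np.ndarray, phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    return loadings @ phi @ loadings.T + np.diag(psi)


class _Parametrization:
    """Unconstrained vector <-> (loadings, factor correlations, psi)."""

    def __init__(self, pattern: np.ndarray, correlated: bool, fixed_psi: np.ndarray):
        self.pattern = pattern  # p x f booleans
        self.p, self.f = pattern.shape
        self.correlated = correlated and self.f > 1
        self.n_corr = self.f * (self.f - 1) // 2 if self.correlated else 0
        self.free_psi = np.isnan(fixed_psi)
        self.fixed_psi = fixed_psi

    @property
    def n_params(self) -> int:
        return self.p + self.n_corr + int(self.free_psi.sum())

    def unpack(self, t: np.ndarray):
        lam = np.zeros((self.p, self.f))
        lam[self.pattern] = t[: self.p]
        pos = self.p
        if self.correlated:
            L = np.eye(self.f)
            for q in range(1, self.f):
                v = np.concatenate([t[pos : pos + q], [1.0]])
                L[q, : q + 1] = v / np.linalg.norm(v)
                pos += q
            phi = L @ L.T
        else:
            phi = np.eye(self.f)
        psi = self.fixed_psi.copy()
        psi[self.free_psi] = np.exp(t[pos:])
        return lam, phi, psi

    def pack(self, lam_vals: np.ndarray, psi: np.ndarray) -> np.ndarray:
        t = np.concatenate(
            [lam_vals, np.zeros(self.n_corr), np.log(np.clip(psi[self.free_psi], 1e-4, None))]
        )
        return t


def fit_cfa(
    data: ResponseMatrix,
    spec: CFAModelSpec,
    estimator: str = "wls",
    ridge: float = 1e-8,
    max_iter: int = 500,
) -> CFAResult:
    """Fit a simple-structure CFA to item scores by WLS/ADF.

    Items are treated as numeric; the input matrix is the sample
    covariance matrix and the weight matrix is the ADF estimate of its
    sampling covariance.  Respondents with missing entries are dropped.
    """
    data = data.complete_rows()
    items = [i for i in data.item_ids if i in spec.factor_of]
    data = data.subset_items(items)
    X = data.values
    n, p = X.shape
    pstar = p * (p + 1) // 2
    if n < 5 * p:
        warnings.warn(f"n = {n} is small for {p} items; CFA may be unstable")
    factors = spec.factors
    pattern = np.zeros((p, len(factors)), dtype=bool)
    for j, item in enumerate(items):
        pattern[j, factors.index(spec.factor_of[item])] = True

    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / (n - 1)
    s = _vech(S)

    # ADF weight matrix (fourth-moment estimate)
    ii, jj = np.tril_indices(p)
    D = Xc[:, ii] * Xc[:, jj]  # n x pstar
    Dc = D - D.mean(axis=0)
    gamma = (Dc.T @ Dc) / n
    use_full = estimator == "wls" and n > pstar + 1
    if use_full:
        gamma_r = gamma + ridge * np.trace(gamma) / pstar * np.eye(pstar)
        try:
            winv = np.linalg.inv(gamma_r)
            est_name = "wls-adf"
        except np.linalg.LinAlgError:
            use_full = False
    if not use_full:
        winv = np.diag(1.0 / np.clip(np.diag(gamma), 1e-10, None))
        est_name = "dwls"
        if estimator == "wls" and n <= pstar + 1:
            warnings.warn(
                "ADF weight matrix is singular (n <= p(p+1)/2); "
                "falling back to diagonal weights"
            )

    # single-indicator factors: fix the uniqueness at 30% of the item variance
    fixed_psi = np.full(p, np.nan)
    for q in range(len(factors)):
        idx = np.nonzero(pattern[:, q])[0]
        if idx.size == 1:
            fixed_psi[idx[0]] = 0.3 * S[idx[0], idx[0]]

    par = _Parametrization(pattern, spec.correlated_factors, fixed_psi)
    # start values: loading = sqrt(half the variance), psi = other half
    lam0 = np.sqrt(np.clip(np.diag(S) * 0.5, 1e-3, None))
    psi0 = np.clip(np.diag(S) * 0.5, 1e-3, None)
    t0 = par.pack(lam0, psi0)

    def discrepancy(t: np.ndarray) -> float:
        lam, phi, psi = par.unpack(t)
        r = s - _vech(_implied(lam, phi, psi))
        return float(r @ winv @ r)

    res = minimize(discrepancy, t0, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9})
    lam, phi, psi = par.unpack(res.x)
    fmin = float(res.fun)
    admissible = bool((psi > 0).all() and np.isfinite(lam).all())

    df = pstar - par.n_params
    chi2 = (n - 1) * fmin

    # independence baseline: diagonal implied covariance
    diag_idx = np.nonzero(ii == jj)[0]

    def base_disc(logv: np.ndarray) -> float:
        r = s.copy()
        r[diag_idx] -= np.exp(logv)
        return float(r @ winv @ r)

    bres = minimize(base_disc, np.log(np.clip(np.diag(S), 1e-6, None)),
                    method="L-BFGS-B", options={"maxiter": 200})
    chi2_b = (n - 1) * float(bres.fun)
    df_b = pstar - p

    # SRMR from correlation-metric residuals (diagonal included)
    sd = np.sqrt(np.diag(S))
    resid = (S - _implied(lam, phi, psi)) / np.outer(sd, sd)
    srmr = float(np.sqrt(np.sum(_vech(resid) ** 2) / pstar))

    indices = None
    if df > 0:
        indices = fit_indices(chi2, df, n, chi2_b, df_b, srmr=srmr)
    if not admissible:
        warnings.warn("inadmissible CFA solution (nonpositive uniqueness)")

    return CFAResult(
        loadings=lam,
        factor_correlations=phi,
        residual_variances=psi,
        fit=indices,
        converged=bool(res.success),
        admissible=admissible,
        estimator=est_name,
        item_ids=items,
        factors=factors,
    )
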