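"""EM-based imputation of missing ordinal responses.

Item scores are modeled as multivariate normal; mean and covariance are
estimated by the standard EM algorithm for incomplete data.  Each
missing entry is then drawn once from its conditional normal
distribution given the respondent's observed items, rounded to the
nearest category and clamped into the valid range.  Observed entries are
never modified.
"""

from __future__ import annotations

import numpy as np

from .instrument import ResponseMatrix
from .rng import child_generators


def _em_mean_cov(
    X: np.ndarray, max_iter: int = 100, tol: float = 1e-5, ridge: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    n, p = X.shape
    miss = np.isnan(X)
    mu = np.nanmean(X, axis=0)
    Xf = np.where(miss, mu[None, :], X)
    sigma = np.cov(Xf, rowvar=False) + ridge * np.eye(p)
    patterns: dict[bytes, np.ndarray] = {}
    rows_of: dict[bytes, list[int]] = {}
    for i in range(n):
        key = miss[i].tobytes()
        patterns[key] = miss[i]
        rows_of.setdefault(key, []).append(i)
    for _ in range(max_iter):
        Xhat = X.copy()
        extra = np.zeros((p, p))
        for key, m in patterns.items():
            rows = rows_of[key]
            if not m.any():
                continue
            o = ~m
            soo = sigma[np.ix_(o, o)] + ridge * np.eye(int(o.sum()))
            smo = sigma[np.ix_(m, o)]
            coef = np.linalg.solve(soo, smo.T).T
            for i in rows:
                Xhat[i, m] = mu[m] + coef @ (X[i, o] - mu[o])
            cond_cov = sigma[np.ix_(m, m)] - coef @ smo.T
            block = np.zeros((p, p))
            block[np.ix_(m, m)] = cond_cov * len(rows)
            extra += block
        mu_new = np.nanmean(np.where(miss, Xhat, X), axis=0)
        Xc = np.where(miss, Xhat, X) - mu_new[None, :]
        sigma_new = (Xc.T @ Xc + extra) / n + ridge * np.eye(p)
        delta = max(
            np.max(np.abs(mu_new - mu)), np.max(np.abs(sigma_new - sigma))
        )
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            break
    return mu, sigma


def em_impute(data: ResponseMatrix, seed: int = 0) -> ResponseMatrix:
    """Impute missing responses; complete input is returned unchanged."""
    if not data.missing_mask.any():
        return data
    frac = data.missing_mask.mean(axis=0)
    bad = [data.item_ids[j] for j in np.nonzero(frac >= 0.5)[0]]
    if bad:
        raise ValueError(f"items with >= 50% missing cannot be imputed: {bad}")
    if data.missing_mask.all(axis=1).any():
        raise ValueError("rows with all items missing cannot be imputed")
    (rng,) = child_generators(seed, 1)
    X = data.values
    mu, sigma = _em_mean_cov(X)
    out = X.copy()
    miss = np.isnan(X)
    for i in np.nonzero(miss.any(axis=1))[0]:
        m = miss[i]
        o = ~m
        soo = sigma[np.ix_(o, o)]
        smo = sigma[np.ix_(m, o)]
        coef = np.linalg.solve(soo + 1e-8 * np.eye(int(o.sum())), smo.T).T
        cmean = mu[m] + coef @ (X[i, o] - mu[o])
        ccov = sigma[np.ix_(m, m)] - coef @ smo.T
        ccov = (ccov + ccov.T) / 2
        w, v = np.linalg.eigh(ccov)
        root = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
        draw = cmean + root @ rng.standard_normal(int(m.sum()))
        out[i, m] = draw
    ncat = data.n_categories.astype(float)
    rounded = np.clip(np.round(out), 1.0, ncat[None, :])
    rounded[~miss] = X[~miss]
    return ResponseMatrix.from_values(rounded, data.item_ids, data.n_categories)
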