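"""Oblique factor rotation by gradient projection.

Implements the gradient-projection algorithm of Bernaards & Jennrich for
oblique rotation with the quartimin (oblimin, gamma = 0) criterion.  The
rotated pattern is ``L = A @ inv(T).T`` with factor correlations
``Phi = T.T @ T``; the columns of ``T`` are constrained to unit length so
factors keep unit variance.
"""

from __future__ import annotations

import numpy as np


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Criterion value and gradient dQ/dL for quartimin."""
    L2 = L**2
    k = L.shape[1]
    N = np.ones((k, k)) - np.eye(k)
    X = L2 @ N
    q = float(np.sum(L2 * X)) / 4.0
    return q, L * X


def oblimin_rotate(
    A: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotate loading matrix ``A`` obliquely toward simple structure.

    Returns ``(L, Phi, T)``: the rotated pattern, the factor correlation
    matrix and the transformation with ``L = A @ inv(T).T``.
    """
    A = np.asarray(A, float)
    k = A.shape[1]
    if k == 1:
        return A.copy(), np.ones((1, 1)), np.ones((1, 1))
    T = np.eye(k)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            X = X / np.sqrt(np.sum(X**2, axis=0))[None, :]
            Ti = np.linalg.inv(X)
            L = A @ Ti.T
            ft, Gq = _quartimin(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = X
        f = ft
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi, T


def align_columns(
    estimate: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve column permutation and sign indeterminacy against a target.

    Greedy matching on absolute column correlation; returns the aligned
    estimate together with the permutation and sign vectors applied.
    """
    est = np.asarray(estimate, float)
    tru = np.asarray(truth, float)
    k = tru.shape[1]
    c = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            with np.errstate(invalid="ignore"):
                c[i, j] = np.corrcoef(tru[:, i], est[:, j])[0, 1]
    c = np.nan_to_num(c)
    perm = np.full(k, -1, dtype=int)
    used: set[int] = set()
    for _ in range(k):
        masked = np.abs(c).copy()
        masked[perm != -1, :] = -np.inf
        masked[:, list(used)] = -np.inf
        i, j = np.unravel_index(np.argmax(masked), c.shape)
        perm[i] = j
        used.add(j)
    signs = np.sign(c[np.arange(k), perm])
    signs[signs == 0] = 1.0
    return est[:, perm] * signs[None, :], perm, signs
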