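"""Genetic-algorithm scale abbreviation.

A binary chromosome marks the retained items; fitness is the negative of

    Cost = I * k + 1 - R^2,

where ``I`` is a fixed per-item cost, ``k`` the number of retained items
and ``R^2`` the mean, over subscales, of the variance in the full-form
subscale score explained by an ordinary least-squares regression on all
retained item scores.  The optimizer is a generational GA with size-2
tournament selection, uniform crossover, per-locus bit-flip mutation and
elitism, run at the conventional hyperparameters (population 100,
1000 generations, elitism 5, crossover 0.8, mutation 0.1).

``sweep_item_cost`` traces cost against the item count by bisecting the
item cost ``I`` until the optimum retains (approximately) each target
number of items, reproducing the familiar cost-versus-k selection curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .instrument import InstrumentSpec, ResponseMatrix
from .rng import child_generators


@dataclass
class GAConfig:
    item_cost: float = 0.05
    population_size: int = 100
    generations: int = 1000
    elitism: int = 5
    p_crossover: float = 0.8
    p_mutation: float = 0.1  # per-chromosome; applied per locus as p/length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.item_cost < 0:
            raise ValueError("item_cost must be >= 0")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("elitism must be < population_size")
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class CostBreakdown:
    k: int
    R2: float
    cost: float
    per_subscale_R2: np.ndarray


@dataclass
class GAResult:
    best_chromosome: np.ndarray
    best_cost: float
    best_breakdown: CostBreakdown
    history: pd.DataFrame  # per-generation best / mean cost
    item_ids: list[str]
    config: GAConfig
    convergent_correlations: dict[str, float] = field(default_factory=dict)

    @property
    def retained_items(self) -> list[str]:
        return [i for i, b in zip(self.item_ids, self.best_chromosome) if b]


# ----------------------------------------------------------------------
# R-squared engine
# ----------------------------------------------------------------------

class _R2Engine:
    """Precomputed Gram matrices for fast per-chromosome R^2 evaluation."""

    def __init__(self, data: ResponseMatrix, instrument: InstrumentSpec) -> None:
        if data.missing_mask.any():
            raise ValueError("GA requires complete (imputed) data")
        X = data.values  # n x p raw scores
        n = X.shape[0]
        self.item_ids = list(data.item_ids)
        self.subscales = instrument.subscales
        cols = np.ones((n, 1))
        self.Xc = np.concatenate([cols, X], axis=1)  # with intercept
        self.G = self.Xc.T @ self.Xc
        Y = np.column_stack(
            [
                X[:, [self.item_ids.index(i) for i in instrument.items_of(s)]].sum(axis=1)
                for s in self.subscales
            ]
        )
        self.XtY = self.Xc.T @ Y
        ybar = Y.mean(axis=0)
        self.sst = np.sum((Y - ybar) ** 2, axis=0)
        self.yty = np.sum(Y * Y, axis=0)

    def r2(self, keep: np.ndarray) -> np.ndarray:
        if not keep.any():
            return np.zeros(len(self.subscales))
        idx = np.concatenate([[0], 1 + np.nonzero(keep)[0]])
        G = self.G[np.ix_(idx, idx)]
        b, *_ = np.linalg.lstsq(G, self.XtY[idx], rcond=None)
        sse = self.yty - np.sum(b * self.XtY[idx], axis=0)
        sse = np.clip(sse, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - sse / self.sst
        return np.clip(np.nan_to_num(r2), 0.0, 1.0)


def subscale_r2(
    data: ResponseMatrix, keep: np.ndarray, instrument: InstrumentSpec
) -> tuple[np.ndarray, float]:
    """Per-subscale and mean R^2 of full-form subscale scores on the kept items.

    Each full-form subscale score (sum of all its items) is regressed by
    OLS on *all* retained item scores; the summary is the arithmetic mean
    over subscales.  With no retained items every R^2 is 0 by convention.
    """
    keep = np.asarray(keep, bool)
    if keep.size != data.p:
        raise ValueError("keep vector length must equal the item count")
    engine = _R2Engine(data, instrument)
    per = engine.r2(keep)
    return per, float(per.mean())


def cost(config: GAConfig, k: int, per_subscale_R2: np.ndarray) -> CostBreakdown:
    """Exact abbreviation cost ``I*k + 1 - R^2`` with its decomposition."""
    per = np.asarray(per_subscale_R2, float)
    if ((per < 0) | (per > 1)).any():
        raise ValueError("R^2 values must lie in [0, 1]")
    r2 = float(per.mean()) if per.size else 0.0
    return CostBreakdown(
        k=int(k), R2=r2, cost=config.item_cost * k + 1.0 - r2, per_subscale_R2=per
    )


# ----------------------------------------------------------------------
# the evolutionary loop
# ----------------------------------------------------------------------

def evolve(
    data: ResponseMatrix,
    instrument: InstrumentSpec,
    config: GAConfig,
    engine: _R2Engine | None = None,
) -> GAResult:
    """Minimize the abbreviation cost over binary keep/drop chromosomes."""
    engine = engine or _R2Engine(data, instrument)
    L = data.p
    rng_init, rng_loop = child_generators(config.seed, 2)
    pop = rng_init.integers(0, 2, size=(config.population_size, L)).astype(np.int8)
    p_locus = config.p_mutation / L
    cache: dict[bytes, float] = {}

    def evaluate(ch: np.ndarray) -> float:
        key = ch.tobytes()
        c = cache.get(key)
        if c is None:
            per = engine.r2(ch.astype(bool))
            c = config.item_cost * int(ch.sum()) + 1.0 - float(per.mean())
            cache[key] = c
        return c

    costs = np.array([evaluate(ch) for ch in pop])
    best_idx = int(np.argmin(costs))
    best = pop[best_idx].copy()
    best_cost = float(costs[best_idx])
    hist_best: list[float] = []
    hist_mean: list[float] = []

    n_off = config.population_size - config.elitism
    for _ in range(config.generations):
        order = np.argsort(costs, kind="stable")
        elites = pop[order[: config.elitism]].copy()
        # size-2 tournament selection for both parents of every offspring
        cand = rng_loop.integers(0, config.population_size, size=(n_off, 2, 2))
        winners = np.where(
            costs[cand[..., 0]] <= costs[cand[..., 1]], cand[..., 0], cand[..., 1]
        )
        pa, pb = pop[winners[:, 0]], pop[winners[:, 1]]
        do_x = rng_loop.uniform(size=n_off) < config.p_crossover
        mix = rng_loop.integers(0, 2, size=(n_off, L)).astype(bool)
        children = np.where(do_x[:, None] & mix, pb, pa).astype(np.int8)
        flips = rng_loop.uniform(size=(n_off, L)) < p_locus
        children ^= flips.astype(np.int8)
        pop = np.concatenate([elites, children], axis=0)
        costs = np.array([evaluate(ch) for ch in pop])
        gen_best = int(np.argmin(costs))
        if costs[gen_best] < best_cost:
            best_cost = float(costs[gen_best])
            best = pop[gen_best].copy()
        hist_best.append(best_cost)
        hist_mean.append(float(costs.mean()))

    per = engine.r2(best.astype(bool))
    breakdown = cost(config, int(best.sum()), per)
    history = pd.DataFrame({"best_cost": hist_best, "mean_cost": hist_mean})
    return GAResult(
        best_chromosome=best.astype(np.int8),
        best_cost=best_cost,
        best_breakdown=breakdown,
        history=history,
        item_ids=list(data.item_ids),
        config=config,
    )


# ----------------------------------------------------------------------
# item-cost sweep
# ----------------------------------------------------------------------

def sweep_item_cost(
    data: ResponseMatrix,
    instrument: InstrumentSpec,
    target_ks: list[int],
    config: GAConfig | None = None,
    max_bisection_steps: int = 8,
    k_tolerance: int = 1,
) -> tuple[pd.DataFrame, GAResult]:
    """Cost-versus-item-count sweep: bisect ``I`` toward each target ``k``.

    For each target the per-item cost is bisected until the GA optimum
    retains (within ``k_tolerance``) the requested number of items; the
    chosen solution is the swept point with minimal cost, ties broken
    toward fewer items.
    """
    if not target_ks:
        raise ValueError("target_ks must be nonempty")
    config = config or GAConfig()
    engine = _R2Engine(data, instrument)
    rows = []
    best_result: GAResult | None = None
    best_key: tuple[float, int] | None = None
    for t_idx, k_target in enumerate(sorted(target_ks, reverse=True)):
        lo, hi = 0.0, 1.0
        closest: tuple[int, GAResult, float] | None = None
        for step in range(max_bisection_steps):
            mid = (lo + hi) / 2.0 if k_target < data.p else 0.0
            cfg = replace(config, item_cost=mid, seed=config.seed + 1000 * t_idx + step)
            res = evolve(data, instrument, cfg, engine=engine)
            k = int(res.best_chromosome.sum())
            if closest is None or abs(k - k_target) < abs(closest[0] - k_target):
                closest = (k, res, mid)
            if abs(k - k_target) <= k_tolerance or k_target >= data.p:
                break
            if k > k_target:
                lo = mid
            else:
                hi = mid
        k, res, used_i = closest
        bd = res.best_breakdown
        row = {
            "k_target": k_target,
            "k": k,
            "item_cost": used_i,
            "cost": bd.cost,
            "R2": bd.R2,
            "reached_target": abs(k - k_target) <= k_tolerance,
        }
        for s, r2s in zip(instrument.subscales, bd.per_subscale_R2):
            row[f"R2_{s}"] = r2s
        rows.append(row)
        key = (bd.cost, k)
        if best_key is None or key < best_key:
            best_key = key
            best_result = res
    table = pd.DataFrame(rows).sort_values("k_target").reset_index(drop=True)
    return table, best_result


# ----------------------------------------------------------------------
# convergent validity of a solution
# ----------------------------------------------------------------------

def convergent_correlation(
    data_train: ResponseMatrix,
    data_valid: ResponseMatrix,
    result: GAResult,
    instrument: InstrumentSpec,
) -> pd.DataFrame:
    """Correlate short-form-predicted with full-form subscale scores.

    Regression weights for the retained items are estimated on the
    training half only; predicted subscale scores are then correlated
    with the full-form subscale scores separately on each half.  A
    ``mean`` row averages over subscales.
    """
    keep = result.best_chromosome.astype(bool)
    kept_idx = np.nonzero(keep)[0]
    rows = []
    Xtr = data_train.values
    Xva = data_valid.values
    if np.isnan(Xtr).any() or np.isnan(Xva).any():
        raise ValueError("convergent correlation requires complete data")
    ids = list(data_train.item_ids)
    for s in instrument.subscales:
        cols = [ids.index(i) for i in instrument.items_of(s)]
        ytr = Xtr[:, cols].sum(axis=1)
        yva = Xva[:, cols].sum(axis=1)
        A = np.concatenate([np.ones((Xtr.shape[0], 1)), Xtr[:, kept_idx]], axis=1)
        b, *_ = np.linalg.lstsq(A, ytr, rcond=None)
        pred_tr = A @ b
        Av = np.concatenate([np.ones((Xva.shape[0], 1)), Xva[:, kept_idx]], axis=1)
        pred_va = Av @ b
        rows.append(
            {
                "subscale": s,
                "train": _safe_corr(pred_tr, ytr),
                "validation": _safe_corr(pred_va, yva),
            }
        )
    df = pd.DataFrame(rows)
    mean_row = {"subscale": "mean", "train": df["train"].mean(),
                "validation": df["validation"].mean()}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
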