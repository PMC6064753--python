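"""S-chi-square item fit and stepwise scale abbreviation.

The S-chi-square statistic compares, for one item, the observed category
frequencies within rest-score groups (total score over the *other* items)
with the frequencies a fitted graded response model implies.  Model-implied
frequencies come from integrating (category probability at theta) x
(rest-score probability at theta) over the quadrature grid; rest-score
distributions use a Lord--Wingersky-style recursion generalized to
polytomous items.  Sparse cells are merged — adjacent rest-score groups
first, then adjacent category cells within a group — until every expected
cell reaches a minimum count.

Raw p-values are corrected with Hochberg's step-up adjustment, and the
stepwise abbreviation loop removes, one at a time, the item with the
smallest adjusted p-value, refitting after every removal, until no
adjusted p-value falls below the significance level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .grm import (
    EstimationOptions,
    ItemParameters,
    MIRTFit,
    QuadratureGrid,
    _free_mask,
    _prob_table,
    fit_grm,
    make_grid,
)
from .instrument import InstrumentSpec, ResponseMatrix


@dataclass
class ItemFitRecord:
    item_id: str
    s_chi2: float
    df: int
    p_raw: float
    p_hochberg: float | None = None
    collapsed_cells: int = 0
    testable: bool = True


@dataclass
class StepRecord:
    removed_item: str
    p_hochberg_at_removal: float
    s_chi2: float
    remaining_count: int


@dataclass
class AbbreviationTrace:
    steps: list[StepRecord]
    final_items: list[str]
    stopped_because: str  # no_significant_misfit | floor_reached | fit_failure
    final_fit: MIRTFit | None = None
    final_records: list[ItemFitRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": i + 1,
                    "removed_item": s.removed_item,
                    "p_hochberg": s.p_hochberg_at_removal,
                    "s_chi2": s.s_chi2,
                    "remaining_count": s.remaining_count,
                }
                for i, s in enumerate(self.steps)
            ]
        )


# ----------------------------------------------------------------------
# summed-score recursion
# ----------------------------------------------------------------------

def summed_score_distribution(
    items: list[ItemParameters], theta: np.ndarray
) -> np.ndarray:
    """Distribution of the summed (0-based) score at a fixed trait vector.

    Convolves the category distributions item by item; the result has
    length ``sum(K_j - 1) + 1`` and sums to one.
    """
    theta = np.atleast_2d(np.asarray(theta, float))
    tables = [_prob_table(it.slopes, it.intercepts, theta)[0] for it in items]
    dist = np.array([1.0])
    for t in tables:
        new = np.zeros(dist.size + t.size - 1)
        for k, pk in enumerate(t):
            new[k : k + dist.size] += dist * pk
        dist = new
    return dist


def _conv_over_nodes(tables: list[np.ndarray]) -> np.ndarray:
    """Summed-score distributions over all grid nodes, shape M x (S+1)."""
    m = tables[0].shape[0] if tables else 1
    dist = np.ones((m, 1))
    for t in tables:
        k = t.shape[1]
        new = np.zeros((m, dist.shape[1] + k - 1))
        for c in range(k):
            new[:, c : c + dist.shape[1]] += dist * t[:, c : c + 1]
        dist = new
    return dist


# ----------------------------------------------------------------------
# collapsing and the statistic
# ----------------------------------------------------------------------

def _collapse_rows(O: np.ndarray, E: np.ndarray, min_total: float):
    groups: list[tuple[np.ndarray, np.ndarray]] = []
    acc_o = np.zeros(O.shape[1])
    acc_e = np.zeros(O.shape[1])
    for r in range(O.shape[0]):
        acc_o = acc_o + O[r]
        acc_e = acc_e + E[r]
        if acc_e.sum() >= min_total:
            groups.append((acc_o, acc_e))
            acc_o = np.zeros(O.shape[1])
            acc_e = np.zeros(O.shape[1])
    if acc_e.sum() > 0 or acc_o.sum() > 0:
        if groups:
            o, e = groups[-1]
            groups[-1] = (o + acc_o, e + acc_e)
        else:
            groups.append((acc_o, acc_e))
    return groups


def _collapse_cells(o: np.ndarray, e: np.ndarray, min_cell: float):
    co: list[float] = []
    ce: list[float] = []
    ao = ae = 0.0
    for k in range(o.size):
        ao += o[k]
        ae += e[k]
        if ae >= min_cell:
            co.append(ao)
            ce.append(ae)
            ao = ae = 0.0
    if ae > 0 or ao > 0:
        if co:
            co[-1] += ao
            ce[-1] += ae
        else:
            co.append(ao)
            ce.append(ae)
    return np.array(co), np.array(ce)


@dataclass
class ItemFitOptions:
    min_cell: float = 1.0
    adjust_df_for_item_params: bool = True
    min_n: int = 100


def _item_fit_from_tables(
    item_id: str,
    O: np.ndarray,
    E: np.ndarray,
    q_item: int,
    min_cell: float,
) -> ItemFitRecord:
    k = O.shape[1]
    groups = _collapse_rows(O, E, min_total=min_cell * k)
    stat = 0.0
    n_cells = 0
    n_rows = 0
    for o_row, e_row in groups:
        co, ce = _collapse_cells(o_row, e_row, min_cell)
        if co.size < 2:
            continue
        n_rows += 1
        n_cells += co.size
        stat += float(np.sum((co - ce) ** 2 / np.clip(ce, 1e-12, None)))
    df = n_cells - n_rows - q_item
    if df <= 0:
        return ItemFitRecord(item_id, stat, df, float("nan"),
                             collapsed_cells=n_cells, testable=False)
    p = float(chi2_dist.sf(stat, df))
    return ItemFitRecord(item_id, stat, df, p, collapsed_cells=n_cells)


def s_chi2_item_fit(
    data: ResponseMatrix,
    fit: MIRTFit,
    item_id: str,
    options: ItemFitOptions | None = None,
) -> ItemFitRecord:
    """S-chi-square fit record for a single item (see ``s_chi2_all``)."""
    records = s_chi2_all(data, fit, options=options, items=[item_id])
    return records[0]


def s_chi2_all(
    data: ResponseMatrix,
    fit: MIRTFit,
    options: ItemFitOptions | None = None,
    items: list[str] | None = None,
) -> list[ItemFitRecord]:
    """S-chi-square records for every requested item of a fitted model.

    Uses complete rows only; run imputation upstream if missingness
    should not drop respondents.
    """
    opts = options or ItemFitOptions()
    data = data.subset_items(fit.item_ids).complete_rows()
    if data.n < opts.min_n:
        raise ValueError(f"need at least {opts.min_n} complete respondents")
    nodes = fit.grid.nodes
    w = fit.grid.weights
    tables = [
        _prob_table(it.slopes, it.intercepts, nodes) for it in fit.params
    ]
    total = data.codes.sum(axis=1)
    wanted = items if items is not None else fit.item_ids
    n_dims = fit.n_dims
    records = []
    for item in wanted:
        j = fit.item_ids.index(item)
        kj = int(data.n_categories[j])
        rest_tables = tables[:j] + tables[j + 1 :]
        f_rest = _conv_over_nodes(rest_tables)  # M x (S+1)
        joint = f_rest.T @ (w[:, None] * tables[j])  # (S+1) x K
        rest_scores = total - data.codes[:, j]
        n_scores = f_rest.shape[1]
        O = np.zeros((n_scores, kj))
        np.add.at(O, (rest_scores, data.codes[:, j]), 1.0)
        n_r = O.sum(axis=1)
        row_mass = joint.sum(axis=1, keepdims=True)
        cond = np.divide(joint, row_mass, out=np.full_like(joint, 1.0 / kj),
                         where=row_mass > 1e-300)
        E = n_r[:, None] * cond
        q_item = (
            int(_free_mask(j, n_dims).sum()) + (kj - 1)
            if opts.adjust_df_for_item_params
            else 0
        )
        records.append(_item_fit_from_tables(item, O, E, q_item, opts.min_cell))
    return records


def fit_from_parameters(
    params: list[ItemParameters],
    item_ids: list[str],
    grid: QuadratureGrid | None = None,
    n_quadrature: int = 21,
) -> MIRTFit:
    """Wrap known item parameters as a fit object (no estimation).

    Used to evaluate item fit against the generating model, e.g. in
    type-I-error calibration experiments.
    """
    n_dims = params[0].slopes.size
    grid = grid or make_grid(n_dims, n_quadrature=n_quadrature)
    from .grm import loadings_from_slopes

    slopes = np.array([it.slopes for it in params])
    load = loadings_from_slopes(slopes)
    return MIRTFit(
        params=params,
        item_ids=list(item_ids),
        loadings=load,
        communalities=np.sum(load**2, axis=1),
        trait_correlations=np.eye(n_dims),
        loglik=float("nan"),
        n_params=0,
        ics={},
        converged=True,
        n_used=0,
        grid=grid,
    )


# ----------------------------------------------------------------------
# Hochberg step-up adjustment
# ----------------------------------------------------------------------

def hochberg_adjust(p_values: np.ndarray) -> np.ndarray:
    """Hochberg step-up adjusted p-values, input order preserved.

    For ascending order statistics p(1) <= ... <= p(m),
    ``adj(i) = min_{j >= i} (m - j + 1) * p(j)``, capped at 1.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj_sorted = np.clip(adj_sorted, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ----------------------------------------------------------------------
# stepwise abbreviation
# ----------------------------------------------------------------------

def stepwise_abbreviate(
    data: ResponseMatrix,
    n_dims: int,
    alpha: float = 0.05,
    estimation: EstimationOptions | None = None,
    itemfit_options: ItemFitOptions | None = None,
    seed: int = 0,
    instrument: InstrumentSpec | None = None,
    start_dims: np.ndarray | None = None,
    max_removals: int | None = None,
) -> AbbreviationTrace:
    """Remove misfitting items one at a time until none remains significant.

    Each iteration refits the GRM on the surviving items (warm-started
    from the previous fit), computes S-chi-square statistics, adjusts
    them with Hochberg's procedure, and removes the single item with the
    smallest adjusted p-value below ``alpha`` (ties broken by larger
    statistic/df ratio, then item id).  The loop stops when no adjusted
    p-value is below ``alpha``, or when removing the candidate would
    empty a subscale (``instrument`` given).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if data.p <= n_dims:
        raise ValueError("instrument must have more items than dimensions")
    current = data
    steps: list[StepRecord] = []
    prev_fit: MIRTFit | None = None
    limit = max_removals if max_removals is not None else data.p
    sd = start_dims
    while True:
        try:
            fit = fit_grm(
                current, n_dims, options=estimation, seed=seed,
                start_dims=sd if prev_fit is None else None, start=prev_fit,
            )
        except Exception as exc:
            warnings.warn(f"fit failed during stepwise abbreviation: {exc}")
            return AbbreviationTrace(steps, list(current.item_ids), "fit_failure")
        records = s_chi2_all(current, fit, options=itemfit_options)
        testable = [r for r in records if r.testable]
        if not testable:
            return AbbreviationTrace(steps, list(current.item_ids),
                                     "no_significant_misfit", fit, records)
        adj = hochberg_adjust(np.array([r.p_raw for r in testable]))
        for r, a in zip(testable, adj):
            r.p_hochberg = float(a)
        significant = [r for r in testable if r.p_hochberg < alpha]
        if not significant or len(steps) >= limit:
            return AbbreviationTrace(steps, list(current.item_ids),
                                     "no_significant_misfit", fit, records)
        significant.sort(
            key=lambda r: (r.p_hochberg, -(r.s_chi2 / max(r.df, 1)), r.item_id)
        )
        candidate = significant[0]
        if instrument is not None:
            sub = instrument.subscale_of[candidate.item_id]
            remaining_in_sub = [
                i for i in current.item_ids
                if instrument.subscale_of[i] == sub and i != candidate.item_id
            ]
            if not remaining_in_sub:
                warnings.warn(
                    f"stopping: removing {candidate.item_id} would empty "
                    f"subscale {sub!r}"
                )
                return AbbreviationTrace(steps, list(current.item_ids),
                                         "floor_reached", fit, records)
        keep = [i for i in current.item_ids if i != candidate.item_id]
        steps.append(
            StepRecord(candidate.item_id, candidate.p_hochberg,
                       candidate.s_chi2, len(keep))
        )
        current = current.subset_items(keep)
        prev_fit = fit
        if sd is not None:
            sd = None
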