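"""Synthetic ordinal response data with known graded-response structure.

The generator emulates the statistical shape of a 500-respondent,
40-item, 4-subscale Likert survey: four correlated latent traits
(pairwise correlations around 0.37-0.49), simple-structure discrimination
(slopes up to about 2.6 on the dominant trait, near-zero elsewhere),
ordered category intercepts spanning roughly -7..+8 on the logit scale,
a small MCAR missingness rate, and two external criterion scores — one
correlating negatively with the traits (a depression-like screen) and one
positively (a generic quality-of-life score).

Every operation takes an explicit integer seed and is bitwise
reproducible.  ``plant_misfit_items`` additionally regenerates chosen
items from a deliberately non-graded-response process, creating
known-truth targets for item-fit-driven abbreviation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .instrument import MISSING, InstrumentSpec, ResponseMatrix
from .rng import child_generators


@dataclass
class SimulationConfig:
    """Ranges that define the generated item bank and trait structure."""

    slope_range: tuple[float, float] = (0.3, 2.6)
    cross_slope_max: float = 0.1
    intercept_top_range: tuple[float, float] = (1.0, 8.0)
    intercept_bottom_range: tuple[float, float] = (-7.0, -1.0)
    trait_correlation_range: tuple[float, float] = (0.367, 0.494)
    missing_rate: float = 0.04
    criterion_noise_sd: float = 4.0


@dataclass
class TrueParameters:
    """Generating graded-response parameters.

    ``slopes`` is items x dimensions (log-odds per trait SD); each row of
    ``intercepts`` is strictly decreasing (log-odds).  Traits are
    multivariate normal with zero mean, unit variances and correlation
    matrix ``trait_correlations``.
    """

    slopes: np.ndarray
    intercepts: np.ndarray
    trait_correlations: np.ndarray
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.intercepts, float)
        if d.ndim != 2 or not (np.diff(d, axis=1) < 0).all():
            raise ValueError("each intercept row must be strictly decreasing")
        r = np.asarray(self.trait_correlations, float)
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("trait correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(r).min() <= 0:
            raise ValueError("trait correlation matrix must be positive definite")

    @property
    def n_items(self) -> int:
        return self.slopes.shape[0]

    @property
    def n_dims(self) -> int:
        return self.slopes.shape[1]

    @property
    def n_categories(self) -> np.ndarray:
        return np.full(self.n_items, self.intercepts.shape[1] + 1)


@dataclass
class SimulatedDataset:
    responses: ResponseMatrix
    true_traits: np.ndarray
    criterion_neg: np.ndarray
    criterion_pos: np.ndarray
    seed: int
    true_params: TrueParameters | None = None
    complete: ResponseMatrix | None = None  # pre-deletion responses
    planted_items: list[str] = field(default_factory=list)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.responses.missing_mask

    @property
    def n(self) -> int:
        return self.responses.n


def _nearest_correlation(r: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest unit-diagonal PD matrix."""
    r = (r + r.T) / 2.0
    w, v = np.linalg.eigh(r)
    if w.min() > min_eig:
        return r
    w = np.clip(w, min_eig, None)
    r = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    if np.linalg.eigvalsh(r).min() <= 0:
        raise ValueError("correlation target not positive definite after projection")
    return r


def generate_true_parameters(
    spec: InstrumentSpec,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> TrueParameters:
    """Draw simple-structure generating parameters for ``spec``.

    The dominant slope of each item (on its subscale's trait) is uniform
    in ``config.slope_range``; off-dominant slopes are uniform in
    ``[0, cross_slope_max]``.  Intercept rows are equally spaced between a
    random top value and a random bottom value, hence strictly decreasing.
    Pairwise trait correlations are drawn in ``trait_correlation_range``
    and projected to the nearest positive-definite correlation matrix.
    """
    config = config or SimulationConfig()
    rng_slope, rng_int, rng_corr = child_generators(seed, 3)
    subscales = spec.subscales
    ndim = len(subscales)
    p = spec.n_items

    slopes = rng_slope.uniform(0.0, config.cross_slope_max, size=(p, ndim))
    lo, hi = config.slope_range
    for j, item in enumerate(spec.item_ids):
        dom = subscales.index(spec.subscale_of[item])
        slopes[j, dom] = rng_slope.uniform(lo, hi)

    kmax = int(spec.categories().max())
    top = rng_int.uniform(*config.intercept_top_range, size=p)
    bottom = rng_int.uniform(*config.intercept_bottom_range, size=p)
    steps = np.linspace(0.0, 1.0, kmax - 1)
    intercepts = top[:, None] + (bottom - top)[:, None] * steps[None, :]

    r = np.eye(ndim)
    iu = np.triu_indices(ndim, k=1)
    vals = rng_corr.uniform(*config.trait_correlation_range, size=len(iu[0]))
    r[iu] = vals
    r = _nearest_correlation(r + np.triu(r, 1).T)

    return TrueParameters(
        slopes=slopes,
        intercepts=intercepts,
        trait_correlations=r,
        item_ids=list(spec.item_ids),
    )


def _draw_responses(
    slopes: np.ndarray, intercepts: np.ndarray, traits: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Zero-based response codes from GRM cumulative probabilities."""
    z = traits @ slopes.T  # n x p
    u = rng.uniform(size=z.shape)
    # P(X >= k+1 | theta) = expit(z + d_k); code = number of exceeded boundaries
    codes = np.zeros(z.shape, dtype=np.int16)
    for k in range(intercepts.shape[1]):
        codes += (u < expit(z + intercepts[None, :, k])).astype(np.int16)
    return codes


def simulate_responses(
    params: TrueParameters,
    n: int,
    seed: int = 0,
) -> SimulatedDataset:
    """Draw ``n`` respondents from the generating graded response model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng_trait, rng_resp, rng_crit = child_generators(seed, 3)
    ndim = params.n_dims
    chol = np.linalg.cholesky(params.trait_correlations)
    traits = rng_trait.standard_normal((n, ndim)) @ chol.T
    codes = _draw_responses(params.slopes, params.intercepts, traits, rng_resp)
    responses = ResponseMatrix(
        codes,
        params.item_ids or [f"Q{j + 1:02d}" for j in range(params.n_items)],
        params.n_categories,
    )
    cfg = SimulationConfig()
    neg, pos = simulate_criterion_scores(
        traits, np.ones(ndim), cfg.criterion_noise_sd, rng=rng_crit
    )
    return SimulatedDataset(
        responses=responses,
        true_traits=traits,
        criterion_neg=neg,
        criterion_pos=pos,
        seed=seed,
        true_params=params,
        complete=responses.copy(),
    )


def inject_missing(data: SimulatedDataset, rate: float, seed: int = 0) -> SimulatedDataset:
    """Delete entries completely at random with per-entry probability ``rate``.

    The pre-deletion responses are retained on ``complete`` so imputation
    accuracy can be scored against the ground truth.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return data
    (rng,) = child_generators(seed, 1)
    rm = data.responses
    mask = rng.uniform(size=rm.codes.shape) < rate
    codes = rm.codes.copy()
    codes[mask] = MISSING
    new_rm = ResponseMatrix(codes, rm.item_ids, rm.n_categories)
    keep = data.complete if data.complete is not None else rm.copy()
    return replace(data, responses=new_rm, complete=keep)


def simulate_criterion_scores(
    traits: np.ndarray,
    loadings: np.ndarray,
    noise_sd: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two external criterion scores: ``-w . traits + e`` and ``+w . traits + e``.

    With the default weights and noise the absolute correlations with the
    trait sum land in the conventional medium/strong bands.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if rng is None:
        (rng,) = child_generators(seed or 0, 1)
    signal = traits @ np.asarray(loadings, float)
    n = traits.shape[0]
    neg = -signal + rng.standard_normal(n) * noise_sd
    pos = signal + rng.standard_normal(n) * noise_sd
    return neg, pos


_MISFIT_MODES = ("category_swap", "nonmonotone", "shuffle")


def plant_misfit_items(
    data: SimulatedDataset,
    item_ids: list[str],
    mode: str = "category_swap",
    seed: int = 0,
) -> SimulatedDataset:
    """Regenerate chosen items from a deliberately non-GRM process.

    Modes
    -----
    ``category_swap``
        Redraw the item from its generating GRM, then relabel categories
        2 and K-1 (a non-monotone category ordering no graded model can
        reproduce, while the extreme categories keep their association
        with the trait).
    ``nonmonotone``
        Redraw with the dominant trait replaced by ``theta**2 - 1``
        (a U-shaped item response function).
    ``shuffle``
        Permute the item's column: the marginal distribution is preserved
        but all association with the traits is destroyed.
    """
    if not item_ids:
        raise ValueError("item_ids must be a nonempty subset of the instrument")
    if mode not in _MISFIT_MODES:
        raise ValueError(f"unknown misfit mode {mode!r}; choose from {_MISFIT_MODES}")
    if data.true_params is None and mode != "shuffle":
        raise ValueError("planting requires the generating parameters")
    rm = data.responses
    unknown = [i for i in item_ids if i not in rm.item_ids]
    if unknown:
        raise ValueError(f"items not in instrument: {unknown}")
    (rng,) = child_generators(seed, 1)
    codes = rm.codes.copy()
    params = data.true_params

    for item in item_ids:
        j = rm.item_ids.index(item)
        k = rm.n_categories[j]
        if mode == "shuffle":
            codes[:, j] = rng.permutation(codes[:, j])
            continue
        a = params.slopes[j]
        d = params.intercepts[j][None, :]
        if mode == "nonmonotone":
            dom = int(np.argmax(np.abs(a)))
            theta = data.true_traits.copy()
            theta[:, dom] = theta[:, dom] ** 2 - 1.0
            z = theta @ a
        else:  # category_swap
            z = data.true_traits @ a
        u = rng.uniform(size=z.shape)
        new = np.zeros(z.shape, dtype=np.int16)
        for kk in range(d.shape[1]):
            new += (u < expit(z + d[:, kk])).astype(np.int16)
        if mode == "category_swap" and k >= 4:
            swapped = new.copy()
            swapped[new == 1] = k - 2
            swapped[new == k - 2] = 1
            new = swapped
        codes[:, j] = new

    new_rm = ResponseMatrix(codes, rm.item_ids, rm.n_categories)
    planted = sorted(set(data.planted_items) | set(item_ids))
    return replace(data, responses=new_rm, complete=new_rm.copy(), planted_items=planted)
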