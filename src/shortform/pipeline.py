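"""End-to-end short-form derivation and validation study.

Stages, in order: simulate (or accept) a 500-respondent ordinal dataset;
EM-impute missing entries; split into calibration and validation halves
(250/250); on the calibration half select the trait dimensionality by
information criteria, derive the item-fit-based short form by stepwise
S-chi-square removal and the GA-based short form by the cost sweep; on
the validation half run the psychometric battery (WLS CFA, Cronbach's
alpha, test--retest ICC on a re-simulated retest subsample, floor/ceiling
feasibility, distribution screens, criterion correlations) for the full
form and both candidates; finally compare the candidates by counting
threshold flags (RMSEA breaks ties) and report the winner.

Every stage draws its randomness from a child stream of the single study
seed, so a config plus seed reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import psych
from .cfa import CFAModelSpec, CFAResult, fit_cfa
from .ga import GAConfig, GAResult, convergent_correlation, sweep_item_cost
from .grm import EstimationOptions, MIRTFit, select_dimension_count
from .impute import em_impute
from .instrument import InstrumentSpec, ResponseMatrix, default_instrument
from .itemfit import AbbreviationTrace, ItemFitOptions, stepwise_abbreviate
from .rng import child_generators, child_seeds
from .simulate import (
    SimulatedDataset,
    SimulationConfig,
    _draw_responses,
    generate_true_parameters,
    inject_missing,
    simulate_responses,
)


@dataclass
class PipelineConfig:
    n: int = 500
    split_sizes: tuple[int, int] = (250, 250)
    seed: int = 0
    missing_rate: float = 0.04
    alpha: float = 0.05
    dim_candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    dim_criterion: str = "BIC"
    estimation: EstimationOptions = field(default_factory=EstimationOptions)
    itemfit: ItemFitOptions = field(default_factory=ItemFitOptions)
    ga: GAConfig = field(default_factory=GAConfig)
    sweep_ks: tuple[int, ...] = (4, 8, 12, 16, 20, 24, 28, 32)
    retest_n: int = 30
    retest_stability_sd: float = 0.3
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if sum(self.split_sizes) > self.n:
            raise ValueError("split sizes must sum to at most n")
        if self.retest_n > min(self.split_sizes):
            raise ValueError("retest size must not exceed the validation half")

    def as_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        blob = json.dumps(self.as_dict(), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
# splitting
# ----------------------------------------------------------------------

def split_sample(
    n: int, sizes: tuple[int, int], seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint split of ``range(n)`` into two index sets."""
    if sizes[0] + sizes[1] > n or min(sizes) < 0:
        raise ValueError(f"cannot split {n} rows into {sizes}")
    (rng,) = child_generators(seed, 1)
    perm = rng.permutation(n)
    first = np.sort(perm[: sizes[0]])
    second = np.sort(perm[sizes[0] : sizes[0] + sizes[1]])
    return first, second


# ----------------------------------------------------------------------
# per-form validation
# ----------------------------------------------------------------------

@dataclass
class ValidationBlock:
    form: str
    items: list[str]
    cfa: CFAResult
    alphas: dict[str, float]
    iccs: dict[str, psych.ICCResult]
    score_report: pd.DataFrame
    criterion_table: pd.DataFrame
    corr_with_full_total: float

    def threshold_flags(self) -> dict[str, bool]:
        flags: dict[str, bool] = {}
        if self.cfa.fit is not None:
            for k, v in self.cfa.fit.thresholds_passed.items():
                flags[f"fit_{k}"] = v
        for scale, a in self.alphas.items():
            flags[f"alpha_{scale}"] = a >= psych.ALPHA_ACCEPTABLE
        for scale, icc in self.iccs.items():
            flags[f"icc_{scale}"] = icc.label in ("good", "excellent")
        for _, row in self.score_report.iterrows():
            flags[f"feasibility_{row['scale']}"] = bool(row["feasible"])
        return flags


def _retest_responses(
    dataset: SimulatedDataset,
    idx: np.ndarray,
    stability_sd: float,
    seed: int,
) -> ResponseMatrix:
    """Second administration: jittered traits pushed back through the GRM."""
    params = dataset.true_params
    if params is None:
        raise ValueError("retest simulation needs the generating parameters")
    rng_noise, rng_resp = child_generators(seed, 2)
    theta = dataset.true_traits[idx]
    theta2 = theta + stability_sd * rng_noise.standard_normal(theta.shape)
    codes = _draw_responses(params.slopes, params.intercepts, theta2, rng_resp)
    return ResponseMatrix(codes, dataset.responses.item_ids,
                          dataset.responses.n_categories)


def validate_form(
    form: str,
    items: list[str],
    valid_data: ResponseMatrix,
    instrument: InstrumentSpec,
    criteria: pd.DataFrame,
    full_total: np.ndarray,
    retest_pair: tuple[ResponseMatrix, ResponseMatrix] | None = None,
) -> ValidationBlock:
    sub_inst = instrument.subset(items)
    sub_data = valid_data.subset_items(items)

    spec = CFAModelSpec(factor_of={i: instrument.subscale_of[i] for i in items})
    cfa_res = fit_cfa(sub_data, spec)

    alphas: dict[str, float] = {}
    vals = sub_data.values
    ids = list(sub_data.item_ids)
    for s in sub_inst.subscales:
        cols = [ids.index(i) for i in sub_inst.items_of(s)]
        if len(cols) >= 2:
            alphas[s] = psych.cronbach_alpha(vals[:, cols])
    alphas["total"] = psych.cronbach_alpha(vals)

    scores = psych.scale_scores(sub_data, sub_inst)
    rows = []
    for scale in scores.columns:
        sc = scores[scale].to_numpy()
        floor, ceiling, feasible = psych.floor_ceiling(sc)
        skew, kurt, normal_ok = psych.distribution_screen(sc)
        rows.append({"scale": scale, "mean": float(np.nanmean(sc)),
                     "sd": float(np.nanstd(sc, ddof=1)), "floor_pct": floor,
                     "ceiling_pct": ceiling, "feasible": feasible,
                     "skewness": skew, "kurtosis": kurt, "normal": normal_ok})
    score_report = pd.DataFrame(rows)

    crit_table = psych.criterion_correlations(scores, criteria)
    corr_full = float(np.corrcoef(scores["total"], full_total)[0, 1])

    iccs: dict[str, psych.ICCResult] = {}
    if retest_pair is not None:
        t1 = psych.scale_scores(retest_pair[0].subset_items(items), sub_inst)
        t2 = psych.scale_scores(retest_pair[1].subset_items(items), sub_inst)
        for scale in t1.columns:
            iccs[scale] = psych.icc_test_retest(t1[scale], t2[scale])

    return ValidationBlock(form, list(items), cfa_res, alphas, iccs,
                           score_report, crit_table, corr_full)


# ----------------------------------------------------------------------
# comparison
# ----------------------------------------------------------------------

def compare_short_forms(
    block_a: ValidationBlock, block_b: ValidationBlock
) -> tuple[str, pd.DataFrame, str]:
    """Pick the candidate passing more threshold flags; RMSEA breaks ties."""
    fa, fb = block_a.threshold_flags(), block_b.threshold_flags()
    keys = sorted(set(fa) | set(fb))
    table = pd.DataFrame(
        {
            "flag": keys,
            block_a.form: [fa.get(k) for k in keys],
            block_b.form: [fb.get(k) for k in keys],
        }
    )
    na, nb = sum(bool(v) for v in fa.values()), sum(bool(v) for v in fb.values())
    if na != nb:
        winner = block_a.form if na > nb else block_b.form
        rationale = f"{winner} passes {max(na, nb)}/{len(keys)} flags vs {min(na, nb)}"
    else:
        ra = block_a.cfa.fit.rmsea if block_a.cfa.fit else float("inf")
        rb = block_b.cfa.fit.rmsea if block_b.cfa.fit else float("inf")
        winner = block_a.form if ra <= rb else block_b.form
        rationale = (f"flag counts tied at {na}; {winner} chosen on smaller "
                     f"RMSEA ({min(ra, rb):.4f} vs {max(ra, rb):.4f})")
    return winner, table, rationale


# ----------------------------------------------------------------------
# the study driver
# ----------------------------------------------------------------------

@dataclass
class StudyReport:
    config: PipelineConfig
    chosen_dims: int
    dim_table: pd.DataFrame
    mirt_trace: AbbreviationTrace
    mirt_items: list[str]
    ga_sweep: pd.DataFrame
    ga_items: list[str]
    ga_result: GAResult
    convergent: pd.DataFrame
    blocks: dict[str, ValidationBlock]
    chosen_form: str
    comparison_table: pd.DataFrame
    rationale: str
    calibration_idx: np.ndarray
    validation_idx: np.ndarray

    def to_json_dict(self) -> dict:
        def ser_block(b: ValidationBlock) -> dict:
            fit = b.cfa.fit
            return {
                "items": b.items,
                "estimator": b.cfa.estimator,
                "fit": None if fit is None else {
                    "chi2": round(fit.chi2, 6), "df": fit.df,
                    "chi2_over_df": round(fit.chi2_over_df, 6),
                    "rmsea": round(fit.rmsea, 6),
                    "rmsea_ci": [round(c, 6) for c in fit.rmsea_ci],
                    "srmr": round(fit.srmr, 6), "cfi": round(fit.cfi, 6),
                    "tli": round(fit.tli, 6),
                    "thresholds_passed": fit.thresholds_passed,
                },
                "alphas": {k: round(v, 6) for k, v in b.alphas.items()},
                "iccs": {k: {"icc": round(v.icc, 6), "ci": [round(v.ci_low, 6),
                         round(v.ci_high, 6)], "label": v.label}
                         for k, v in b.iccs.items()},
                "score_report": json.loads(
                    b.score_report.round(6).to_json(orient="records")
                ),
                "criterion_correlations": json.loads(
                    b.criterion_table.round(6).to_json(orient="records")
                ),
                "corr_with_full_total": round(b.corr_with_full_total, 6),
                "threshold_flags": b.threshold_flags(),
            }

        return {
            "provenance": {
                "seed": self.config.seed,
                "config_digest": self.config.digest(),
                "n": self.config.n,
                "split_sizes": list(self.config.split_sizes),
            },
            "dimension_selection": {
                "chosen": self.chosen_dims,
                "table": json.loads(self.dim_table.round(4).to_json(orient="index")),
            },
            "mirt_form": {
                "items": self.mirt_items,
                "n_items": len(self.mirt_items),
                "stopped_because": self.mirt_trace.stopped_because,
                "trace": json.loads(
                    self.mirt_trace.to_frame().round(6).to_json(orient="records")
                ),
            },
            "ga_form": {
                "items": self.ga_items,
                "n_items": len(self.ga_items),
                "best_cost": round(float(self.ga_result.best_cost), 6),
                "sweep": json.loads(self.ga_sweep.round(6).to_json(orient="records")),
                "convergent_correlations": json.loads(
                    self.convergent.round(6).to_json(orient="records")
                ),
            },
            "validation": {k: ser_block(b) for k, b in self.blocks.items()},
            "comparison": {
                "chosen_form": self.chosen_form,
                "rationale": self.rationale,
                "table": json.loads(self.comparison_table.to_json(orient="records")),
            },
        }

    def to_text(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2, sort_keys=True)


def run_full_pipeline(
    config: PipelineConfig,
    instrument: InstrumentSpec | None = None,
    dataset: SimulatedDataset | None = None,
) -> StudyReport:
    instrument = instrument or default_instrument()
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child_seeds(config.seed, 8)]
    (s_sim, s_miss, s_split, s_mirt, s_ga, s_retest, s_impute, _) = seeds

    if dataset is None:
        params = generate_true_parameters(instrument, config.simulation, seed=s_sim)
        dataset = simulate_responses(params, config.n, seed=s_sim)
        if config.missing_rate > 0:
            dataset = inject_missing(dataset, config.missing_rate, seed=s_miss)

    imputed = em_impute(dataset.responses, seed=s_impute)
    cal_idx, val_idx = split_sample(imputed.n, config.split_sizes, seed=s_split)
    calib = imputed.take_rows(cal_idx)
    valid = imputed.take_rows(val_idx)

    subscales = instrument.subscales
    start_dims = np.array(
        [subscales.index(instrument.subscale_of[i]) for i in instrument.item_ids]
    )

    chosen_d, dim_table, _fits = select_dimension_count(
        calib, list(config.dim_candidates), options=config.estimation,
        seed=s_mirt, criterion=config.dim_criterion, start_dims=start_dims,
    )

    trace = stepwise_abbreviate(
        calib, chosen_d, alpha=config.alpha, estimation=config.estimation,
        itemfit_options=config.itemfit, seed=s_mirt, instrument=instrument,
        start_dims=start_dims,
    )
    mirt_items = trace.final_items

    ga_cfg = replace(config.ga, seed=s_ga)
    sweep, ga_best = sweep_item_cost(
        calib, instrument, list(config.sweep_ks), config=ga_cfg
    )
    ga_items = ga_best.retained_items
    convergent = convergent_correlation(calib, valid, ga_best, instrument)

    criteria = pd.DataFrame(
        {
            "criterion_neg": dataset.criterion_neg[val_idx],
            "criterion_pos": dataset.criterion_pos[val_idx],
        }
    )
    full_scores = psych.scale_scores(valid, instrument)
    full_total = full_scores["total"].to_numpy()

    retest_pair = None
    if dataset.true_params is not None:
        (rng_pick,) = child_generators(s_retest, 1)
        pick = np.sort(rng_pick.choice(val_idx, size=config.retest_n, replace=False))
        retest1 = imputed.take_rows(pick)
        retest2 = _retest_responses(dataset, pick, config.retest_stability_sd,
                                    seed=s_retest)
        retest_pair = (retest1, retest2)

    blocks: dict[str, ValidationBlock] = {}
    blocks["full"] = validate_form(
        "full", list(instrument.item_ids), valid, instrument, criteria,
        full_total, retest_pair,
    )
    blocks["mirt"] = validate_form(
        "mirt", mirt_items, valid, instrument, criteria, full_total, retest_pair
    )
    blocks["ga"] = validate_form(
        "ga", ga_items, valid, instrument, criteria, full_total, retest_pair
    )

    chosen, table, rationale = compare_short_forms(blocks["mirt"], blocks["ga"])

    return StudyReport(
        config=config,
        chosen_dims=chosen_d,
        dim_table=dim_table,
        mirt_trace=trace,
        mirt_items=mirt_items,
        ga_sweep=sweep,
        ga_items=ga_items,
        ga_result=ga_best,
        convergent=convergent,
        blocks=blocks,
        chosen_form=chosen,
        comparison_table=table,
        rationale=rationale,
        calibration_idx=cal_idx,
        validation_idx=val_idx,
    )
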