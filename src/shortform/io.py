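"""Delimited-text and YAML input/output.

Responses travel as CSV with a header row of item ids, one row per
respondent and empty cells for missing entries; instruments and
simulation/pipeline settings as YAML; parameter tables, traces and sweep
tables as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .instrument import InstrumentSpec, ResponseMatrix


def write_responses(path, data: ResponseMatrix) -> None:
    data.to_dataframe().to_csv(path, index=False, na_rep="")


def read_responses(path, instrument: InstrumentSpec | None = None) -> ResponseMatrix:
    df = pd.read_csv(path)
    return ResponseMatrix.from_dataframe(df, instrument)


def write_instrument(path, spec: InstrumentSpec) -> None:
    doc = {
        "items": [
            {
                "id": i,
                "subscale": spec.subscale_of[i],
                "n_categories": int(spec.n_categories[i]),
            }
            for i in spec.item_ids
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_instrument(path) -> InstrumentSpec:
    doc = yaml.safe_load(Path(path).read_text())
    items = doc["items"]
    return InstrumentSpec(
        item_ids=tuple(it["id"] for it in items),
        subscale_of={it["id"]: it["subscale"] for it in items},
        n_categories={it["id"]: int(it.get("n_categories", 5)) for it in items},
    )


def write_true_parameters(path, params) -> None:
    rows = []
    for j, item in enumerate(params.item_ids):
        row = {"item": item}
        for q in range(params.n_dims):
            row[f"a{q + 1}"] = params.slopes[j, q]
        for k in range(params.intercepts.shape[1]):
            row[f"d{k + 1}"] = params.intercepts[j, k]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_criteria(path, neg: np.ndarray, pos: np.ndarray) -> None:
    pd.DataFrame({"criterion_neg": neg, "criterion_pos": pos}).to_csv(path, index=False)


def read_criteria(path) -> pd.DataFrame:
    return pd.read_csv(path)
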