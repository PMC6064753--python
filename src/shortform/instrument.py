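"""Instrument definitions and the ordinal response-matrix container.

An *instrument* is a fixed battery of Likert-type items partitioned into
subscales.  The default layout mirrors a 40-item postpartum quality-of-life
questionnaire with four subscales (physical functioning, child care,
psychological functioning, social support) of 8, 12, 8 and 12 items, each
answered on a 5-point scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SUBSCALES = (
    ("physical_functioning", 8),
    ("child_care", 12),
    ("psychological_functioning", 8),
    ("social_support", 12),
)

MISSING = -1  # internal code for a missing response


@dataclass(frozen=True)
class InstrumentSpec:
    """Item battery: identifiers, item -> subscale map and category counts.

    Parameters
    ----------
    item_ids:
        Ordered item identifiers.
    subscale_of:
        Map from item id to subscale label.  Every item must belong to
        exactly one subscale.
    n_categories:
        Number of ordered response categories per item (>= 2).
    response_anchors:
        Optional verbal anchors for the categories, reporting only.
    """

    item_ids: tuple[str, ...]
    subscale_of: dict[str, str]
    n_categories: dict[str, int] = field(default_factory=dict)
    response_anchors: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        missing = [i for i in self.item_ids if i not in self.subscale_of]
        if missing:
            raise ValueError(f"items without a subscale: {missing}")
        if not self.n_categories:
            object.__setattr__(
                self, "n_categories", {i: 5 for i in self.item_ids}
            )
        for item, k in self.n_categories.items():
            if k < 2:
                raise ValueError(f"item {item}: n_categories must be >= 2, got {k}")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def subscales(self) -> tuple[str, ...]:
        seen: list[str] = []
        for i in self.item_ids:
            s = self.subscale_of[i]
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def items_of(self, subscale: str) -> tuple[str, ...]:
        return tuple(i for i in self.item_ids if self.subscale_of[i] == subscale)

    def categories(self) -> np.ndarray:
        return np.array([self.n_categories[i] for i in self.item_ids])

    def subset(self, keep: list[str] | tuple[str, ...]) -> "InstrumentSpec":
        keep_set = set(keep)
        ids = tuple(i for i in self.item_ids if i in keep_set)
        return InstrumentSpec(
            item_ids=ids,
            subscale_of={i: self.subscale_of[i] for i in ids},
            n_categories={i: self.n_categories[i] for i in ids},
            response_anchors=self.response_anchors,
        )


def default_instrument(
    layout: tuple[tuple[str, int], ...] = DEFAULT_SUBSCALES,
    n_categories: int = 5,
    prefix: str = "Q",
) -> InstrumentSpec:
    """The standard 40-item, 4-subscale, 5-category instrument."""
    item_ids: list[str] = []
    subscale_of: dict[str, str] = {}
    idx = 1
    for label, count in layout:
        for _ in range(count):
            iid = f"{prefix}{idx:02d}"
            item_ids.append(iid)
            subscale_of[iid] = label
            idx += 1
    return InstrumentSpec(
        item_ids=tuple(item_ids),
        subscale_of=subscale_of,
        n_categories={i: n_categories for i in item_ids},
    )


class ResponseMatrix:
    """n x p ordinal response table with a missing mask.

    Responses are stored internally as zero-based integer codes (0..K-1)
    with ``-1`` marking a missing entry; the public ``values`` view uses
    the conventional 1..K coding with NaN for missing.
    """

    def __init__(self, codes: np.ndarray, item_ids, n_categories) -> None:
        codes = np.asarray(codes, dtype=np.int16)
        if codes.ndim != 2:
            raise ValueError("codes must be 2-D (respondents x items)")
        n_categories = np.asarray(n_categories, dtype=int)
        if codes.shape[1] != len(item_ids) or len(n_categories) != len(item_ids):
            raise ValueError("item_ids / n_categories length mismatch")
        bad = (codes < MISSING) | (codes >= n_categories[None, :])
        if bad.any():
            raise ValueError("response codes outside 0..K-1 / missing range")
        self.codes = codes
        self.item_ids = list(item_ids)
        self.n_categories = n_categories

    # -- constructors -------------------------------------------------
    @classmethod
    def from_values(cls, values: np.ndarray, item_ids, n_categories) -> "ResponseMatrix":
        """Build from 1..K float values with NaN as missing."""
        values = np.asarray(values, dtype=float)
        codes = np.where(np.isnan(values), MISSING, values - 1)
        return cls(codes.astype(np.int16), item_ids, n_categories)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, instrument: InstrumentSpec | None = None) -> "ResponseMatrix":
        if instrument is not None:
            df = df[list(instrument.item_ids)]
            ncat = instrument.categories()
        else:
            ncat = np.array([int(np.nanmax(df[c])) if df[c].notna().any() else 2 for c in df.columns])
        return cls.from_values(df.to_numpy(dtype=float), list(df.columns), ncat)

    # -- basic views --------------------------------------------------
    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def p(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    @property
    def values(self) -> np.ndarray:
        v = self.codes.astype(float) + 1.0
        v[self.missing_mask] = np.nan
        return v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.item_ids)

    # -- slicing ------------------------------------------------------
    def take_rows(self, idx: np.ndarray) -> "ResponseMatrix":
        return ResponseMatrix(self.codes[idx], self.item_ids, self.n_categories)

    def subset_items(self, keep) -> "ResponseMatrix":
        pos = [self.item_ids.index(i) for i in keep]
        return ResponseMatrix(
            self.codes[:, pos], [self.item_ids[j] for j in pos], self.n_categories[pos]
        )

    def complete_rows(self) -> "ResponseMatrix":
        ok = ~self.missing_mask.any(axis=1)
        return self.take_rows(np.nonzero(ok)[0])

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(self.codes.copy(), list(self.item_ids), self.n_categories.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"ResponseMatrix(n={self.n}, p={self.p})"
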