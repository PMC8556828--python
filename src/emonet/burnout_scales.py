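"""Scoring of the Maslach Burnout Inventory - General Survey (MBI-GS).

The MBI-GS has 16 items on a 0-7 Likert scale across three dimensions:
emotional exhaustion (5 items), depersonalization/cynicism (5 items) and
professional efficacy (6 items, keyed in the healthy direction and therefore
reverse-coded as 7 - item before aggregation).  Burnout severity is a
weighted combination of the three dimension means, rescaled to the
instrument's declared 0-6 range.

The weighting convention is configurable.  The default weights the
dimension means (0.4, 0.3, 0.3) — exhaustion is commonly up-weighted in
total-score formulas — and maps the weighted mean from the 0-7 item scale
onto 0-6 by multiplying by 6/7.  The weights and the range map are recorded
in every score so the convention is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

N_ITEMS = 16
ITEM_MIN, ITEM_MAX = 0, 7

#: 1-based item positions per dimension in the standard MBI-GS ordering.
DEFAULT_DIMENSIONS: dict[str, tuple[int, ...]] = {
    "exhaustion": (1, 2, 3, 4, 6),
    "depersonalization": (8, 9, 13, 14, 15),
    "professional_efficacy": (5, 7, 10, 11, 12, 16),
}

DEFAULT_WEIGHTS: tuple[float, float, float] = (0.4, 0.3, 0.3)
#: Affine map taking the weighted 0-7 dimension-mean scale to 0-6.
DEFAULT_RANGE_SCALE = 6.0 / 7.0


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class MbiResponse:
    """One subject's 16 MBI-GS item responses (raw, unreversed)."""

    subject_id: object
    items: tuple[int, ...]
    dimensions: Mapping[str, tuple[int, ...]] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dimensions is None:
            object.__setattr__(self, "dimensions", dict(DEFAULT_DIMENSIONS))
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if len(items) != N_ITEMS:
            raise ScoringError(f"expected {N_ITEMS} items, got {len(items)}")
        for i, v in enumerate(items, start=1):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ScoringError(f"item {i} missing for subject {self.subject_id} (no imputation)")
            if not ITEM_MIN <= v <= ITEM_MAX:
                raise ScoringError(f"item {i} value {v} outside [{ITEM_MIN}, {ITEM_MAX}]")
        idx = sorted(i for pos in self.dimensions.values() for i in pos)
        if idx != list(range(1, N_ITEMS + 1)):
            raise ScoringError("dimension map must partition items 1..16")
        sizes = sorted(len(v) for v in self.dimensions.values())
        if sizes != [5, 5, 6]:
            raise ScoringError("dimension sizes must be 5/5/6")


@dataclass
class BurnoutScore:
    subject_id: object
    exhaustion_mean: float
    depersonalization_mean: float
    efficacy_mean_reversed: float
    total: float
    weights: tuple[float, float, float]
    range_scale: float


def reverse_code(values: np.ndarray) -> np.ndarray:
    """Reverse a 0-7 keyed item: 7 - value (an involution)."""
    return ITEM_MAX - np.asarray(values, dtype=float)


def score_mbi(
    resp: MbiResponse,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    range_scale: float = DEFAULT_RANGE_SCALE,
) -> BurnoutScore:
    """Weighted MBI-GS total on the declared 0-6 range.

    ``total = range_scale * (w_EE*EE + w_DP*DP + w_PE*revPE) / sum(w)`` where
    the dimension values are item means and professional-efficacy items are
    reverse-coded first.
    """
    w = tuple(float(x) for x in weights)
    if len(w) != 3 or any(x <= 0 for x in w):
        raise ScoringError("weights must be three positive numbers")
    items = np.asarray(resp.items, dtype=float)
    dims = resp.dimensions
    ee = items[[i - 1 for i in dims["exhaustion"]]].mean()
    dp = items[[i - 1 for i in dims["depersonalization"]]].mean()
    pe_rev = reverse_code(items[[i - 1 for i in dims["professional_efficacy"]]]).mean()
    total = range_scale * (w[0] * ee + w[1] * dp + w[2] * pe_rev) / sum(w)
    return BurnoutScore(
        subject_id=resp.subject_id,
        exhaustion_mean=float(ee),
        depersonalization_mean=float(dp),
        efficacy_mean_reversed=float(pe_rev),
        total=float(total),
        weights=w,
        range_scale=float(range_scale),
    )


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha, the classical internal-consistency coefficient.

    ``alpha = k/(k-1) * (1 - sum(item variances) / variance(item sum))``
    with sample (n-1) variances.  Rows (subjects) containing missing cells
    are dropped.  Efficacy items must be passed already reverse-coded when
    scoring the MBI-GS total scale.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ScoringError("need a subjects x items matrix with >= 2 items")
    complete = ~np.isnan(X).any(axis=1)
    n_dropped = int((~complete).sum())
    X = X[complete]
    if n_dropped:
        import logging

        logging.getLogger(__name__).info("cronbach_alpha: dropped %d incomplete rows", n_dropped)
    if X.shape[0] < 3:
        raise ScoringError("need >= 3 complete subjects")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ScoringError("zero variance of the item sum; alpha undefined")
    item_vars = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_vars / total_var))
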