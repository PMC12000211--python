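"""Fixed-layout accuracy / response-time summary vectors.

The amortized networks never see raw trials; each simulated participant is
reduced to a deterministic vector of accuracy and RT statistics.  Two layouts
are used: a 15-slot single-condition layout (mean accuracy; minimum and mean
RT for correct and error responses; five RT quantiles at .1/.3/.5/.7/.9 for
each response type) and an 8-slots-per-condition design layout (mean
accuracy, mean correct/error RT, five quantiles of the correct-RT
distribution), which for the 12-condition application design gives 96 slots.

Quantiles use linear interpolation of order statistics (the type-7
convention).  Cells with no error (or no correct) trials have the missing
side copied from the other side and the vector flagged as imputed, keeping
the inputs finite without inventing a sentinel scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import DesignSpec

__all__ = [
    "SummaryVector",
    "rt_quantiles",
    "summarize_single_condition",
    "summarize_design",
    "QUANTILE_PROBS",
]

QUANTILE_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class SummaryVector:
    """Ordered summary statistics with a slot-naming layout."""

    values: np.ndarray
    layout: tuple[str, ...]
    imputed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.layout = tuple(self.layout)
        if self.values.shape != (len(self.layout),):
            raise ValueError("values and layout lengths differ")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.layout))


def rt_quantiles(rts, probs=QUANTILE_PROBS) -> np.ndarray:
    """Empirical RT quantiles by linear interpolation of order statistics."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("empty RT sample")
    probs = np.asarray(probs, dtype=float)
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError("probs must lie in (0, 1)")
    if np.any(np.diff(probs) < 0):
        raise ValueError("probs must be sorted")
    return np.quantile(rts, probs, method="linear")


def _split_rts(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    ok = ~trials["censored"].astype(bool) if "censored" in trials else np.ones(len(trials), bool)
    sub = trials[ok]
    rt_c = sub.loc[sub["correct"] == 1, "rt"].to_numpy(float)
    rt_e = sub.loc[sub["correct"] == 0, "rt"].to_numpy(float)
    return rt_c, rt_e


def _side_stats(rts: np.ndarray, with_min: bool) -> np.ndarray:
    stats = [rts.min(), rts.mean()] if with_min else [rts.mean()]
    return np.concatenate([stats, rt_quantiles(rts)])


def summarize_single_condition(trials: pd.DataFrame) -> SummaryVector:
    """15-slot summary of a single-condition trial table.

    Layout: mean accuracy; min RT (correct, error); mean RT (correct,
    error); five RT quantiles for correct then error responses.  The
    minimum RT helps the networks identify non-decision time.
    """
    rt_c, rt_e = _split_rts(trials)
    n = rt_c.size + rt_e.size
    if n == 0:
        raise ValueError("no uncensored trials to summarize")
    acc = rt_c.size / n
    imputed = rt_c.size == 0 or rt_e.size == 0
    stats_c = _side_stats(rt_c if rt_c.size else rt_e, with_min=True)
    stats_e = _side_stats(rt_e if rt_e.size else rt_c, with_min=True)
    values = np.concatenate(
        [[acc], [stats_c[0], stats_e[0]], [stats_c[1], stats_e[1]], stats_c[2:], stats_e[2:]]
    )
    layout = (
        ["accuracy", "min_rt_correct", "min_rt_error", "mean_rt_correct", "mean_rt_error"]
        + [f"q{int(p * 100)}_correct" for p in QUANTILE_PROBS]
        + [f"q{int(p * 100)}_error" for p in QUANTILE_PROBS]
    )
    return SummaryVector(values=values, layout=layout, imputed=imputed)


def summarize_design(trials: pd.DataFrame, design: DesignSpec) -> SummaryVector:
    """Per-condition 8-slot summaries, concatenated in canonical order.

    Each condition contributes mean accuracy, mean correct and error RT, and
    the five quantiles of its correct-RT distribution; the 12-condition
    application design therefore yields 96 slots.  Conditions follow the
    design's (coherence, match, discriminability) lexicographic order and
    the result is invariant to trial-row order.
    """
    values: list[float] = []
    layout: list[str] = []
    imputed = False
    for cond in design.conditions:
        label = DesignSpec.condition_label(cond)
        sub = trials[trials["condition"] == label]
        if len(sub) == 0:
            raise ValueError(f"condition {label} absent from trial table")
        rt_c, rt_e = _split_rts(sub)
        if rt_c.size + rt_e.size == 0:
            raise ValueError(f"condition {label} has no uncensored trials")
        if rt_c.size == 0 or rt_e.size == 0:
            imputed = True
        acc = rt_c.size / (rt_c.size + rt_e.size)
        base_c = rt_c if rt_c.size else rt_e
        base_e = rt_e if rt_e.size else rt_c
        values.extend([acc, base_c.mean(), base_e.mean()])
        values.extend(rt_quantiles(base_c))
        layout.extend(
            [f"{label}:accuracy", f"{label}:mean_rt_correct", f"{label}:mean_rt_error"]
            + [f"{label}:q{int(p * 100)}" for p in QUANTILE_PROBS]
        )
    return SummaryVector(values=np.array(values), layout=layout, imputed=imputed)
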