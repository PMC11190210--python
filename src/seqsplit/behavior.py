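"""Anticipatory licking metrics and the behavioral performance index."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import SessionData
from .task import TaskDesign

__all__ = [
    "anticipatory_lick_rate",
    "lick_latency",
    "performance_index",
    "BehaviorMetrics",
    "session_behavior_metrics",
]

ANTICIPATORY_WINDOW = (0.0, 7.0)


@dataclass(frozen=True)
class BehaviorMetrics:
    """Per-pair behavioral summary for one session."""

    pair: str
    lr_plus: float
    lr_minus: float
    pi: float  # NaN when both rates are zero (undefined, not 0)


def anticipatory_lick_rate(
    licks: pd.DataFrame,
    n_trials: int,
    window: tuple[float, float] = ANTICIPATORY_WINDOW,
) -> np.ndarray:
    """Lick events in the half-open window divided by its length, per trial."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive length")
    sel = licks[(licks["time_s"] >= lo) & (licks["time_s"] < hi)]
    counts = np.bincount(sel["trial"].to_numpy(dtype=np.int64), minlength=n_trials)
    if counts.size > n_trials:
        raise ValueError("lick trial index exceeds n_trials")
    return counts / (hi - lo)


def lick_latency(
    licks: pd.DataFrame,
    n_trials: int,
    window: tuple[float, float] = ANTICIPATORY_WINDOW,
) -> np.ndarray:
    """Time of first lick in the window per trial; NaN when no lick."""
    lo, hi = window
    out = np.full(n_trials, np.nan)
    sel = licks[(licks["time_s"] >= lo) & (licks["time_s"] < hi)]
    first = sel.groupby("trial")["time_s"].min()
    out[first.index.to_numpy(dtype=np.int64)] = first.to_numpy() - lo
    return out


def performance_index(lr_plus: float, lr_minus: float) -> float:
    """(LR+ - LR-) / (LR+ + LR-); NaN when both rates are zero."""
    if lr_plus < 0 or lr_minus < 0:
        raise ValueError("lick rates must be non-negative")
    total = lr_plus + lr_minus
    if total == 0:
        return math.nan
    return (lr_plus - lr_minus) / total


def session_behavior_metrics(
    session: SessionData, design: TaskDesign
) -> pd.DataFrame:
    """Tidy per-pair table: (mouse, day, pair, lr_plus, lr_minus, pi).

    LR(+) and LR(-) are trial-mean anticipatory lick rates over the pair's
    (+) and (-) trials in this session.
    """
    window = (0.0, design.outcome_s)
    rates = anticipatory_lick_rate(session.licks, session.n_trials, window)
    rows = []
    for pair, (plus, minus) in design.pair_members.items():
        lr_p = float(np.mean(rates[session.trials_of(plus)]))
        lr_m = float(np.mean(rates[session.trials_of(minus)]))
        rows.append(
            {
                "mouse": session.mouse_id,
                "day": session.day,
                "pair": pair,
                "lr_plus": lr_p,
                "lr_minus": lr_m,
                "pi": performance_index(lr_p, lr_m),
            }
        )
    return pd.DataFrame(rows)
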