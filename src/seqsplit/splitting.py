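"""Sequence-splitting neuron detection and splitting-strength quantification.

A splitting neuron responds differently to the two members of a sequence
pair during an epoch in which external input is identical (shared second
odor, delay, or reward).  Detection is a two-sided Wilcoxon rank-sum test
on per-trial epoch-mean rates at alpha = 0.01; splitting strength is the
discrimination index DI = |AUC - 0.5| * 2, with AUC the midrank ROC area
between the two trial-wise rate distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import SessionData
from .task import BinGrid, TaskDesign, epoch_bins, epoch_samples

__all__ = [
    "SplittingResult",
    "OverlapReport",
    "rank_sum_pvalues",
    "auc_many",
    "discrimination_index",
    "identify_splitting_neurons",
    "splitting_fraction_timecourse",
    "lick_correlation_screen",
    "overlap_fraction",
    "track_across_days",
    "di_ks_test",
    "fraction_day_trend",
]


@dataclass
class SplittingResult:
    pair: str
    epoch: str
    mean_plus: np.ndarray  # per-neuron epoch-mean rate, first pair member
    mean_minus: np.ndarray
    p_value: np.ndarray
    auc: np.ndarray
    di: np.ndarray
    is_splitting: np.ndarray  # bool, p < alpha
    alpha: float = 0.01
    denominator_policy: str = "all_imaged"

    @property
    def fraction(self) -> float:
        return float(np.mean(self.is_splitting))

    @property
    def splitting_ids(self) -> set[int]:
        return set(np.nonzero(self.is_splitting)[0].tolist())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron": np.arange(self.p_value.size),
                "pair": self.pair,
                "epoch": self.epoch,
                "p": self.p_value,
                "auc": self.auc,
                "di": self.di,
                "is_splitting": self.is_splitting,
            }
        )


@dataclass(frozen=True)
class OverlapReport:
    set_a: frozenset
    set_b: frozenset
    n_intersection: int = field(init=False)
    n_union: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_intersection", len(self.set_a & self.set_b))
        object.__setattr__(self, "n_union", len(self.set_a | self.set_b))

    @property
    def overlap_fraction(self) -> float:
        if self.n_union == 0:
            return float("nan")
        return self.n_intersection / self.n_union

    @property
    def venn(self) -> tuple[int, int, int]:
        return (
            len(self.set_a - self.set_b),
            self.n_intersection,
            len(self.set_b - self.set_a),
        )


def rank_sum_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per row of (n, trials_a) vs (n, trials_b).

    Exact null distribution for tie-free samples up to 64 trials per
    group, midrank tie correction with the normal approximation
    otherwise; all-tied rows get p = 1 (never flagged).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("a and b must have the same number of rows")
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = bool(
        np.any(np.diff(np.sort(np.concatenate([a, b], axis=1), axis=1), axis=1) == 0)
    )
    # exact null distribution when tie-free and affordable; midrank-corrected
    # normal approximation otherwise (the asymptotic test is slightly
    # conservative, so exact is preferred for calibration)
    exact_ok = not has_ties and max(a.shape[1], b.shape[1]) <= 64
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, axis=1, alternative="two-sided", method=method,
        use_continuity=False,
    )
    p = np.asarray(res.pvalue, dtype=float)
    # mannwhitneyu yields NaN when every value in a row is tied
    tied = np.isnan(p)
    if np.any(tied):
        p = np.where(tied, 1.0, p)
    return p


def auc_many(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Midrank ROC AUC per row: P(a > b) + 0.5 P(a = b) over cross-pairs."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a == 0 or n_b == 0:
        raise ValueError("both samples must be non-empty")
    both = np.concatenate([a, b], axis=1)
    ranks = stats.rankdata(both, axis=1)
    r_a = ranks[:, :n_a].sum(axis=1)
    u = r_a - n_a * (n_a + 1) / 2.0
    return u / (n_a * n_b)


def discrimination_index(rates_a: np.ndarray, rates_b: np.ndarray) -> tuple[float, float]:
    """(AUC, DI) for one neuron's per-trial rates in the two conditions."""
    auc = float(auc_many(np.asarray(rates_a)[None, :], np.asarray(rates_b)[None, :])[0])
    return auc, abs(auc - 0.5) * 2.0


def _pair_members(design: TaskDesign, pair: str) -> tuple[str, str]:
    if pair in design.pair_members:
        return design.pair_members[pair]
    if pair in design.reward_pairs:
        return design.reward_pairs[pair]
    raise KeyError(f"unknown pair: {pair!r}")


def epoch_trial_means(
    session: SessionData, epoch: str, design: TaskDesign | None = None
) -> np.ndarray:
    """(n_neurons, n_trials) mean rate over the epoch's raw samples."""
    samp = epoch_samples(epoch, session.grid, design)
    if samp.size == 0:
        raise ValueError(f"epoch {epoch!r} contains no samples")
    return session.rates[:, :, samp].mean(axis=2)


def identify_splitting_neurons(
    session: SessionData,
    design: TaskDesign,
    pair: str,
    epoch: str = "overlap",
    alpha: float = 0.01,
) -> SplittingResult:
    """Rank-sum test on epoch-average activity between the pair's members."""
    m_plus, m_minus = _pair_members(design, pair)
    idx_p = session.trials_of(m_plus)
    idx_m = session.trials_of(m_minus)
    if idx_p.size < 2 or idx_m.size < 2:
        raise ValueError(f"pair {pair!r} needs >= 2 trials per member")
    means = epoch_trial_means(session, epoch, design)
    a, b = means[:, idx_p], means[:, idx_m]
    p = rank_sum_pvalues(a, b)
    auc = auc_many(a, b)
    return SplittingResult(
        pair=pair,
        epoch=epoch,
        mean_plus=a.mean(axis=1),
        mean_minus=b.mean(axis=1),
        p_value=p,
        auc=auc,
        di=np.abs(auc - 0.5) * 2.0,
        is_splitting=p < alpha,
        alpha=alpha,
    )


def splitting_fraction_timecourse(
    session: SessionData,
    design: TaskDesign,
    pair: str,
    alpha: float = 0.01,
) -> np.ndarray:
    """Fraction of neurons with p < alpha per 1-s analysis bin.

    Denominator is all neurons in the session.
    """
    m_plus, m_minus = _pair_members(design, pair)
    idx_p = session.trials_of(m_plus)
    idx_m = session.trials_of(m_minus)
    if idx_p.size < 2 or idx_m.size < 2:
        raise ValueError(f"pair {pair!r} needs >= 2 trials per member")
    grid = session.grid
    out = np.empty(grid.n_bins)
    for b in range(grid.n_bins):
        samp = grid.bin_samples(b)
        binned = session.rates[:, :, samp].mean(axis=2)
        p = rank_sum_pvalues(binned[:, idx_p], binned[:, idx_m])
        out[b] = np.mean(p < alpha)
    return out


def lick_correlation_screen(
    rates: np.ndarray,
    lick_metric: np.ndarray,
    alpha: float = 0.01,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Pearson screen of per-trial neuron rates against a lick metric.

    ``rates`` is (n_neurons, n_trials); ``lick_metric`` is per-trial lick
    rate or latency (NaN entries dropped pairwise).  Returns
    (flagged fraction, flags, r, p); neurons with undefined correlation
    (zero variance) are excluded from numerator and denominator, and the
    fraction is NaN when no neuron has a defined correlation.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    metric = np.asarray(lick_metric, dtype=float)
    ok = ~np.isnan(metric)
    if ok.sum() < 3:
        raise ValueError("need >= 3 trials with a defined lick metric")
    x = rates[:, ok]
    y = metric[ok]
    n = y.size
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    xc = x - x.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    denom = sx * sy
    valid = denom > 0
    r = np.full(rates.shape[0], np.nan)
    p = np.full(rates.shape[0], np.nan)
    if sy > 0:
        r[valid] = (xc[valid] @ yc) / denom[valid]
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = r[valid] * np.sqrt((n - 2) / np.maximum(1.0 - r[valid] ** 2, 1e-300))
        p[valid] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    else:
        valid = np.zeros(rates.shape[0], dtype=bool)
    flags = (p < alpha) & valid
    n_valid = int(valid.sum())
    frac = float(flags.sum() / n_valid) if n_valid else float("nan")
    return frac, flags, r, p


def overlap_fraction(set_a, set_b) -> OverlapReport:
    """|A ∩ B| / |A ∪ B| with Venn counts; undefined for two empty sets."""
    return OverlapReport(frozenset(set_a), frozenset(set_b))


def _to_global(ids, reg: dict, day: int) -> set:
    out = set()
    for i in ids:
        key = (day, i)
        if key not in reg:
            raise KeyError(f"neuron id {i!r} on day {day} not in registration")
        out.add(reg[key])
    return out


def track_across_days(
    registration: pd.DataFrame,
    sets_by_day: dict[int, dict[str, set]],
) -> pd.DataFrame:
    """Across-day overlap and conversion fractions on registered neurons.

    ``registration`` has columns (day, local_id, global_id); ``sets_by_day``
    maps day -> {splitting type -> set of local neuron ids}.  For each
    consecutive day pair and type: the overlap fraction of the two sets in
    global coordinates, and for each ordered type pair (src, dst) the
    conversion fraction = share of day-t src-splitting neurons that are
    dst-splitting on day t+1 (NaN when the source set is empty).
    """
    reg = {
        (int(d), int(l)): g
        for d, l, g in zip(
            registration["day"], registration["local_id"], registration["global_id"]
        )
    }
    days = sorted(sets_by_day)
    rows = []
    for d0, d1 in zip(days[:-1], days[1:]):
        types0, types1 = sets_by_day[d0], sets_by_day[d1]
        glob0 = {t: _to_global(s, reg, d0) for t, s in types0.items()}
        glob1 = {t: _to_global(s, reg, d1) for t, s in types1.items()}
        for t in sorted(set(glob0) & set(glob1)):
            rep = overlap_fraction(glob0[t], glob1[t])
            rows.append(
                {
                    "day_from": d0, "day_to": d1, "kind": "overlap",
                    "src_type": t, "dst_type": t,
                    "value": rep.overlap_fraction,
                }
            )
        for t_src in sorted(glob0):
            for t_dst in sorted(glob1):
                if t_src == t_dst:
                    continue
                src = glob0[t_src]
                conv = len(src & glob1[t_dst]) / len(src) if src else float("nan")
                rows.append(
                    {
                        "day_from": d0, "day_to": d1, "kind": "conversion",
                        "src_type": t_src, "dst_type": t_dst, "value": conv,
                    }
                )
    return pd.DataFrame(rows)


def di_ks_test(di_x: np.ndarray, di_y: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic and p on DI distributions."""
    di_x, di_y = np.asarray(di_x), np.asarray(di_y)
    if di_x.size < 2 or di_y.size < 2:
        raise ValueError("need >= 2 DI values per group")
    res = stats.ks_2samp(di_x, di_y)
    return float(res.statistic), float(res.pvalue)


def fraction_day_trend(days: np.ndarray, fractions: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation of per-day splitting fractions vs day."""
    days, fractions = np.asarray(days), np.asarray(fractions)
    if days.size < 2:
        raise ValueError("need >= 2 days")
    rho, p = stats.spearmanr(days, fractions)
    return float(rho), float(p)
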