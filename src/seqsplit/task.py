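"""Task structure: problems, sequence pairs, trial types, epochs, binning.

Two odor-outcome association problems, four trial types each.  Within a
problem, type ``a`` sequences present a first odor at t=0 s and a shared
second odor at t=4 s; type ``b`` sequences present a single odor at t=0 s
followed by a shared delay.  The outcome ((+) sucrose / (-) nothing)
arrives at t=7 s.  Paired sequences are externally indistinguishable during
the overlap epoch [4, 7) s, which is where splitting signals live.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "TaskDesign",
    "BinGrid",
    "EPOCHS",
    "build_task_design",
    "epoch_bins",
    "make_trial_schedule",
]

#: Half-open epoch windows in seconds from first-odor onset.
EPOCHS: dict[str, tuple[float, float]] = {
    "overlap": (4.0, 7.0),
    "reward": (7.0, 10.0),
    "anticipatory": (0.0, 7.0),
}

#: Canonical pair order: index 1..4.
PAIR_ORDER: tuple[str, ...] = ("1a", "2a", "1b", "2b")


@dataclass(frozen=True)
class TaskDesign:
    """Full description of one session's task structure.

    ``pair_members`` maps a pair id (e.g. ``"1a"``) to its (+) and (-)
    trial types; ``reward_pairs`` maps cross-pair reward comparisons
    (two rewarded types sharing the same outcome) analysed in [7, 10) s.
    """

    problems: tuple[int, ...]
    trial_types: tuple[str, ...]
    pair_index: dict[str, int]
    pair_type: dict[str, str]
    pair_members: dict[str, tuple[str, str]]
    reward_pairs: dict[str, tuple[str, str]]
    trials_per_type: int
    odor_s: float = 1.0
    second_odor_onset_s: float = 4.0
    outcome_s: float = 7.0
    window_s: tuple[float, float] = (0.0, 10.0)
    epochs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(EPOCHS)
    )
    iti_range: tuple[float, float] = (15.0, 25.0)

    @property
    def n_trials(self) -> int:
        return len(self.trial_types) * self.trials_per_type

    def pair_of(self, trial_type: str) -> str:
        return trial_type[:-1]

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TaskDesign":
        d = json.loads(text)
        for key in ("problems", "trial_types", "window_s", "iti_range"):
            d[key] = tuple(d[key])
        d["pair_members"] = {k: tuple(v) for k, v in d["pair_members"].items()}
        d["reward_pairs"] = {k: tuple(v) for k, v in d["reward_pairs"].items()}
        d["epochs"] = {k: tuple(v) for k, v in d["epochs"].items()}
        return cls(**d)


@dataclass(frozen=True)
class BinGrid:
    """Sampling and analysis-bin conventions on the trial window."""

    rate_hz: float = 10.0
    bin_s: float = 1.0
    window_s: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        length = self.window_s[1] - self.window_s[0]
        if length <= 0:
            raise ValueError("window must have positive length")
        if abs(length / self.bin_s - round(length / self.bin_s)) > 1e-9:
            raise ValueError("bin_s must divide the analysis window")

    @property
    def n_samples(self) -> int:
        return int(round((self.window_s[1] - self.window_s[0]) * self.rate_hz))

    @property
    def n_bins(self) -> int:
        return int(round((self.window_s[1] - self.window_s[0]) / self.bin_s))

    @property
    def sample_times(self) -> np.ndarray:
        """Centres of raw samples, seconds."""
        dt = 1.0 / self.rate_hz
        return self.window_s[0] + dt * (np.arange(self.n_samples) + 0.5)

    @property
    def bin_times(self) -> np.ndarray:
        """Centres of analysis bins, seconds."""
        return self.window_s[0] + self.bin_s * (np.arange(self.n_bins) + 0.5)

    def window_samples(self, start: float, stop: float) -> np.ndarray:
        """Raw-sample indices whose interval lies inside [start, stop)."""
        dt = 1.0 / self.rate_hz
        lo = self.window_s[0] + dt * np.arange(self.n_samples)
        hi = lo + dt
        eps = 1e-9
        return np.nonzero((lo >= start - eps) & (hi <= stop + eps))[0]

    def bin_samples(self, b: int) -> np.ndarray:
        start = self.window_s[0] + b * self.bin_s
        return self.window_samples(start, start + self.bin_s)


def build_task_design(
    problem_set: set[int] | frozenset[int],
    trials_per_type: int = 40,
    iti_range: tuple[float, float] = (15.0, 25.0),
) -> TaskDesign:
    """Build the design covering the requested problems.

    Each problem contributes four trial types {pa+, pa-, pb+, pb-}; pairs
    are indexed 1: 1a, 2: 2a, 3: 1b, 4: 2b.
    """
    problems = tuple(sorted(problem_set))
    for p in problems:
        if p not in (1, 2):
            raise ValueError(f"unknown problem id: {p!r} (must be 1 or 2)")
    if not problems:
        raise ValueError("problem_set must be non-empty")
    if trials_per_type < 2:
        raise ValueError("trials_per_type must be >= 2")

    trial_types = tuple(
        f"{p}{s}{o}" for p in problems for s in ("a", "b") for o in ("+", "-")
    )
    # canonical pair order (1a, 2a, 1b, 2b) so similarity matrices line up
    # with the model's pair indexing
    pairs = [pid for pid in PAIR_ORDER if int(pid[0]) in problems]
    pair_index = {pid: PAIR_ORDER.index(pid) + 1 for pid in pairs}
    pair_type = {pid: pid[-1] for pid in pairs}
    pair_members = {pid: (f"{pid}+", f"{pid}-") for pid in pairs}
    reward_pairs = {f"{p}+": (f"{p}a+", f"{p}b+") for p in problems}

    return TaskDesign(
        problems=problems,
        trial_types=trial_types,
        pair_index=pair_index,
        pair_type=pair_type,
        pair_members=pair_members,
        reward_pairs=reward_pairs,
        trials_per_type=trials_per_type,
        iti_range=tuple(iti_range),
    )


def epoch_bins(epoch_name: str, grid: BinGrid, design: TaskDesign | None = None) -> np.ndarray:
    """0-based analysis-bin indices fully inside the named epoch window."""
    epochs = design.epochs if design is not None else EPOCHS
    if epoch_name not in epochs:
        raise KeyError(f"unknown epoch: {epoch_name!r}; known: {sorted(epochs)}")
    start, stop = epochs[epoch_name]
    lo = grid.window_s[0] + grid.bin_s * np.arange(grid.n_bins)
    hi = lo + grid.bin_s
    eps = 1e-9
    return np.nonzero((lo >= start - eps) & (hi <= stop + eps))[0]


def epoch_samples(epoch_name: str, grid: BinGrid, design: TaskDesign | None = None) -> np.ndarray:
    """Raw-sample indices fully inside the named epoch window."""
    epochs = design.epochs if design is not None else EPOCHS
    if epoch_name not in epochs:
        raise KeyError(f"unknown epoch: {epoch_name!r}; known: {sorted(epochs)}")
    start, stop = epochs[epoch_name]
    return grid.window_samples(start, stop)


def make_trial_schedule(
    design: TaskDesign, seed: int
) -> tuple[list[str], np.ndarray]:
    """Pseudo-random trial order plus per-trial ITIs.

    A seeded uniform shuffle of the multiset of trial types; ITIs drawn
    uniformly from ``design.iti_range``.  No run-length constraint is
    imposed.
    """
    rng = np.random.default_rng(seed)
    types = np.repeat(np.array(design.trial_types, dtype=object), design.trials_per_type)
    rng.shuffle(types)
    itis = rng.uniform(design.iti_range[0], design.iti_range[1], size=types.size)
    return list(types), itis
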