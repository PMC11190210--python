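"""Synthetic sessions with known latent structure.

The pair-discriminating component of each simulated population is a
weighted mixture of four latent directions per sequence pair — past cue
(a_i), current cue (b_i), sequence structure (t_i) and expected outcome
(o_i) — so every downstream analysis stage can be validated against
ground truth without any external data.

Correlation structure of the basis: a_1..a_4, b_1, b_2 mutually
uncorrelated; b_3 = b_4 = 0 (pure delay); t_1 = t_2 and t_3 = t_4
(shared sequence structure within type); o_1 = .. = o_4 (shared outcome).
Nine distinct underlying directions in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import BinGrid, TaskDesign, epoch_samples, make_trial_schedule

__all__ = [
    "BasisSpec",
    "BasisSet",
    "GroundTruth",
    "SessionData",
    "generate_basis",
    "compose_splitting_vectors",
    "simulate_session",
    "simulate_licks",
]

#: pair type per pair index 1..4 (1a, 2a, 1b, 2b)
PAIR_TYPES: tuple[str, ...] = ("a", "a", "b", "b")
N_DISTINCT = 9  # a1..a4, b1, b2, t_a, t_b, o


@dataclass(frozen=True)
class BasisSpec:
    """How to draw the latent basis."""

    n_neurons: int = 100
    mode: str = "approx"  # or "exact-orthogonal"

    def __post_init__(self) -> None:
        if self.mode not in ("approx", "exact-orthogonal"):
            raise ValueError(f"unknown basis mode: {self.mode!r}")
        if self.mode == "exact-orthogonal" and self.n_neurons < N_DISTINCT:
            raise ValueError(
                f"exact-orthogonal mode needs n_neurons >= {N_DISTINCT} "
                f"(got {self.n_neurons})"
            )
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be positive")


@dataclass(frozen=True)
class BasisSet:
    """Latent component vectors per pair: rows i=1..4 of a, b, t, o."""

    a: np.ndarray  # (4, n)
    b: np.ndarray  # (4, n); rows 2 and 3 are zero
    t: np.ndarray  # (4, n); t[0] is t[1], t[2] is t[3]
    o: np.ndarray  # (4, n); all rows identical
    spec: BasisSpec
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.a.shape[1]


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters for one simulated population."""

    weights: "np.ndarray | tuple[float, float, float, float]"
    signal_amplitude: float = 1.0
    baseline_rate: float = 2.0
    noise_sd: float = 0.5
    cue_response_amplitude: float = 0.5
    outcome_amplitude: float | None = None  # defaults to signal_amplitude
    noise_model: str = "gaussian"  # or "poisson"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,):
            raise ValueError("weights must have 4 entries (alpha,beta,gamma,delta)")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        if not np.any(w > 0):
            raise ValueError("weights must not all be zero")
        for name in ("signal_amplitude", "baseline_rate", "noise_sd",
                     "cue_response_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.outcome_amplitude is not None and self.outcome_amplitude < 0:
            raise ValueError("outcome_amplitude must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model: {self.noise_model!r}")

    @property
    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    @property
    def outcome_amp(self) -> float:
        return (self.signal_amplitude if self.outcome_amplitude is None
                else self.outcome_amplitude)


@dataclass
class SessionData:
    """One session: labeled rate tensor plus lick events.

    ``rates`` is (n_neurons, n_trials, n_samples) at ``grid.rate_hz``,
    non-negative.  ``licks`` is a DataFrame with columns (trial, time_s).
    """

    rates: np.ndarray
    trial_type: np.ndarray  # (n_trials,) of str
    licks: pd.DataFrame
    grid: BinGrid = field(default_factory=BinGrid)
    day: int = 1
    mouse_id: str = "sim"
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_trials(self) -> int:
        return self.rates.shape[1]

    def trials_of(self, trial_type: str) -> np.ndarray:
        return np.nonzero(self.trial_type == trial_type)[0]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        return v
    return v / n


def generate_basis(spec: BasisSpec, seed: int | None = None,
                   rng: np.random.Generator | None = None) -> BasisSet:
    """Draw the nine distinct latent directions and assemble the basis.

    ``approx`` mode: independent standard-normal draws scaled to unit
    norm (pairwise overlaps are O(1/sqrt(n)), as in the published
    construction).  ``exact-orthogonal`` mode: the same draws followed by
    Gram-Schmidt, giving exactly orthonormal distinct directions.
    Equality constraints (shared t within type, shared o) are enforced by
    reusing the same vector object.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = spec.n_neurons
    raw = rng.standard_normal((N_DISTINCT, n))
    if spec.mode == "exact-orthogonal":
        # Gram-Schmidt across the distinct directions
        q = np.zeros_like(raw)
        for k in range(N_DISTINCT):
            v = raw[k].copy()
            for j in range(k):
                v -= (v @ q[j]) * q[j]
            q[k] = _unit(v)
        raw = q
    else:
        raw = raw / np.linalg.norm(raw, axis=1, keepdims=True)

    a1, a2, a3, a4, b1, b2, t_a, t_b, o = raw
    zero = np.zeros(n)
    return BasisSet(
        a=np.stack([a1, a2, a3, a4]),
        b=np.stack([b1, b2, zero, zero]),
        t=np.stack([t_a, t_a, t_b, t_b]),
        o=np.stack([o, o, o, o]),
        spec=spec,
        seed=seed,
    )


def compose_splitting_vectors(basis: BasisSet,
                              weights: np.ndarray | tuple) -> np.ndarray:
    """s_i = alpha*a_i + beta*b_i + gamma*t_i + delta*o_i, rows i=1..4.

    The weight vector is L2-normalized before composition, so type-a
    splitting vectors have unit norm under an exactly orthonormal basis
    (type-b vectors are shorter because b_3 = b_4 = 0).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,):
        raise ValueError("weights must have 4 entries")
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("weights must not all be zero")
    w = w / norm
    return (w[0] * basis.a + w[1] * basis.b + w[2] * basis.t + w[3] * basis.o)


def simulate_session(
    design: TaskDesign,
    truth: GroundTruth,
    n_trials_per_type: int | None = None,
    seed: int = 0,
    basis: BasisSet | None = None,
    spec: BasisSpec | None = None,
    grid: BinGrid | None = None,
    learning_level: float = 0.8,
    profile: str = "sustained",
    day: int = 1,
    mouse_id: str = "sim",
) -> SessionData:
    """Simulate one session's rate tensor and lick events.

    During the overlap epoch the (+) member of pair i receives
    ``+signal_amplitude/2 * s_i`` per neuron and the (-) member
    ``-signal_amplitude/2 * s_i``; both members share non-discriminative
    cue responses at odor onsets; (+) trials add an outcome response
    along the shared outcome direction during the reward epoch.  Noise is
    added per raw sample and rates are rectified at zero.
    """
    if profile not in ("sustained", "ramp"):
        raise ValueError(f"unknown profile: {profile!r}")
    grid = grid or BinGrid()
    spec = spec or BasisSpec()
    ss = np.random.SeedSequence(seed)
    s_basis, s_cue, s_noise, s_sched, s_lick = ss.spawn(5)
    if basis is None:
        basis = generate_basis(spec, rng=np.random.default_rng(s_basis))
    n = basis.n_neurons

    if n_trials_per_type is not None and n_trials_per_type != design.trials_per_type:
        from dataclasses import replace
        design = replace(design, trials_per_type=n_trials_per_type)

    s_vecs = compose_splitting_vectors(basis, truth.weight_array)  # (4, n)
    schedule, _ = make_trial_schedule(
        design, int(s_sched.generate_state(1)[0]) % (2**31)
    )
    trial_type = np.array(schedule, dtype=object)
    n_trials = trial_type.size
    n_samp = grid.n_samples

    # non-discriminative cue response profile: non-negative, shared by
    # both members of every pair
    cue_rng = np.random.default_rng(s_cue)
    cue_vec = np.abs(cue_rng.standard_normal(n))
    cue_vec = cue_vec / max(np.linalg.norm(cue_vec), 1e-12)

    mean = np.full((n, n_trials, n_samp), float(truth.baseline_rate))

    ov = epoch_samples("overlap", grid, design)
    rw = epoch_samples("reward", grid, design)
    first_odor = grid.window_samples(0.0, design.odor_s)
    second_odor = grid.window_samples(
        design.second_odor_onset_s, design.second_odor_onset_s + design.odor_s
    )

    if profile == "sustained":
        shape_ov = np.ones(ov.size)
    else:  # linear ramp across the overlap epoch, mean 1
        shape_ov = np.linspace(0.0, 2.0, ov.size + 1)[1:]
        shape_ov *= ov.size / shape_ov.sum()

    o_dir = basis.o[0]
    for tt in design.trial_types:
        idx = np.nonzero(trial_type == tt)[0]
        if idx.size == 0:
            continue
        pair = design.pair_of(tt)
        i = design.pair_index[pair] - 1
        sign = +1.0 if tt.endswith("+") else -1.0
        # cue responses (identical within a pair -> never splitting)
        mean[:, idx[:, None], first_odor[None, :]] += (
            truth.cue_response_amplitude * cue_vec[:, None, None]
        )
        if design.pair_type[pair] == "a":
            mean[:, idx[:, None], second_odor[None, :]] += (
                truth.cue_response_amplitude * cue_vec[:, None, None]
            )
        # discriminative splitting component in the overlap epoch
        add = (sign * truth.signal_amplitude / 2.0) * s_vecs[i]
        mean[:, idx[:, None], ov[None, :]] += add[:, None, None] * shape_ov[None, None, :]
        # outcome response on rewarded trials
        if tt.endswith("+"):
            mean[:, idx[:, None], rw[None, :]] += (
                truth.outcome_amp * o_dir[:, None, None]
            )

    noise_rng = np.random.default_rng(s_noise)
    if truth.noise_model == "gaussian":
        rates = mean + truth.noise_sd * noise_rng.standard_normal(mean.shape)
        np.clip(rates, 0.0, None, out=rates)
    else:
        # Poisson counts per sample around the (rectified) mean rate
        lam = np.clip(mean, 0.0, None) / grid.rate_hz
        rates = noise_rng.poisson(lam).astype(float) * grid.rate_hz

    licks = simulate_licks(
        design, schedule, learning_level,
        seed=int(s_lick.generate_state(1)[0]) % (2**31),
    )

    return SessionData(
        rates=rates.astype(np.float32),
        trial_type=trial_type,
        licks=licks,
        grid=grid,
        day=day,
        mouse_id=mouse_id,
        seed=seed,
    )


def simulate_licks(
    design: TaskDesign,
    schedule: list[str],
    learning_level: float,
    seed: int = 0,
    base_rate: float = 2.0,
    outcome_rate: float = 4.0,
) -> pd.DataFrame:
    """Poisson lick events per trial.

    Anticipatory rate over [0, 7) s is ``base_rate * (1 + learning_level)``
    on (+) trials and ``base_rate * (1 - learning_level)`` on (-) trials;
    (+) trials additionally lick at ``outcome_rate`` after the outcome.
    """
    if not 0.0 <= learning_level <= 1.0:
        raise ValueError("learning_level must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t_out = design.outcome_s
    t_end = design.window_s[1]
    rows_trial: list[np.ndarray] = []
    rows_time: list[np.ndarray] = []
    for k, tt in enumerate(schedule):
        plus = tt.endswith("+")
        rate = base_rate * (1.0 + learning_level if plus else 1.0 - learning_level)
        n_ant = rng.poisson(rate * t_out)
        times = np.sort(rng.uniform(0.0, t_out, size=n_ant))
        if plus and outcome_rate > 0:
            n_post = rng.poisson(outcome_rate * (t_end - t_out))
            times = np.concatenate(
                [times, np.sort(rng.uniform(t_out, t_end, size=n_post))]
            )
        rows_trial.append(np.full(times.size, k, dtype=np.int64))
        rows_time.append(times)
    return pd.DataFrame(
        {
            "trial": np.concatenate(rows_trial) if rows_trial else np.array([], dtype=np.int64),
            "time_s": np.concatenate(rows_time) if rows_time else np.array([], dtype=float),
        }
    )
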