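"""Session containers, run configuration, and stage-seed derivation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synth import SessionData
from .task import BinGrid

__all__ = [
    "write_session",
    "read_session",
    "export_session_csv",
    "import_session_csv",
    "RunConfig",
    "stage_seed",
]

_STAGES = (
    "simulate", "behavior", "splitting", "decode", "similarity", "fit",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence(master, stage index).

    Stages can be re-run in isolation given only the master seed.
    """
    if stage not in _STAGES:
        raise KeyError(f"unknown stage: {stage!r}; known: {_STAGES}")
    ss = np.random.SeedSequence([master_seed, _STAGES.index(stage)])
    return int(ss.generate_state(1)[0])


def write_session(session: SessionData, path: str | Path) -> None:
    """HDF5 layout: /rates, /trial_type, /time, /licks + metadata attrs."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=session.rates.astype(np.float32))
        f.create_dataset(
            "trial_type",
            data=np.array([str(t) for t in session.trial_type], dtype=object),
            dtype=h5py.string_dtype(),
        )
        f.create_dataset("time", data=session.grid.sample_times)
        lick_dtype = np.dtype([("trial", np.int64), ("time_s", np.float64)])
        licks = np.empty(len(session.licks), dtype=lick_dtype)
        licks["trial"] = session.licks["trial"].to_numpy()
        licks["time_s"] = session.licks["time_s"].to_numpy()
        f.create_dataset("licks", data=licks)
        f.attrs["seed"] = -1 if session.seed is None else int(session.seed)
        f.attrs["day"] = session.day
        f.attrs["mouse_id"] = session.mouse_id
        f.attrs["rate_hz"] = session.grid.rate_hz
        f.attrs["bin_s"] = session.grid.bin_s
        f.attrs["window_s"] = list(session.grid.window_s)


def read_session(path: str | Path) -> SessionData:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("rates", "trial_type", "time", "licks"):
            if name not in f:
                raise KeyError(f"{path}: missing dataset /{name}")
        rates = f["rates"][...]
        if rates.ndim != 3:
            raise ValueError(f"{path}: /rates must be 3-D (neurons, trials, samples)")
        trial_type = np.array(
            [t.decode() if isinstance(t, bytes) else str(t) for t in f["trial_type"][...]],
            dtype=object,
        )
        if trial_type.size != rates.shape[1]:
            raise ValueError(f"{path}: /trial_type length != number of trials in /rates")
        licks_raw = f["licks"][...]
        licks = pd.DataFrame(
            {"trial": licks_raw["trial"], "time_s": licks_raw["time_s"]}
        )
        window = tuple(float(x) for x in f.attrs["window_s"])
        grid = BinGrid(
            rate_hz=float(f.attrs["rate_hz"]),
            bin_s=float(f.attrs["bin_s"]),
            window_s=window,
        )
        if rates.shape[2] != grid.n_samples:
            raise ValueError(
                f"{path}: /rates has {rates.shape[2]} samples, grid expects {grid.n_samples}"
            )
        seed = int(f.attrs["seed"])
        return SessionData(
            rates=rates,
            trial_type=trial_type,
            licks=licks,
            grid=grid,
            day=int(f.attrs["day"]),
            mouse_id=str(f.attrs["mouse_id"]),
            seed=None if seed == -1 else seed,
        )


def export_session_csv(session: SessionData, path: str | Path) -> None:
    """Long-format text export (neuron, trial, sample, rate) for small fixtures."""
    n, t, s = session.rates.shape
    idx = np.indices((n, t, s))
    df = pd.DataFrame(
        {
            "neuron": idx[0].ravel(),
            "trial": idx[1].ravel(),
            "sample": idx[2].ravel(),
            "rate": session.rates.ravel(),
        }
    )
    df.to_csv(path, index=False)


def import_session_csv(
    path: str | Path,
    trial_type: np.ndarray,
    licks: pd.DataFrame,
    grid: BinGrid | None = None,
) -> SessionData:
    df = pd.read_csv(path)
    n = df["neuron"].max() + 1
    t = df["trial"].max() + 1
    s = df["sample"].max() + 1
    rates = np.zeros((n, t, s), dtype=np.float32)
    rates[df["neuron"], df["trial"], df["sample"]] = df["rate"]
    return SessionData(
        rates=rates,
        trial_type=np.asarray(trial_type, dtype=object),
        licks=licks,
        grid=grid or BinGrid(),
    )


@dataclass
class RunConfig:
    """Parameters for one reproducible end-to-end run."""

    seed: int = 0
    problems: tuple[int, ...] = (1, 2)
    trials_per_type: int = 40
    n_sessions: int = 2
    n_neurons: int = 100
    weights: tuple[float, float, float, float] = (0.7, 0.7, 0.4, 0.4)
    signal_amplitude: float = 1.0
    baseline_rate: float = 2.0
    noise_sd: float = 0.5
    cue_response_amplitude: float = 0.5
    learning_level: float = 0.8
    alpha: float = 0.01
    svm_c: float = 1.0
    n_folds: int = 50
    n_repeats: int = 100
    n_draws: int = 5000
    n_restarts: int = 100
    overlap_q: float = 0.25
    ensemble_neurons: int | None = None
    fit_mode: str = "analytic"
    basis_mode: str = "approx"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        self.problems = tuple(int(p) for p in self.problems)
        self.weights = tuple(float(w) for w in self.weights)
        if self.seed is None:
            raise ValueError("config must set an explicit seed")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["problems"] = list(self.problems)
        d["weights"] = list(self.weights)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".json":
            return cls(**json.loads(path.read_text()))
        return cls.from_yaml(path)

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)
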