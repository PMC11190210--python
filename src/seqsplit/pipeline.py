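"""End-to-end run: simulate -> behavior -> splitting -> decode ->
similarity -> model fit, with a manifest for exact reproduction."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import decoding as dec
from . import model as mdl
from . import splitting as spl
from .io import RunConfig, write_session
from .synth import BasisSpec, GroundTruth, simulate_session
from .task import build_task_design

log = logging.getLogger("seqsplit")

__all__ = ["run_pipeline", "recovery_experiment"]

_FLOAT_FMT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def simulate_stage(config: RunConfig, out: Path | None = None):
    design = build_task_design(set(config.problems), config.trials_per_type)
    truth = GroundTruth(
        weights=np.asarray(config.weights),
        signal_amplitude=config.signal_amplitude,
        baseline_rate=config.baseline_rate,
        noise_sd=config.noise_sd,
        cue_response_amplitude=config.cue_response_amplitude,
    )
    spec = BasisSpec(n_neurons=config.n_neurons, mode=config.basis_mode)
    base = config.stage_seed("simulate")
    sessions = [
        simulate_session(
            design, truth, seed=base + k, spec=spec,
            learning_level=config.learning_level,
            mouse_id=f"sim{k}",
        )
        for k in range(config.n_sessions)
    ]
    if out is not None:
        for k, s in enumerate(sessions):
            write_session(s, out / f"session_{k}.h5")
    log.info("simulate: %d sessions, %d neurons, %d trials each",
             len(sessions), config.n_neurons, sessions[0].n_trials)
    return design, truth, sessions


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages, write text outputs + manifest, return results."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    outputs: list[str] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        outputs.append(name)

    try:
        design, truth, sessions = simulate_stage(config, out=None)
    except Exception as e:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    # behavior
    beh = pd.concat(
        [bh.session_behavior_metrics(s, design) for s in sessions],
        ignore_index=True,
    )
    results["behavior"] = beh
    emit("behavior.csv", lambda p: _write_csv(beh, p))

    # splitting
    rows = []
    for si, s in enumerate(sessions):
        for pair in design.pair_members:
            res = spl.identify_splitting_neurons(
                s, design, pair, epoch="overlap", alpha=config.alpha
            )
            df = res.to_frame()
            df.insert(0, "session", si)
            rows.append(df)
        for pair in design.reward_pairs:
            res = spl.identify_splitting_neurons(
                s, design, pair, epoch="reward", alpha=config.alpha
            )
            df = res.to_frame()
            df.insert(0, "session", si)
            rows.append(df)
    split_df = pd.concat(rows, ignore_index=True)
    results["splitting"] = split_df
    emit("splitting.csv", lambda p: _write_csv(split_df, p))

    # decoding
    n_ens = config.ensemble_neurons or config.n_neurons * config.n_sessions
    ensemble = dec.build_pseudo_ensemble(
        sessions, n_ens, seed=config.stage_seed("decode"), design=design
    )
    acc_rows = []
    rng_seed = config.stage_seed("decode")
    for pair in design.pair_members:
        X, y = ensemble.pair_subset(design, pair)
        acc = dec.cv_accuracy(
            X, y, n_folds=config.n_folds, seed=rng_seed, C=config.svm_c
        )
        upper, _ = dec.shuffle_null_ci(
            X, y, n_shuffles=20, n_folds=config.n_folds,
            seed=rng_seed + 1, C=config.svm_c,
        )
        acc_rows.append(
            {"pair": pair, "accuracy": acc, "null_ci_upper": upper,
             "significant": acc > upper}
        )
    acc_df = pd.DataFrame(acc_rows)
    results["decoding"] = acc_df
    emit("decoding.csv", lambda p: _write_csv(acc_df, p))

    # similarity
    sim = dec.split_half_similarity_matrix(
        ensemble.activity, ensemble.labels, design.pair_members,
        n_repeats=config.n_repeats, seed=config.stage_seed("similarity"),
        C=config.svm_c,
    )
    results["similarity"] = sim
    sim_df = pd.DataFrame(sim.mean, index=sim.pairs, columns=sim.pairs)
    emit("similarity.tsv", lambda p: sim_df.to_csv(p, sep="\t", float_format=_FLOAT_FMT))
    emit("similarity_meta.json", lambda p: p.write_text(json.dumps(
        {"pairs": list(sim.pairs), "n_repeats": sim.n_repeats,
         "sd": sim.sd.tolist()}, indent=2)))

    # model fit
    noise = mdl.noise_term(sim.within_pair_values())
    fits = mdl.fit_ensemble(
        sim.mean, noise=noise, n_restarts=config.n_restarts,
        mode=config.fit_mode, n_draws=config.n_draws,
        seed=config.stage_seed("fit"),
    )
    results["fit"] = fits
    results["noise_term"] = noise
    emit("fit.csv", lambda p: _write_csv(fits, p))
    summary = {
        "noise_term": noise,
        "weights_mean": {k: float(fits[k].mean()) for k in mdl.PARAM_NAMES},
        "weights_sd": {k: float(fits[k].std(ddof=1)) for k in mdl.PARAM_NAMES},
        "mse_mean": float(fits["mse"].mean()),
        "true_weights": list(config.weights),
    }
    emit("fit_summary.json", lambda p: p.write_text(json.dumps(summary, indent=2)))

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": {st: config.stage_seed(st) for st in
                        ("simulate", "decode", "similarity", "fit")},
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def recovery_experiment(
    weights,
    seed: int = 0,
    n_neurons: int = 100,
    trials_per_type: int = 40,
    n_sessions: int = 2,
    signal_amplitude: float = 2.0,
    noise_sd: float = 1.0,
    n_repeats: int = 50,
    n_restarts: int = 20,
    svm_c: float = 1.0,
    basis_mode: str = "approx",
) -> dict:
    """Generate sessions with known weights and recover them end-to-end.

    Returns the empirical similarity matrix, the noise term, the analytic
    prediction for the true weights, and the fit ensemble.
    """
    config = RunConfig(
        seed=seed,
        weights=tuple(np.asarray(weights, dtype=float)),
        n_neurons=n_neurons,
        trials_per_type=trials_per_type,
        n_sessions=n_sessions,
        signal_amplitude=signal_amplitude,
        noise_sd=noise_sd,
        n_repeats=n_repeats,
        n_restarts=n_restarts,
        svm_c=svm_c,
        basis_mode=basis_mode,
    )
    design, truth, sessions = simulate_stage(config)
    ensemble = dec.build_pseudo_ensemble(
        sessions, n_neurons * n_sessions, seed=config.stage_seed("decode"),
        design=design,
    )
    sim = dec.split_half_similarity_matrix(
        ensemble.activity, ensemble.labels, design.pair_members,
        n_repeats=n_repeats, seed=config.stage_seed("similarity"), C=svm_c,
    )
    noise = mdl.noise_term(sim.within_pair_values())
    fits = mdl.fit_ensemble(
        sim.mean, noise=noise, n_restarts=n_restarts,
        mode="analytic", seed=config.stage_seed("fit"),
    )
    return {
        "similarity": sim,
        "noise_term": noise,
        "analytic": mdl.predict_similarity_analytic(np.asarray(weights, dtype=float)),
        "fits": fits,
        "weights_mean": fits[list(mdl.PARAM_NAMES)].mean().to_numpy(),
    }
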