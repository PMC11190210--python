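"""Generative linear model of splitting signals.

Each pair's splitting signal is a weighted mixture of four latent
directions — past cue (alpha), current cue (beta), sequence structure
(gamma) and expected outcome (delta) — whose sharing pattern across the
four sequence pairs fully determines the expected coding-similarity
matrix.  This module provides the Monte-Carlo prediction (random
near-orthogonal bases, as published), an exact closed form under strict
orthogonality, bias-pattern simulation, predicted splitting-neuron
overlaps, and weight recovery by bounded simplex search on the MSE
between (noise-scaled) predicted and observed between-pair similarities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .synth import BasisSpec, BasisSet, generate_basis, compose_splitting_vectors

__all__ = [
    "ModelWeights",
    "FitResult",
    "BETWEEN_PAIRS",
    "predict_similarity_analytic",
    "predict_similarity_mc",
    "simulate_bias_patterns",
    "predicted_overlap",
    "noise_term",
    "similarity_mse",
    "fit_weights",
    "fit_ensemble",
]

#: pair indices (0-based) of the six between-pair entries, row-major upper triangle
BETWEEN_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
)

#: pair types for pair indices 0..3 (pairs 1a, 2a, 1b, 2b)
_IS_TYPE_A = np.array([True, True, False, False])

PARAM_NAMES = ("alpha", "beta", "gamma", "delta")


@dataclass(frozen=True)
class ModelWeights:
    """Mixture weights (alpha, beta, gamma, delta), each in [0, 1]."""

    alpha: float
    beta: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        arr = self.as_array
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("weights must lie in [0, 1]")
        if not np.any(arr > 0):
            raise ValueError("weights must not all be zero")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta])

    def normalized(self) -> np.ndarray:
        a = self.as_array
        return a / np.linalg.norm(a)


def _coerce_weights(weights) -> np.ndarray:
    if isinstance(weights, ModelWeights):
        w = weights.as_array
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (4,):
        raise ValueError("weights must have 4 entries")
    if not np.any(np.abs(w) > 0):
        raise ValueError("weights must not all be zero")
    return w


def predict_similarity_analytic(weights) -> np.ndarray:
    """Expected 4x4 coding-similarity matrix under exact orthogonality.

    With an exactly orthonormal basis, the inner product of two splitting
    signals keeps only the shared components: the outcome direction
    (always shared) and the structure direction (shared within pair
    type); the current-cue component is absent from type-b signal norms
    because their current-cue vectors are zero.  Scale-invariant in the
    weights.
    """
    w = _coerce_weights(weights)
    a2, b2, g2, d2 = w**2
    norm2 = np.where(_IS_TYPE_A, a2 + b2 + g2 + d2, a2 + g2 + d2)
    same_type = _IS_TYPE_A[:, None] == _IS_TYPE_A[None, :]
    num = d2 + g2 * same_type
    sim = num / np.sqrt(norm2[:, None] * norm2[None, :])
    np.fill_diagonal(sim, 1.0)
    return sim


def _basis_tensor(spec: BasisSpec, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """(n_draws, 4 pairs, 4 components, n) stacked bases for vectorized MC."""
    n = spec.n_neurons
    out = np.empty((n_draws, 4, 4, n))
    for d in range(n_draws):
        basis = generate_basis(spec, rng=rng)
        out[d, :, 0] = basis.a
        out[d, :, 1] = basis.b
        out[d, :, 2] = basis.t
        out[d, :, 3] = basis.o
    return out


def _cosines_from_tensor(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-draw 4x4 cosine matrices for splitting signals sum_k w_k v[:, i, k]."""
    s = np.einsum("k,dikn->din", w, v)
    gram = np.einsum("din,djn->dij", s, s)
    norms = np.sqrt(np.einsum("dii->di", gram))
    cos = gram / (norms[:, :, None] * norms[:, None, :])
    return cos


def predict_similarity_mc(
    weights,
    spec: BasisSpec | None = None,
    n_draws: int = 5000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    chunk: int = 2000,
) -> np.ndarray:
    """Monte-Carlo predicted 4x4 similarity: mean cosine over regenerated bases."""
    w = _coerce_weights(weights)
    w = w / np.linalg.norm(w)
    spec = spec or BasisSpec()
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    total = np.zeros((4, 4))
    done = 0
    while done < n_draws:
        k = min(chunk, n_draws - done)
        v = _basis_tensor(spec, k, rng)
        total += _cosines_from_tensor(v, w).sum(axis=0)
        done += k
    sim = total / n_draws
    np.fill_diagonal(sim, 1.0)
    return sim


def simulate_bias_patterns(
    high: float = 0.98,
    low: float = 0.11,
    spec: BasisSpec | None = None,
    n_draws: int = 5000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Predicted similarity for the four one-weight-high bias settings."""
    out = {}
    for k, name in enumerate(PARAM_NAMES):
        w = np.full(4, low)
        w[k] = high
        out[name] = predict_similarity_mc(
            w, spec=spec, n_draws=n_draws, seed=seed + k
        )
    return out


def predicted_overlap(
    weights,
    spec: BasisSpec | None = None,
    q: float = 0.25,
    n_draws: int = 200,
    seed: int = 0,
) -> dict[tuple[int, int], dict]:
    """Predicted splitting-neuron overlap between pairs.

    Per draw, a neuron is "splitting for pair i" when its |s_i| component
    exceeds the (1 - q) quantile of |s_i| across neurons; the reported
    overlap is |A ∩ B| / |A ∪ B| averaged over draws, with the mean Venn
    triple.  The thresholding rule is this module's documented choice.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    w = _coerce_weights(weights)
    spec = spec or BasisSpec()
    rng = np.random.default_rng(seed)
    fractions = {ij: [] for ij in BETWEEN_PAIRS}
    venns = {ij: [] for ij in BETWEEN_PAIRS}
    for _ in range(n_draws):
        basis = generate_basis(spec, rng=rng)
        s = compose_splitting_vectors(basis, w)
        mags = np.abs(s)
        thr = np.quantile(mags, 1.0 - q, axis=1)
        flags = mags > thr[:, None]
        # a pair with identical signals must overlap itself fully even at
        # quantile boundary ties; guard zero signals (all-False flags)
        for (i, j) in BETWEEN_PAIRS:
            fa, fb = flags[i], flags[j]
            union = int(np.sum(fa | fb))
            inter = int(np.sum(fa & fb))
            venns[(i, j)].append((int(fa.sum()) - inter, inter, int(fb.sum()) - inter))
            fractions[(i, j)].append(inter / union if union else np.nan)
    out = {}
    for ij in BETWEEN_PAIRS:
        arr = np.asarray(fractions[ij], dtype=float)
        out[ij] = {
            "overlap_fraction": float(np.nanmean(arr)),
            "venn": tuple(np.mean(np.asarray(venns[ij], dtype=float), axis=0)),
            "q": q,
        }
    return out


def noise_term(within_pair_similarities) -> float:
    """Mean of the four within-pair split-half coding similarities."""
    vals = np.asarray(within_pair_similarities, dtype=float)
    if vals.shape != (4,):
        raise ValueError("expected 4 within-pair similarity values")
    if np.any(np.abs(vals) > 1 + 1e-9):
        raise ValueError("similarities must lie in [-1, 1]")
    return float(np.mean(vals))


def _observed_vector(observed) -> np.ndarray:
    obs = np.asarray(observed, dtype=float)
    if obs.shape == (4, 4):
        obs = obs[np.triu_indices(4, k=1)]
    if obs.shape != (6,):
        raise ValueError("observed must be 6 between-pair values or a 4x4 matrix")
    if not np.all(np.isfinite(obs)):
        raise ValueError("observed similarities must be finite")
    return obs


class _FrozenMCPredictor:
    """Between-pair similarity predictor on a frozen set of basis draws.

    Precomputes per-draw Gram tensors so each weight evaluation is a small
    einsum rather than a fresh basis simulation.
    """

    def __init__(self, spec: BasisSpec, n_draws: int, rng: np.random.Generator):
        v = _basis_tensor(spec, n_draws, rng)  # (D, 4, 4, n)
        self.gram = np.einsum("dikn,djln->dijkl", v, v)

    def between(self, w: np.ndarray) -> np.ndarray:
        num = np.einsum("dijkl,k,l->dij", self.gram, w, w)
        norms = np.sqrt(np.einsum("dii->di", num))
        cos = num / (norms[:, :, None] * norms[:, None, :])
        mean = cos.mean(axis=0)
        return mean[np.triu_indices(4, k=1)]


def _analytic_between(w: np.ndarray) -> np.ndarray:
    return predict_similarity_analytic(w)[np.triu_indices(4, k=1)]


def similarity_mse(
    weights,
    observed,
    noise: float = 1.0,
    entries: list[int] | None = None,
    predictor=None,
) -> float:
    """MSE between noise-scaled predicted and observed between-pair entries.

    ``entries`` selects a subset of the six between-pair values (indices
    into ``BETWEEN_PAIRS``); ``predictor`` defaults to the closed form.
    """
    w = _coerce_weights(weights)
    w = w / np.linalg.norm(w)
    if entries is None:
        obs = _observed_vector(observed)
    else:
        obs = _observed_vector_subset(observed, entries)
    pred = predictor(w) if predictor is not None else _analytic_between(w)
    if entries is not None:
        pred = pred[entries]
    return float(np.mean((noise * pred - obs) ** 2))


def _observed_vector_subset(observed, entries) -> np.ndarray:
    obs = np.asarray(observed, dtype=float)
    if obs.shape == (4, 4):
        obs = obs[np.triu_indices(4, k=1)]
    if obs.size == len(entries):
        return obs
    return obs[entries]


def _moment_init(obs: np.ndarray, noise: float) -> np.ndarray | None:
    """Invert the closed form for a starting point.

    Under exact orthogonality (normalized weights): c12 = g2 + d2,
    c34 = (g2 + d2) / (1 - b2), cross = d2 / sqrt(1 - b2); solve for the
    squared weights and clip into the simplex.  Returns None when the
    observations leave the invertible region.
    """
    v = obs / noise
    c12, c34 = v[0], v[5]
    cross = float(np.mean(v[1:5]))
    if c34 <= 1e-9 or c12 < 0:
        return None
    b2 = float(np.clip(1.0 - c12 / c34, 0.0, 1.0))
    d2 = float(np.clip(cross * np.sqrt(max(1.0 - b2, 0.0)), 0.0, 1.0))
    g2 = float(np.clip(c12 - d2, 0.0, 1.0))
    a2 = float(np.clip(1.0 - b2 - g2 - d2, 0.0, 1.0))
    w = np.sqrt(np.array([a2, b2, g2, d2]))
    if not np.any(w > 0):
        return None
    return w / np.linalg.norm(w)


@dataclass
class FitResult:
    weights: np.ndarray  # normalized (alpha, beta, gamma, delta)
    mse: float
    n_fevals: int
    converged: bool
    restart: int = 0

    def as_dict(self) -> dict:
        d = {name: float(v) for name, v in zip(PARAM_NAMES, self.weights)}
        d.update(mse=float(self.mse), n_fevals=self.n_fevals,
                 converged=self.converged, restart=self.restart)
        return d


def fit_weights(
    observed,
    noise: float = 1.0,
    mode: str = "analytic",
    spec: BasisSpec | None = None,
    n_draws: int = 5000,
    max_fevals: int = 20000,
    seed: int = 0,
    n_starts: int = 3,
    tol: float = 1e-12,
    restart: int = 0,
) -> FitResult:
    """Recover (alpha, beta, gamma, delta) from between-pair similarities.

    Bounded Nelder-Mead simplex on a sigmoid reparameterization of
    [0, 1]^4, minimizing the MSE between noise * predicted and observed
    between-pair similarities; the weight vector is L2-normalized at every
    evaluation.  ``mode="analytic"`` uses the closed form (fast,
    deterministic); ``mode="mc"`` evaluates against ``n_draws`` frozen
    random bases regenerated per call, mirroring the published
    Monte-Carlo averaging.
    """
    if not 0.0 < noise <= 1.0 + 1e-9:
        raise ValueError("noise must be in (0, 1]")
    if mode not in ("analytic", "mc"):
        raise ValueError(f"unknown fit mode: {mode!r}")
    obs = _observed_vector(observed)
    rng = np.random.default_rng(seed)
    if mode == "mc":
        spec = spec or BasisSpec()
        predictor = _FrozenMCPredictor(spec, n_draws, rng).between
    else:
        predictor = _analytic_between

    def cost(z: np.ndarray) -> float:
        w = expit(z)
        nrm = np.linalg.norm(w)
        if nrm < 1e-12:
            return 1e6
        w = w / nrm
        return float(np.mean((noise * predictor(w) - obs) ** 2))

    starts: list[np.ndarray] = []
    w0 = _moment_init(obs, noise)
    if w0 is not None:
        starts.append(logit(np.clip(w0, 1e-3, 1.0 - 1e-3)))
    while len(starts) < max(n_starts, 1 + (w0 is not None)):
        starts.append(logit(rng.uniform(0.15, 0.85, size=4)))

    best = None
    fevals_used = 0
    budget = max_fevals
    n_starts = len(starts)
    for k in range(n_starts):
        x0 = starts[k]
        maxfev = max(100, (budget - fevals_used) // (n_starts - k))
        res = minimize(
            cost, x0, method="Nelder-Mead",
            options={"maxfev": maxfev, "fatol": tol, "xatol": 1e-8},
        )
        fevals_used += res.nfev
        if best is None or res.fun < best.fun:
            best = res
        if fevals_used >= budget:
            break

    # polish: restart the simplex from the best point (Nelder-Mead can
    # stall when the simplex collapses early)
    if fevals_used < budget:
        res = minimize(
            cost, best.x, method="Nelder-Mead",
            options={"maxfev": budget - fevals_used, "fatol": tol, "xatol": 1e-8},
        )
        fevals_used += res.nfev
        if res.fun < best.fun:
            best = res

    w = expit(best.x)
    w = w / np.linalg.norm(w)
    return FitResult(
        weights=w,
        mse=float(best.fun),
        n_fevals=fevals_used,
        converged=bool(best.success),
        restart=restart,
    )


def fit_ensemble(
    observed,
    noise: float = 1.0,
    n_restarts: int = 100,
    mode: str = "analytic",
    spec: BasisSpec | None = None,
    n_draws: int = 5000,
    max_fevals: int = 20000,
    seed: int = 0,
    n_starts: int = 3,
) -> pd.DataFrame:
    """Repeated independent fits (fresh bases and inits per restart).

    Returns one row per restart with the recovered normalized weights and
    the optimal MSE; summarize with ``df[PARAM_NAMES].mean()/std()``.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for k, child in enumerate(ss.spawn(n_restarts)):
        res = fit_weights(
            observed, noise=noise, mode=mode, spec=spec, n_draws=n_draws,
            max_fevals=max_fevals, seed=int(child.generate_state(1)[0]),
            n_starts=n_starts, restart=k,
        )
        rows.append(res.as_dict())
    return pd.DataFrame(rows)
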