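"""Population decoding: pseudo-ensembles, linear max-margin decoding,
splitting vectors, coding similarity and MDS geometry.

The splitting vector of a sequence pair is the unit normal to a linear
SVM's separating hyperplane in population-activity space, oriented so the
(+) class lies on the positive side.  Coding similarity between two
splitting signals is the cosine of the angle between their vectors; the
within-pair (diagonal) similarity comes from decoders trained on
independent halves of the same pair's trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .synth import SessionData
from .task import TaskDesign

__all__ = [
    "PseudoEnsemble",
    "DecoderModel",
    "SimilarityMatrix",
    "build_pseudo_ensemble",
    "train_linear_decoder",
    "cv_accuracy",
    "shuffle_null_ci",
    "splitting_vector",
    "coding_similarity",
    "split_half_similarity_matrix",
    "classical_mds",
    "mds_embedding",
]


@dataclass
class PseudoEnsemble:
    """Pooled neurons with within-trial-type alignment destroyed.

    ``activity`` is (n_trials, n_neurons) of overlap-epoch mean rates;
    ``labels`` the trial type per row; ``neuron_ids`` the contributing
    (session index, neuron index) pairs.
    """

    activity: np.ndarray
    labels: np.ndarray
    neuron_ids: list[tuple[int, int]]
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[1]

    def pair_subset(self, design: TaskDesign, pair: str) -> tuple[np.ndarray, np.ndarray]:
        plus, minus = design.pair_members[pair]
        keep = np.isin(self.labels, [plus, minus])
        return self.activity[keep], self.labels[keep]


@dataclass
class DecoderModel:
    w: np.ndarray
    b: float
    classes: tuple[str, str]
    C: float = 1.0


@dataclass
class SimilarityMatrix:
    """Split-half coding-similarity summary over repeats.

    Diagonal entries are within-pair similarities between the two trial
    halves of the same pair; off-diagonal entries compare vectors from
    different pairs (one half each, both crossings averaged).
    """

    pairs: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    n_repeats: int
    per_repeat: np.ndarray | None = None

    def between_pair_values(self) -> np.ndarray:
        """Upper-triangle (i<j) entries in row-major order: 6 values for 4 pairs."""
        iu = np.triu_indices(len(self.pairs), k=1)
        return self.mean[iu]

    def within_pair_values(self) -> np.ndarray:
        return np.diag(self.mean)


def _epoch_means(session: SessionData, epoch: str, design: TaskDesign | None):
    from .splitting import epoch_trial_means

    return epoch_trial_means(session, epoch, design)


def build_pseudo_ensemble(
    sessions: list[SessionData],
    n_neurons: int,
    seed: int = 0,
    epoch: str = "overlap",
    design: TaskDesign | None = None,
) -> PseudoEnsemble:
    """Sample neurons across sessions and align trials within type.

    Neurons are drawn without replacement from the pooled population.
    Each neuron's trials are independently permuted within trial type
    (destroying noise correlations) and truncated to the minimum per-type
    count across sessions.
    """
    if not sessions:
        raise ValueError("need at least one session")
    type_set = sorted(set(sessions[0].trial_type.tolist()))
    for s in sessions[1:]:
        if sorted(set(s.trial_type.tolist())) != type_set:
            raise ValueError("all sessions must share the same trial-type set")
    pool = [
        (si, ni) for si, s in enumerate(sessions) for ni in range(s.n_neurons)
    ]
    if n_neurons > len(pool):
        raise ValueError(
            f"requested {n_neurons} neurons but pool has only {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(pool), size=n_neurons, replace=False)
    chosen = [pool[k] for k in chosen_idx]

    min_count = {
        tt: min(int(np.sum(s.trial_type == tt)) for s in sessions) for tt in type_set
    }
    means = [_epoch_means(s, epoch, design) for s in sessions]
    trials_by_type = {
        tt: [s.trials_of(tt) for s in sessions] for tt in type_set
    }

    n_rows = sum(min_count.values())
    activity = np.empty((n_rows, n_neurons))
    labels = np.empty(n_rows, dtype=object)
    row = 0
    blocks: dict[str, slice] = {}
    for tt in type_set:
        k = min_count[tt]
        blocks[tt] = slice(row, row + k)
        labels[row : row + k] = tt
        row += k

    for col, (si, ni) in enumerate(chosen):
        for tt in type_set:
            idx = trials_by_type[tt][si]
            perm = rng.permutation(idx)[: min_count[tt]]
            activity[blocks[tt], col] = means[si][ni, perm]
    return PseudoEnsemble(activity=activity, labels=labels, neuron_ids=chosen, seed=seed)


def train_linear_decoder(
    activity: np.ndarray, labels: np.ndarray, C: float = 1.0
) -> DecoderModel:
    """Linear max-margin (hinge-loss) binary classifier."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    clf = SVC(kernel="linear", C=C)
    clf.fit(activity, labels)
    return DecoderModel(
        w=np.asarray(clf.coef_).ravel().copy(),
        b=float(clf.intercept_[0]),
        classes=(str(clf.classes_[0]), str(clf.classes_[1])),
        C=C,
    )


def _predict(model: DecoderModel, X: np.ndarray) -> np.ndarray:
    score = X @ model.w + model.b
    # SVC decision function is positive for classes_[1]
    return np.where(score > 0, model.classes[1], model.classes[0])


def cv_accuracy(
    activity: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 50,
    seed: int = 0,
    C: float = 1.0,
) -> float:
    """Leave-one-per-class-out cross-validated accuracy.

    Each fold holds out one randomly chosen trial per class, trains on the
    rest and tests on the held-out trials; the mean over folds is returned.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("binary labels required")
    idx_by_class = {c: np.nonzero(labels == c)[0] for c in classes}
    for c, idx in idx_by_class.items():
        if idx.size < 2:
            raise ValueError(f"class {c!r} needs >= 2 trials")
    rng = np.random.default_rng(seed)
    correct = 0
    total = 0
    for _ in range(n_folds):
        held = np.array([rng.choice(idx_by_class[c]) for c in classes])
        mask = np.ones(labels.size, dtype=bool)
        mask[held] = False
        model = train_linear_decoder(activity[mask], labels[mask], C=C)
        pred = _predict(model, activity[held])
        correct += int(np.sum(pred == labels[held]))
        total += held.size
    return correct / total


def shuffle_null_ci(
    activity: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 20,
    level: float = 0.95,
    n_folds: int = 50,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Upper bound of the label-shuffle accuracy CI.

    Class labels are permuted across trials per shuffle and the CV
    accuracy recomputed; returns the (1 + level)/2 percentile (linear
    interpolation between order statistics) and the per-shuffle accuracies.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be >= 20")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = rng.permutation(labels)
        accs[k] = cv_accuracy(
            activity, shuffled, n_folds=n_folds,
            seed=int(rng.integers(2**31)), C=C,
        )
    upper = float(np.percentile(accs, 100 * (1 + level) / 2))
    return upper, accs


def splitting_vector(
    model: DecoderModel, plus_label: str | None = None
) -> np.ndarray:
    """Unit hyperplane normal, oriented so the (+) class scores positive."""
    norm = np.linalg.norm(model.w)
    if norm == 0:
        raise ValueError("decoder weight vector is zero")
    v = model.w / norm
    if plus_label is not None:
        if plus_label not in model.classes:
            raise ValueError(f"{plus_label!r} not among classes {model.classes}")
        if plus_label == model.classes[0]:
            v = -v
    return v


def coding_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine of the angle between two coding directions."""
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("coding similarity undefined for zero vectors")
    return float(np.dot(v1, v2) / (n1 * n2))


def _half_split(idx: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(idx)
    half = idx.size // 2
    # odd counts: the first (larger) half receives the extra trial
    return perm[: idx.size - half], perm[idx.size - half :]


def split_half_similarity_matrix(
    activity: np.ndarray,
    labels: np.ndarray,
    pair_members: dict[str, tuple[str, str]],
    n_repeats: int = 100,
    seed: int = 0,
    C: float = 1.0,
    shuffle_labels: bool = False,
) -> SimilarityMatrix:
    """Within/between-pair coding-similarity matrix over random re-divisions.

    Per repeat and per pair, the pair's trials are split into random
    halves and one decoder is trained per half.  Diagonal = similarity of
    the two halves of the same pair; entry (i, j), i != j, = the average
    of the two half-crossings between pairs i and j.  With
    ``shuffle_labels`` the two class labels are permuted within each half
    before training (the label-shuffle null).
    """
    labels = np.asarray(labels)
    pairs = tuple(pair_members)
    n_pairs = len(pairs)
    rng = np.random.default_rng(seed)
    per_repeat = np.empty((n_repeats, n_pairs, n_pairs))
    idx_by_class = {}
    for pid, (plus, minus) in pair_members.items():
        for lab in (plus, minus):
            idx = np.nonzero(labels == lab)[0]
            if idx.size < 4:
                raise ValueError(f"class {lab!r} needs >= 4 trials for split-half")
            idx_by_class[lab] = idx

    for rep in range(n_repeats):
        vecs = np.empty((n_pairs, 2, activity.shape[1]))
        for pi, pid in enumerate(pairs):
            plus, minus = pair_members[pid]
            p1, p2 = _half_split(idx_by_class[plus], rng)
            m1, m2 = _half_split(idx_by_class[minus], rng)
            for hi, (pp, mm) in enumerate(((p1, m1), (p2, m2))):
                rows = np.concatenate([pp, mm])
                y = labels[rows]
                if shuffle_labels:
                    y = rng.permutation(y)
                    if len(set(y.tolist())) < 2:  # degenerate permutation
                        y = labels[rows]
                model = train_linear_decoder(activity[rows], y, C=C)
                vecs[pi, hi] = splitting_vector(model, plus_label=plus)
        for i in range(n_pairs):
            per_repeat[rep, i, i] = coding_similarity(vecs[i, 0], vecs[i, 1])
            for j in range(i + 1, n_pairs):
                s = 0.5 * (
                    coding_similarity(vecs[i, 0], vecs[j, 1])
                    + coding_similarity(vecs[i, 1], vecs[j, 0])
                )
                per_repeat[rep, i, j] = per_repeat[rep, j, i] = s
    return SimilarityMatrix(
        pairs=pairs,
        mean=per_repeat.mean(axis=0),
        sd=per_repeat.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros((n_pairs, n_pairs)),
        n_repeats=n_repeats,
        per_repeat=per_repeat,
    )


def classical_mds(dist: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    Exact for Euclidean input of true dimensionality <= k.  A degenerate
    (all-zero) matrix embeds to zeros.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def mds_embedding(
    activity: np.ndarray, labels: np.ndarray, k: int = 2
) -> tuple[np.ndarray, list[str]]:
    """2-D classical MDS of trial-type mean population vectors.

    Euclidean distances between trial-averaged epoch activity per type.
    """
    labels = np.asarray(labels)
    types = sorted(set(labels.tolist()))
    if len(types) < 3:
        raise ValueError("need >= 3 trial types")
    means = np.stack([activity[labels == t].mean(axis=0) for t in types])
    diff = means[:, None, :] - means[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    return classical_mds(dist, k=k), types
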