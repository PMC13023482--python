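"""Classifiers for reservoir state vectors, with a reject option.

Four classifier families operate on (z-scored) state vectors: an RBF-kernel
SVM, a feature-SNR-weighted k-nearest-neighbour rule (WWKNN), a normalised
centroid prototype per class, and prototypes refined by gradient descent on
a temperature-scaled cosine-similarity cross-entropy (the learned
prototype, the framework's default). Prediction confidences are softmax
probabilities over cosine similarities; thresholding them yields a
"don't know" output whose quality is summarised by coverage / overall
accuracy / selective accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.svm import SVC

DONT_KNOW = -1  # sentinel label for rejected predictions

#: default confidence thresholds per model variant
DEFAULT_THRESHOLDS = {"visual": 0.65, "audio": 0.55, "multimodal": 0.60}


def _round1(x: float) -> float:
    """Percentage rounded half-up to one decimal (table printing rule)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _unit_rows(M: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    return M / np.maximum(norms, eps)


# ---------------------------------------------------------------------------
# Prototype classifiers
# ---------------------------------------------------------------------------

@dataclass
class PrototypeSet:
    """Unit-norm class prototypes with a softmax temperature."""

    prototypes: np.ndarray  # [n_classes x n_features], unit rows
    classes: np.ndarray
    tau: float = 0.1


@dataclass
class LearnedPrototypeConfig:
    """Gradient-descent refinement of the centroid prototypes.

    Adaptive-moment (Adam) full-batch updates on the cross-entropy of
    temperature-scaled cosine similarities; prototypes are re-normalised to
    unit length after every step. ``init_jitter > 0`` adds seeded Gaussian
    noise to the centroid initialisation (used for multi-seed stability
    sweeps); at 0 epochs the classifier is exactly the centroid one.
    """

    learning_rate: float = 0.01
    epochs: int = 300
    tau: float = 0.1
    seed: int | None = None
    init_jitter: float = 0.0


def fit_centroid(states: np.ndarray, labels: np.ndarray, tau: float = 0.1) -> PrototypeSet:
    """Per class: mean state vector, normalised to unit length."""
    X = np.asarray(states, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    protos = np.empty((len(classes), X.shape[1]))
    for i, c in enumerate(classes):
        mean = X[y == c].mean(axis=0)
        norm = np.linalg.norm(mean)
        if norm == 0:
            raise ValueError(f"class {c!r} centroid has zero norm")
        protos[i] = mean / norm
    return PrototypeSet(protos, classes, tau)


def _cosine_sims(X: np.ndarray, protos: np.ndarray) -> np.ndarray:
    return _unit_rows(X) @ protos.T  # prototypes already unit rows


def predict_proba(protoset: PrototypeSet, states: np.ndarray) -> np.ndarray:
    """Softmax over cosine similarities / tau; rows sum to 1."""
    X = np.atleast_2d(np.asarray(states, dtype=float))
    logits = _cosine_sims(X, protoset.prototypes) / protoset.tau
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def predict(protoset: PrototypeSet, states: np.ndarray) -> np.ndarray:
    probs = predict_proba(protoset, states)
    return protoset.classes[np.argmax(probs, axis=1)]


def fit_learned_prototype(states: np.ndarray, labels: np.ndarray,
                          cfg: LearnedPrototypeConfig | None = None) -> PrototypeSet:
    """Refine centroid prototypes by Adam on the softmax cross-entropy."""
    cfg = cfg or LearnedPrototypeConfig()
    X = np.asarray(states, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    protos = fit_centroid(X, y, cfg.tau).prototypes.copy()
    if cfg.init_jitter > 0:
        rng = np.random.default_rng(cfg.seed)
        protos = _unit_rows(protos + rng.normal(0, cfg.init_jitter, protos.shape))
    y_idx = np.searchsorted(classes, y)
    onehot = np.zeros((len(y), len(classes)))
    onehot[np.arange(len(y)), y_idx] = 1.0
    Xhat = _unit_rows(X)

    m = np.zeros_like(protos)
    v = np.zeros_like(protos)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    for epoch in range(cfg.epochs):
        sims = Xhat @ protos.T
        logits = sims / cfg.tau
        logits -= logits.max(axis=1, keepdims=True)
        q = np.exp(logits)
        q /= q.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(np.maximum(q[np.arange(len(y)), y_idx], 1e-300)))
        if not math.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        # d loss / d p_c through the cosine similarity of unit prototypes:
        # dsim/dp = (xhat - sim * p) since ||p|| is re-normalised to 1
        coef = (q - onehot) / (cfg.tau * len(y))  # [n x C]
        grad = coef.T @ Xhat - (coef * sims).sum(axis=0)[:, None] * protos
        m = beta1 * m + (1 - beta1) * grad
        v = beta2 * v + (1 - beta2) * grad**2
        mhat = m / (1 - beta1 ** (epoch + 1))
        vhat = v / (1 - beta2 ** (epoch + 1))
        protos -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        protos = _unit_rows(protos)
    return PrototypeSet(protos, classes, cfg.tau)


# ---------------------------------------------------------------------------
# WWKNN
# ---------------------------------------------------------------------------

@dataclass
class WWKNNModel:
    """k-NN with per-feature signal-to-noise distance weights.

    ``snr[f]`` = between-class variance / within-class variance of feature
    f on the training set (within floored); features that do not separate
    the classes get weight ~0 and drop out of the distance.
    """

    X: np.ndarray
    y: np.ndarray
    snr: np.ndarray
    k: int = 5


def fit_wwknn(states: np.ndarray, labels: np.ndarray, k: int = 5,
              within_floor: float = 1e-8) -> WWKNNModel:
    X = np.asarray(states, dtype=float)
    y = np.asarray(labels)
    if k <= 0:
        raise ValueError("k must be positive")
    classes = np.unique(y)
    gmean = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        w = len(Xc) / len(X)
        between += w * (Xc.mean(axis=0) - gmean) ** 2
        within += w * Xc.var(axis=0)
    snr = between / np.maximum(within, within_floor)
    return WWKNNModel(X, y, snr, k)


def wwknn_predict(model: WWKNNModel, queries: np.ndarray):
    """Distance-weighted majority vote among the k SNR-nearest neighbours.

    Returns (labels, confidences) where confidence is the winning class's
    share of the inverse-distance vote mass.
    """
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    if model.k > len(model.X):
        raise ValueError("k exceeds the number of training samples")
    diff = Q[:, None, :] - model.X[None, :, :]
    d = np.sqrt(np.maximum((model.snr[None, None, :] * diff**2).sum(axis=2), 0.0))
    classes = np.unique(model.y)
    labels = np.empty(len(Q), dtype=model.y.dtype)
    confs = np.empty(len(Q))
    for i in range(len(Q)):
        nn = np.argsort(d[i], kind="stable")[: model.k]
        w = 1.0 / (d[i][nn] + 1e-12)
        votes = np.array([w[model.y[nn] == c].sum() for c in classes])
        best = int(np.argmax(votes))
        labels[i] = classes[best]
        confs[i] = votes[best] / votes.sum()
    return labels, confs


def rbf_kernel(x_i: np.ndarray, x_j: np.ndarray, gamma: float | None = None) -> float:
    """K(x_i, x_j) = exp(-gamma * ||x_i - x_j||^2); gamma defaults to 1/d."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError("inputs must share dimensionality")
    if gamma is None:
        gamma = 1.0 / x_i.size
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(np.exp(-gamma * np.sum((x_i - x_j) ** 2)))


def fit_svm(states: np.ndarray, labels: np.ndarray, gamma: float | None = None) -> SVC:
    """RBF-kernel max-margin classifier (standard solver behind our kernel)."""
    X = np.asarray(states, dtype=float)
    clf = SVC(kernel="rbf", gamma=(gamma if gamma is not None else 1.0 / X.shape[1]),
              probability=True, random_state=0)
    clf.fit(X, np.asarray(labels))
    return clf


# ---------------------------------------------------------------------------
# Selective classification
# ---------------------------------------------------------------------------

def selective_predict(probs: np.ndarray, threshold: float, classes=None):
    """Argmax label when max probability >= threshold, else DONT_KNOW."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    P = np.atleast_2d(np.asarray(probs, dtype=float))
    classes = np.arange(P.shape[1]) if classes is None else np.asarray(classes)
    top = P.max(axis=1)
    pred = classes[np.argmax(P, axis=1)]
    return np.where(top >= threshold, pred, DONT_KNOW)


@dataclass
class SelectiveReport:
    """Counts and rounded percentages of one thresholded prediction pass.

    Identities: correct + wrong + rejected = n and
    rejected = lost_correct + errors_avoided. ``selective_accuracy`` is
    None when everything is rejected.
    """

    n: int
    threshold: float
    correct: int
    wrong: int
    rejected: int
    lost_correct: int
    errors_avoided: int
    coverage: float
    overall_accuracy: float
    selective_accuracy: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def selective_metrics(truth, selective_preds, forced_preds,
                      threshold: float = 0.0) -> SelectiveReport:
    """Tabulate a selective prediction pass against the forced (threshold-0) one.

    ``lost_correct`` counts rejected samples whose forced prediction was
    right; ``errors_avoided`` the rejected samples whose forced prediction
    was wrong. Percentages are rounded half-up to one decimal.
    """
    truth = np.asarray(truth)
    sel = np.asarray(selective_preds)
    forced = np.asarray(forced_preds)
    if not (len(truth) == len(sel) == len(forced)):
        raise ValueError("truth, selective and forced predictions must align")
    n = len(truth)
    rejected_mask = sel == DONT_KNOW
    accepted = ~rejected_mask
    correct = int(np.sum(accepted & (sel == truth)))
    wrong = int(np.sum(accepted & (sel != truth)))
    rejected = int(rejected_mask.sum())
    lost_correct = int(np.sum(rejected_mask & (forced == truth)))
    errors_avoided = rejected - lost_correct
    coverage = _round1(100.0 * (correct + wrong) / n)
    overall = _round1(100.0 * (correct + lost_correct) / n)
    selective = (_round1(100.0 * correct / (correct + wrong))
                 if correct + wrong > 0 else None)
    return SelectiveReport(
        n=n, threshold=threshold, correct=correct, wrong=wrong, rejected=rejected,
        lost_correct=lost_correct, errors_avoided=errors_avoided,
        coverage=coverage, overall_accuracy=overall, selective_accuracy=selective,
    )


# ---------------------------------------------------------------------------
# Training-set conditioning and multi-seed summaries
# ---------------------------------------------------------------------------

@dataclass
class Normaliser:
    """Per-feature z-scoring with training-set statistics."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Normaliser":
        X = np.asarray(X, dtype=float)
        return cls(X.mean(axis=0), np.maximum(X.std(axis=0), 1e-8))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def balance_by_duplication(X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Equalise class counts by duplicating minority-class samples."""
    X = np.asarray(X)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    idx_out = []
    for c, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == c)
        idx_out.append(idx)
        if cnt < n_max:
            idx_out.append(rng.choice(idx, n_max - cnt, replace=True))
    idx_all = np.concatenate(idx_out)
    return X[idx_all], y[idx_all]


def seed_sweep(fit_predict_fn, seeds=None, n_seeds: int = 30) -> dict:
    """Accuracy mean, sample std and normal-approximation 95% CI over seeds.

    ``fit_predict_fn(seed)`` must return the accuracy for one seed.
    """
    if seeds is None:
        seeds = list(range(n_seeds))
    if len(seeds) < 2:
        raise ValueError("need at least two seeds")
    accs = np.array([float(fit_predict_fn(s)) for s in seeds])
    mean = float(accs.mean())
    std = float(accs.std(ddof=1))
    half = 1.96 * std / math.sqrt(len(accs))
    return {
        "accuracies": accs,
        "mean": mean,
        "std": std,
        "ci95": (mean - half, mean + half),
    }
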