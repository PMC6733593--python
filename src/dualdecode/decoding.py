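"""Time-resolved linear-discriminant decoding of target position.

For each time sample, a pooled-covariance LDA (Ledoit-Wolf shrinkage,
equal priors) is trained on the channel vector of that sample under 10-fold
cross-validation and scored with the AUC (Mann-Whitney form, ties counted
half). Per-trial classifier confidence is the signed distance from the
decision boundary, taken from the fold in which the trial was test data;
positive confidence means the first-listed class (left, or top). Classifier
weights are turned into interpretable activation maps by multiplication with
the training-data channel covariance (forward-model transformation).

Class imbalance is handled as in the published analysis: *within-class*
balancing undersamples so that, inside each class of the decoded dimension,
both levels of the orthogonal dimension are equally frequent; *between-class*
balancing oversamples the minority class on training folds only, with
synthetic samples formed as convex combinations of k-nearest minority
neighbours (SMOTE-style interpolation).

The LDA solver is a batched closed form vectorized over timepoints (class
means, per-class Ledoit-Wolf shrunk covariance, averaged with equal priors,
then ``w = Sigma^-1 (mu_pos - mu_neg)``), numerically equivalent to
scikit-learn's ``LinearDiscriminantAnalysis(solver='lsqr')``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .epochs import EpochsSet

__all__ = [
    "DecodingResult", "TimeResolvedDecoder", "auc_from_scores",
    "balance_within_class", "balance_between_class", "train_lda",
    "activation_map", "make_fold_plan", "crossval_decode",
]

DIMENSION_CLASSES = {"horizontal": ("left", "right"),
                     "vertical": ("top", "bottom")}


# ----------------------------------------------------------------------
# AUC
def auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve for binary labels.

    Equals the Mann-Whitney U statistic normalized by ``n_pos * n_neg``,
    with tied scores counted one half. ``labels`` is boolean (True = positive
    class).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def _auc_batch(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise AUC for ``scores`` of shape (T, n); ties counted half."""
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    ranks = rankdata(scores, axis=1)
    return (ranks[:, labels].sum(axis=1) - n_pos * (n_pos + 1) / 2.0) \
        / (n_pos * n_neg)


# ----------------------------------------------------------------------
# Balancing
def balance_within_class(trials, decode_dimension: str,
                         rng: np.random.Generator) -> np.ndarray:
    """Undersample so the orthogonal dimension is balanced inside each class.

    Returns positional indices of retained trials. Inside each class of the
    decoded dimension (e.g. left targets), the two levels of the irrelevant
    dimension (top/bottom) are randomly undersampled to their minimum count.
    """
    dim_col, orth_col = (("h_class", "v_class")
                         if decode_dimension == "horizontal"
                         else ("v_class", "h_class"))
    y = trials[dim_col].to_numpy()
    orth = trials[orth_col].to_numpy()
    classes = DIMENSION_CLASSES[decode_dimension]
    orth_levels = DIMENSION_CLASSES[
        "vertical" if decode_dimension == "horizontal" else "horizontal"]
    keep = []
    for c in classes:
        groups = [np.flatnonzero((y == c) & (orth == lv)) for lv in orth_levels]
        m = min(len(g) for g in groups)
        if m == 0:
            raise ValueError(
                f"cannot balance: class {c!r} lacks one level of {orth_col}")
        for g in groups:
            keep.append(rng.permutation(g)[:m] if len(g) > m else g)
    return np.sort(np.concatenate(keep))


def balance_between_class(X: np.ndarray, y: np.ndarray,
                          rng: np.random.Generator,
                          k_neighbors: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by interpolation-based minority oversampling.

    Synthetic samples are convex combinations ``x_a + gap * (x_b - x_a)`` of
    a minority sample and one of its ``k_neighbors`` nearest minority
    neighbours (gap uniform on [0, 1)), so every synthetic sample lies within
    the componentwise min-max envelope of the minority class. ``X`` may have
    any trailing feature shape; neighbours are found on flattened features.
    A single-sample minority class falls back to duplication with a warning.
    """
    y = np.asarray(y, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == n_neg:
        return X, y
    minority = y if n_pos < n_neg else ~y
    n_extra = abs(n_pos - n_neg)
    Xm = X[minority]
    flat = Xm.reshape(len(Xm), -1)
    if len(Xm) == 1:
        warnings.warn("minority class has a single sample; duplicating it")
        synth = np.repeat(Xm, n_extra, axis=0)
    else:
        from sklearn.neighbors import NearestNeighbors

        k = min(k_neighbors, len(Xm) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(flat)
        neigh = nn.kneighbors(flat, return_distance=False)[:, 1:]
        base = rng.integers(0, len(Xm), n_extra)
        partner = neigh[base, rng.integers(0, k, n_extra)]
        gap = rng.random(n_extra).reshape((-1,) + (1,) * (X.ndim - 1))
        synth = Xm[base] + gap * (Xm[partner] - Xm[base])
    X_aug = np.concatenate([X, synth], axis=0)
    y_aug = np.concatenate([y, np.full(n_extra, bool(n_pos < n_neg))])
    return X_aug, y_aug


# ----------------------------------------------------------------------
# Batched Ledoit-Wolf LDA
def _ledoit_wolf_cov_batch(Xraw: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrunk covariance for centered input of shape (T, n, p).

    Features are standardized before estimating the shrinkage intensity and
    the result rescaled, matching scikit-learn's covariance path for
    shrinkage LDA.
    """
    T, n, p = Xraw.shape
    sd = np.sqrt((Xraw ** 2).mean(axis=1))          # (T, p), data centered
    sd = np.where(sd > 0, sd, 1.0)
    Xc = Xraw / sd[:, None, :]
    S = Xc.transpose(0, 2, 1) @ Xc / n                      # (T, p, p)
    mu = np.trace(S, axis1=1, axis2=2) / p                  # (T,)
    sum_S2 = np.einsum("tij,tij->t", S, S)
    delta = sum_S2 / p - 2.0 * mu * np.trace(S, axis1=1, axis2=2) / p + mu ** 2
    sq_norms = np.einsum("tnp,tnp->tn", Xc, Xc)             # ||x_i||^2
    beta_ = (np.sum(sq_norms ** 2, axis=1) / n - sum_S2) / (n * p)
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(delta > 0, np.minimum(beta_, delta) / delta, 0.0)
        shrink = np.clip(np.nan_to_num(shrink), 0.0, 1.0)
    out = (1.0 - shrink)[:, None, None] * S
    idx = np.arange(p)
    out[:, idx, idx] += (shrink * mu)[:, None]
    return out * (sd[:, :, None] * sd[:, None, :])


def _fit_lda_batch(X: np.ndarray, y: np.ndarray,
                   shrinkage: str | float = "auto"
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-covariance LDA per timepoint: ``X`` (T, n, p), boolean ``y``.

    Returns weights (T, p) and intercepts (T,) such that the decision score
    ``w . x + b`` is positive for the positive class (equal priors).
    """
    y = np.asarray(y, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    covs = []
    means = []
    for cls in (True, False):
        Xg = X[:, y == cls, :]
        mu = Xg.mean(axis=1)
        Xc = Xg - mu[:, None, :]
        if shrinkage == "auto":
            covs.append(_ledoit_wolf_cov_batch(Xc))
        else:
            T, n, p = Xc.shape
            S = Xc.transpose(0, 2, 1) @ Xc / n
            m = np.trace(S, axis1=1, axis2=2) / p
            S = (1.0 - shrinkage) * S
            idx = np.arange(p)
            S[:, idx, idx] += (shrinkage * m)[:, None]
            covs.append(S)
        means.append(mu)
    cov = 0.5 * (covs[0] + covs[1])                 # equal priors
    diff = means[0] - means[1]                      # mu_pos - mu_neg
    w = np.linalg.solve(cov, diff[..., None])[..., 0]
    b = -0.5 * np.einsum("tp,tp->t", means[0] + means[1], w)
    return w, b


def train_lda(X: np.ndarray, y: np.ndarray,
              shrinkage: str | float = "auto") -> tuple[np.ndarray, float]:
    """Single-timepoint LDA: ``X`` (n, p), boolean ``y``; returns (w, b)."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    w, b = _fit_lda_batch(X[None], y, shrinkage)
    return w[0], float(b[0])


def activation_map(weights: np.ndarray, train_X: np.ndarray) -> np.ndarray:
    """Forward-model pattern: data covariance times classifier weights.

    ``weights`` (p,) or (T, p); ``train_X`` (n, p) or (T, n, p). The pattern
    ``Sigma w`` is interpretable as the source topography driving the
    discriminant, unlike the weights themselves.
    """
    weights = np.asarray(weights, dtype=float)
    train_X = np.asarray(train_X, dtype=float)
    if weights.ndim == 1:
        Xc = train_X - train_X.mean(axis=0)
        cov = Xc.T @ Xc / len(Xc)
        return cov @ weights
    Xc = train_X - train_X.mean(axis=1, keepdims=True)
    cov = Xc.transpose(0, 2, 1) @ Xc / train_X.shape[1]
    return np.einsum("tpq,tq->tp", cov, weights)


# ----------------------------------------------------------------------
def make_fold_plan(n_trials: int, n_folds: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Random fold assignment: shuffle order, split into near-equal folds."""
    if n_trials < n_folds:
        raise ValueError("fewer trials than folds")
    fold = np.empty(n_trials, dtype=int)
    perm = rng.permutation(n_trials)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        fold[chunk] = f
    return fold


@dataclass
class DecodingResult:
    """Cross-validated time-resolved decoding output for one dimension."""

    dimension: str
    classes: tuple[str, str]              # (positive, negative)
    times_ms: np.ndarray                  # (T,)
    auc: np.ndarray                       # (T,) fold-averaged
    confidence: np.ndarray                # (n_retained, T) signed distance
    y: np.ndarray                         # (n_retained,) True = positive class
    fold: np.ndarray                      # (n_retained,)
    trial_index: np.ndarray               # positions in the input epochs
    weights: np.ndarray                   # (T, channels) fold-averaged
    activation: np.ndarray                # (T, channels) fold-averaged

    @property
    def peak_time_ms(self) -> float:
        return float(self.times_ms[int(np.argmax(self.auc))])

    def auc_in_window(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        m = (self.times_ms >= lo) & (self.times_ms <= hi)
        return self.auc[m]

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for k in ("times_ms", "auc", "confidence", "fold",
                      "trial_index", "weights", "activation"):
                f.create_dataset(k, data=getattr(self, k))
            f.create_dataset("y", data=self.y.astype(bool))
            f.attrs["dimension"] = self.dimension
            f.attrs["classes"] = list(self.classes)


class TimeResolvedDecoder(BaseEstimator):
    """Per-timepoint LDA decoder with cross-validated confidence extraction.

    scikit-learn-style estimator over epoched data ``X`` of shape
    ``(n_trials, n_channels, n_times)`` with binary string or boolean labels
    ``y``. ``fit`` runs the full cross-validation (the estimator is a
    cross-validated read-out, so fitting and scoring are one pass) and
    exposes fold-averaged AUC, per-trial test-fold confidence, weights and
    activation maps as fitted attributes.

    Parameters
    ----------
    n_folds : int
        Cross-validation folds (10 in the reference analysis).
    shrinkage : 'auto' or float in [0, 1]
        Covariance shrinkage; 'auto' is Ledoit-Wolf.
    between_balance : bool
        Oversample the training minority class (interpolation-based).
    k_neighbors : int
        Neighbourhood size for synthetic oversampling.
    random_state : int or None
        Seed for fold assignment and oversampling.
    """

    def __init__(self, n_folds: int = 10, shrinkage="auto",
                 between_balance: bool = True, k_neighbors: int = 5,
                 random_state: int | None = None):
        self.n_folds = n_folds
        self.shrinkage = shrinkage
        self.between_balance = between_balance
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_trials, n_channels, n_times)")
        y = np.asarray(y)
        if y.dtype != bool:
            classes = np.unique(y)
            if len(classes) != 2:
                raise ValueError("y must be binary")
            y = y == classes[0]      # first-listed class is positive
            self.classes_ = tuple(classes)
        else:
            self.classes_ = (True, False)
        n, n_ch, n_t = X.shape
        rng = np.random.default_rng(self.random_state)
        fold = make_fold_plan(n, self.n_folds, rng)

        auc = np.zeros((self.n_folds, n_t))
        weights = np.zeros((self.n_folds, n_t, n_ch))
        activation = np.zeros((self.n_folds, n_t, n_ch))
        confidence = np.full((n, n_t), np.nan)
        for f in range(self.n_folds):
            tr, te = fold != f, fold == f
            Xtr, ytr = X[tr], y[tr]
            if self.between_balance:
                Xtr, ytr = balance_between_class(Xtr, ytr, rng,
                                                 self.k_neighbors)
            Xt = np.ascontiguousarray(Xtr.transpose(2, 0, 1))  # (T, n, C)
            w, b = _fit_lda_batch(Xt, ytr, self.shrinkage)
            scores = np.einsum("tc,ntc->tn", w,
                               X[te].transpose(0, 2, 1)) + b[:, None]
            auc[f] = _auc_batch(scores, y[te])
            confidence[te] = scores.T
            weights[f] = w
            activation[f] = activation_map(w, Xt)

        self.fold_ = fold
        self.auc_ = auc.mean(axis=0)
        self.weights_ = weights.mean(axis=0)
        self.activation_ = activation.mean(axis=0)
        self.confidence_ = confidence
        self.y_ = y
        self.n_features_in_ = n_ch
        return self

    def score(self, X=None, y=None) -> float:
        """Mean cross-validated AUC over timepoints (fitted attribute)."""
        return float(self.auc_.mean())


# ----------------------------------------------------------------------
def crossval_decode(epochs: EpochsSet, dimension: str, folds: int = 10,
                    seed: int | None = None, shrinkage="auto",
                    window_ms: tuple[float, float] | None = None,
                    within_balance: bool = True,
                    between_balance: bool = True) -> DecodingResult:
    """Decode target position along one dimension from an epochs set.

    Applies within-class balancing (before fold assignment; removed trials
    drop out of the analysis entirely), then runs the cross-validated
    per-timepoint LDA. ``window_ms`` optionally restricts decoding to a time
    window (e.g. the analysis window) to save computation.
    """
    if dimension not in DIMENSION_CLASSES:
        raise ValueError("dimension must be 'horizontal' or 'vertical'")
    classes = DIMENSION_CLASSES[dimension]
    col = "h_class" if dimension == "horizontal" else "v_class"
    rng = np.random.default_rng(seed)
    if within_balance:
        retained = balance_within_class(epochs.trials, dimension, rng)
    else:
        retained = np.arange(epochs.n_trials)
    y = epochs.trials[col].to_numpy()[retained] == classes[0]
    tsel = (epochs.time_mask(window_ms) if window_ms is not None
            else np.ones(epochs.n_samples, bool))
    X = epochs.data[np.ix_(retained, np.arange(epochs.n_channels),
                           np.flatnonzero(tsel))]

    dec = TimeResolvedDecoder(
        n_folds=folds, shrinkage=shrinkage, between_balance=between_balance,
        random_state=int(rng.integers(0, 2 ** 31 - 1)),
    ).fit(X, y)
    return DecodingResult(
        dimension=dimension, classes=classes,
        times_ms=epochs.times_ms[tsel], auc=dec.auc_,
        confidence=dec.confidence_, y=dec.y_, fold=dec.fold_,
        trial_index=retained, weights=dec.weights_,
        activation=dec.activation_,
    )
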