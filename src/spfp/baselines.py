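"""Reference potency predictors for benchmarking against the CVAE.

All regressors share one interface — ``fit(fingerprints, potencies)``
and ``predict(fingerprints)`` on (n, 2048) binary matrices — so the
evaluation harness treats them identically:

* Tanimoto-kernel support vector regression (SVR), the field's
  state of the art, with the cost parameter C tuned by 5-fold CV;
* random forest regression (RFR) with tree-count/split/leaf grids;
* a feed-forward deep neural network (DNN) regressor, tanh + Adam,
  tuned on an internal 90:10 train-validation split;
* k-nearest-neighbor (kNN) prediction by Tanimoto similarity;
* the mean regressor (MR) control; and
* y-randomization, which shuffles potencies across a class to give a
  chance-level control model.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .curation import ActivityClass

__all__ = [
    "tanimoto_kernel",
    "TanimotoSVR",
    "fit_svr",
    "fit_rfr",
    "fit_dnn",
    "TanimotoKNN",
    "knn_predict",
    "MeanRegressor",
    "mean_regressor",
    "y_randomize",
    "SVR_C_GRID",
    "RFR_GRID",
    "DNN_GRID",
    "KNN_K_GRID",
]

SVR_C_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1, 10, 100, 10000)
RFR_GRID = {
    "n_estimators": [50, 100, 200],
    "min_samples_split": [2, 3, 5, 10],
    "min_samples_leaf": [1, 2, 5, 10],
}
# hidden-layer depth 2 or 3, width sampled from the 100-500 range
DNN_GRID = {
    "hidden_layer_sizes": [(w,) * depth for depth in (2, 3) for w in (100, 300, 500)],
    "batch_size": [16, 64],
    "learning_rate_init": [0.1, 0.01, 0.001],
}
KNN_K_GRID = (1, 3, 5)


def tanimoto_kernel(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity |a AND b| / |a OR b| of bit vectors.

    Accepts single vectors or (n, d) matrices; returns a scalar or the
    (n, m) Gram matrix. The degenerate all-zero/all-zero pair is
    defined as 1.0 so K(x, x) = 1 holds for every x and the kernel
    matrix stays well-formed.
    """
    A = np.atleast_2d(np.asarray(A))
    B = np.atleast_2d(np.asarray(B))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"length mismatch: {A.shape[1]} vs {B.shape[1]}")
    Af = A.astype(np.float64)
    Bf = B.astype(np.float64)
    inter = Af @ Bf.T
    union = Af.sum(axis=1)[:, None] + Bf.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return K[0, 0] if K.size == 1 and A.shape[0] == 1 and B.shape[0] == 1 else K


class _ConstantPredictor:
    def __init__(self, value: float):
        self.value = float(value)

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.value)


class TanimotoSVR:
    """Support vector regression with a precomputed Tanimoto kernel.

    C is selected by internal 5-fold cross-validation minimizing MAE;
    epsilon stays at the library default unless overridden.
    """

    def __init__(self, c_grid=SVR_C_GRID, epsilon: float = 0.1, seed: int = 0, cv: int = 5):
        self.c_grid = tuple(c_grid)
        self.epsilon = epsilon
        self.seed = seed
        self.cv = cv
        self.best_C: float | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TanimotoSVR":
        X = np.asarray(X)
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            warnings.warn("constant training potencies; returning constant predictor")
            self._model = _ConstantPredictor(y[0])
            self.best_C = None
            return self
        self._train_X = X
        K = tanimoto_kernel(X, X)
        if len(self.c_grid) == 1 or len(y) < self.cv:
            self.best_C = self.c_grid[0]
        else:
            kf = KFold(self.cv, shuffle=True, random_state=self.seed)
            scores = []
            for C in self.c_grid:
                maes = []
                for tr, va in kf.split(X):
                    m = SVR(kernel="precomputed", C=C, epsilon=self.epsilon)
                    m.fit(K[np.ix_(tr, tr)], y[tr])
                    maes.append(np.mean(np.abs(m.predict(K[np.ix_(va, tr)]) - y[va])))
                scores.append(np.mean(maes))
            self.best_C = self.c_grid[int(np.argmin(scores))]
        self._model = SVR(kernel="precomputed", C=self.best_C, epsilon=self.epsilon)
        self._model.fit(K, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if isinstance(self._model, _ConstantPredictor):
            return self._model.predict(X)
        return self._model.predict(tanimoto_kernel(np.asarray(X), self._train_X))


def fit_svr(X, y, c_grid=SVR_C_GRID, seed: int = 0) -> TanimotoSVR:
    return TanimotoSVR(c_grid=c_grid, seed=seed).fit(X, y)


class _GridRFR:
    def __init__(self, grid=None, seed: int = 0, cv: int = 5):
        self.grid = grid or RFR_GRID
        self.seed = seed
        self.cv = cv

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            warnings.warn("constant training potencies; returning constant predictor")
            self._model = _ConstantPredictor(y[0])
            return self
        base = RandomForestRegressor(random_state=self.seed, n_jobs=1)
        sizes = [len(v) for v in self.grid.values()]
        if np.prod(sizes) == 1:
            self._model = base.set_params(**{k: v[0] for k, v in self.grid.items()})
            self._model.fit(X, y)
        else:
            gs = GridSearchCV(
                base, self.grid, scoring="neg_mean_absolute_error", cv=self.cv, n_jobs=1
            )
            gs.fit(X, y)
            self._model = gs.best_estimator_
            self.best_params_ = gs.best_params_
        return self

    def predict(self, X):
        return self._model.predict(X)


def fit_rfr(X, y, grid=None, seed: int = 0) -> _GridRFR:
    """Random forest regressor; grid tuned by 5-fold CV on MAE."""
    return _GridRFR(grid=grid, seed=seed).fit(X, y)


class _GridDNN:
    """Feed-forward regressor tuned on an internal 90:10 split."""

    def __init__(self, grid=None, seed: int = 0, max_iter: int = 200):
        self.grid = grid or DNN_GRID
        self.seed = seed
        self.max_iter = max_iter

    def _make(self, n_samples: int, **params) -> MLPRegressor:
        # early stopping needs a non-trivial validation split
        early = n_samples >= 30
        return MLPRegressor(
            activation="tanh",
            solver="adam",
            max_iter=self.max_iter,
            early_stopping=early,
            n_iter_no_change=10,
            random_state=self.seed,
            **params,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(y) < 20:
            warnings.warn("fewer than 20 training compounds for the DNN")
        import itertools

        keys = sorted(self.grid)
        combos = list(itertools.product(*(self.grid[k] for k in keys)))
        if len(combos) == 1:
            best = dict(zip(keys, combos[0]))
        else:
            Xtr, Xva, ytr, yva = train_test_split(
                X, y, test_size=0.1, random_state=self.seed
            )
            scores = []
            for combo in combos:
                params = dict(zip(keys, combo))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = self._make(len(ytr), **params).fit(Xtr, ytr)
                pred = m.predict(Xva)
                scores.append(np.mean(np.abs(pred - yva)) if np.all(np.isfinite(pred)) else np.inf)
            best = dict(zip(keys, combos[int(np.argmin(scores))]))
        self.best_params_ = best
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._model = self._make(len(y), **best).fit(X, y)
        if not np.all(np.isfinite(self._model.loss_curve_)):
            raise RuntimeError(
                f"DNN training diverged at epoch {len(self._model.loss_curve_)}"
            )
        return self

    def predict(self, X):
        return self._model.predict(np.asarray(X, dtype=float))


def fit_dnn(X, y, grid=None, seed: int = 0) -> _GridDNN:
    return _GridDNN(grid=grid, seed=seed).fit(X, y)


class TanimotoKNN:
    """k-nearest-neighbor potency prediction by Tanimoto similarity.

    The prediction is the mean potency of the k most similar training
    compounds (1-NN: the single neighbor's value). Similarity ties are
    broken by ascending training index, so output is deterministic.
    k may be tuned over a grid by 5-fold CV, or fixed.
    """

    def __init__(self, k: int | None = None, k_grid=KNN_K_GRID, seed: int = 0, cv: int = 5):
        self.k = k
        self.k_grid = tuple(k_grid)
        self.seed = seed
        self.cv = cv

    def fit(self, X, y):
        self._X = np.asarray(X)
        self._y = np.asarray(y, dtype=float)
        if self.k is None:
            if len(self.k_grid) == 1 or len(self._y) < self.cv + 1:
                self.k = self.k_grid[0]
            else:
                kf = KFold(self.cv, shuffle=True, random_state=self.seed)
                scores = []
                for k in self.k_grid:
                    maes = []
                    for tr, va in kf.split(self._X):
                        pred = knn_predict(self._X[va], self._X[tr], self._y[tr], k)
                        maes.append(np.mean(np.abs(pred - self._y[va])))
                    scores.append(np.mean(maes))
                self.k = self.k_grid[int(np.argmin(scores))]
        return self

    def predict(self, X):
        return knn_predict(np.asarray(X), self._X, self._y, self.k)


def knn_predict(
    queries: np.ndarray, train_X: np.ndarray, train_y: np.ndarray, k: int
) -> np.ndarray:
    """Mean potency of the k most Tanimoto-similar training compounds."""
    train_y = np.asarray(train_y, dtype=float)
    n_train = len(train_y)
    if n_train == 0:
        raise ValueError("empty training set")
    if k > n_train:
        warnings.warn(f"k={k} exceeds training size {n_train}; capped")
        k = n_train
    sims = np.atleast_2d(tanimoto_kernel(queries, train_X))
    # stable argsort on -sim keeps ascending-index order among ties
    order = np.argsort(-sims, axis=1, kind="stable")[:, :k]
    return train_y[order].mean(axis=1)


class MeanRegressor:
    """Control model: predicts the training-set mean for every query."""

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            raise ValueError("empty training set")
        self.mean_ = float(y.mean())
        return self

    def predict(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.mean_)


def mean_regressor(y) -> MeanRegressor:
    m = MeanRegressor()
    m.fit(np.empty((len(y), 0)), y)
    return m


def y_randomize(activity_class: ActivityClass, seed: int = 0) -> ActivityClass:
    """Shuffle potency values across a class (y-randomization control).

    Structures are untouched and the multiset of potencies conserved;
    the permutation is reproducible from the seed.
    """
    if len(activity_class) < 2:
        raise ValueError("need at least 2 compounds to shuffle")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(activity_class))
    shuffled = activity_class.potencies[perm]
    records = [
        replace(rec, pIC50=float(shuffled[i]))
        for i, rec in enumerate(activity_class.records)
    ]
    return ActivityClass(activity_class.target_id, records, activity_class.target_name)
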