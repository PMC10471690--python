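"""Pluggable per-question classifier backends.

Every backend implements the same contract::

    fit(X, y, class_weights, hyperparams, seed) -> self
    predict_scores(X) -> (n, len(labels_)) score matrix over ``labels_``

``labels_`` is the ordered set of labels observed in training; scores are
non-negative and row-normalised where probabilistic.  Four backends ship:

``linear``
    weighted multinomial logistic regression; fast, deterministic, the
    default for testing and batch generation.
``mlp``
    feed-forward network with per-class weighting, dropout, and early
    stopping on validation macro recall.
``xgb``
    gradient-boosted trees (optional; requires xgboost).
``rounded``
    ridge regression whose continuous prediction is rounded half away from
    zero and clamped to the item's answer rank - the regression baseline the
    classification backends are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HyperParams",
    "STEP_DEFAULT_HYPERPARAMS",
    "BackendContractError",
    "make_backend",
    "round_half_away",
    "ConstantBackend",
    "LinearBackend",
    "MLPBackend",
    "XGBBackend",
    "RoundedRegressorBackend",
]


class BackendContractError(RuntimeError):
    """A backend returned scores inconsistent with its observed labels."""


@dataclass(frozen=True)
class HyperParams:
    """Network-style hyperparameters; non-network backends use what applies.

    ``neurons`` lists hidden-layer widths; ``dropout_layers`` counts how many
    of the trailing hidden layers carry dropout; training stops early when
    validation macro recall has not improved for ``early_stop_patience``
    epochs.
    """

    neurons: tuple[int, ...] = (64, 32)
    dropout_layers: int = 1
    dropout_rate: float = 0.2
    epochs: int = 200
    early_stop_patience: int = 25
    monitor: str = "val_recall"
    validation_fraction: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 64

    @property
    def layers(self) -> int:
        return len(self.neurons)


# Per-step defaults for the five-step battery cascade (network backend).
STEP_DEFAULT_HYPERPARAMS: tuple[HyperParams, ...] = (
    HyperParams(neurons=(400, 400, 200, 100), dropout_layers=2, epochs=4000, early_stop_patience=400),
    HyperParams(neurons=(1500, 1500, 750), dropout_layers=2, epochs=3000, early_stop_patience=300),
    HyperParams(neurons=(1000, 1000, 500, 250), dropout_layers=3, epochs=3000, early_stop_patience=300),
    HyperParams(neurons=(1000, 1000, 500, 250), dropout_layers=3, epochs=3000, early_stop_patience=300),
    HyperParams(neurons=(500, 500, 250, 100), dropout_layers=2, epochs=3000, early_stop_patience=400),
)


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (2.5 -> 3, -2.5 -> -3)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _check_fit_args(X, y, class_weights):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y) or len(y) == 0:
        raise ValueError("X and y must be non-empty and aligned")
    labels = np.unique(y)
    if class_weights is None:
        class_weights = {int(l): 1.0 for l in labels}
    missing = [l for l in labels if int(l) not in class_weights]
    if missing:
        raise BackendContractError(f"class_weights missing observed labels {missing}")
    return X, y, labels, class_weights


class _ScoresMixin:
    labels_: np.ndarray

    def _validate_scores(self, scores: np.ndarray, n: int) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (n, len(self.labels_)):
            raise BackendContractError(
                f"score matrix shape {scores.shape} does not match "
                f"(n={n}, labels={len(self.labels_)})"
            )
        return scores


class ConstantBackend(_ScoresMixin):
    """Degenerate predictor for targets with a single observed class."""

    def fit(self, X, y, class_weights=None, hyperparams=None, seed=0):
        _, y, labels, _ = _check_fit_args(X, y, class_weights)
        self.labels_ = labels
        return self

    def predict_scores(self, X) -> np.ndarray:
        n = len(np.asarray(X))
        return self._validate_scores(np.ones((n, len(self.labels_))), n)


class LinearBackend(_ScoresMixin):
    """Class-weighted multinomial logistic regression (deterministic)."""

    def __init__(self, C: float = 1.0, max_iter: int = 1000):
        self.C = C
        self.max_iter = max_iter

    def fit(self, X, y, class_weights=None, hyperparams=None, seed=0):
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        X, y, labels, class_weights = _check_fit_args(X, y, class_weights)
        self.labels_ = labels
        if len(labels) == 1:
            self._const = ConstantBackend().fit(X, y)
            return self
        self._const = None
        self._scaler = StandardScaler().fit(X)
        self._clf = LogisticRegression(
            C=self.C,
            max_iter=self.max_iter,
            class_weight={int(l): class_weights[int(l)] for l in labels},
        ).fit(self._scaler.transform(X), y)
        return self

    def predict_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._const is not None:
            return self._const.predict_scores(X)
        proba = self._clf.predict_proba(self._scaler.transform(X))
        # sklearn orders classes_ ascending, matching labels_
        return self._validate_scores(proba, len(X))


class MLPBackend(_ScoresMixin):
    """Feed-forward softmax classifier trained with class-weighted
    cross-entropy, inverted dropout on the trailing hidden layers, Adam, and
    early stopping on validation macro recall (best weights restored)."""

    def fit(self, X, y, class_weights=None, hyperparams=None, seed=0):
        hp = hyperparams or HyperParams(neurons=(32,), epochs=100, early_stop_patience=20)
        X, y, labels, class_weights = _check_fit_args(X, y, class_weights)
        self.labels_ = labels
        if len(labels) == 1:
            self._const = ConstantBackend().fit(X, y)
            return self
        self._const = None
        rng = np.random.default_rng(seed)
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        Xs = (X - self._mu) / self._sd
        label_pos = {int(l): i for i, l in enumerate(labels)}
        yi = np.array([label_pos[int(v)] for v in y])
        w = np.array([class_weights[int(v)] for v in y], dtype=float)

        # stratified-ish validation split
        n = len(Xs)
        n_val = max(1, int(round(hp.validation_fraction * n))) if n >= 5 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0 or len(np.unique(yi[tr_idx])) < len(labels):
            tr_idx, val_idx = perm, perm  # tiny data: validate on train
        Xtr, ytr, wtr = Xs[tr_idx], yi[tr_idx], w[tr_idx]
        Xval, yval = Xs[val_idx], yi[val_idx]

        sizes = [Xs.shape[1], *hp.neurons, len(labels)]
        params = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            params.append(
                [rng.normal(0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)),
                 np.zeros(fan_out)]
            )
        m_adam = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params]
        v_adam = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params]
        dropout_from = len(hp.neurons) - min(hp.dropout_layers, len(hp.neurons))

        def forward(xb, train: bool):
            acts, caches = xb, []
            for li, (W, b) in enumerate(params):
                zz = acts @ W + b
                if li < len(params) - 1:
                    aa = np.maximum(zz, 0.0)
                    mask = None
                    if train and hp.dropout_rate > 0 and li >= dropout_from:
                        mask = (rng.random(aa.shape) >= hp.dropout_rate) / (1 - hp.dropout_rate)
                        aa = aa * mask
                    caches.append((acts, zz, mask))
                    acts = aa
                else:
                    caches.append((acts, zz, None))
            logits = caches[-1][1]
            logits = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            return p, caches

        def macro_recall(Xv, yv):
            p, _ = forward(Xv, train=False)
            pred = p.argmax(axis=1)
            recs = []
            for k in range(len(labels)):
                mask = yv == k
                if mask.any():
                    recs.append((pred[mask] == k).mean())
            return float(np.mean(recs)) if recs else 0.0

        best = (-np.inf, [ [W.copy(), b.copy()] for W, b in params ])
        patience_left = hp.early_stop_patience
        t = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for epoch in range(hp.epochs):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), hp.batch_size):
                idx = order[start:start + hp.batch_size]
                xb, yb, wb = Xtr[idx], ytr[idx], wtr[idx]
                p, caches = forward(xb, train=True)
                wsum = wb.sum() or 1.0
                delta = p.copy()
                delta[np.arange(len(yb)), yb] -= 1.0
                delta *= (wb / wsum)[:, None]
                t += 1
                for li in range(len(params) - 1, -1, -1):
                    a_in, zz, mask = caches[li]
                    gW = a_in.T @ delta
                    gb = delta.sum(axis=0)
                    if li > 0:
                        delta = delta @ params[li][0].T
                        _, z_prev, mask_prev = caches[li - 1]
                        if mask_prev is not None:
                            delta = delta * mask_prev
                        delta = delta * (z_prev > 0)
                    for slot, g in ((0, gW), (1, gb)):
                        m_adam[li][slot] = beta1 * m_adam[li][slot] + (1 - beta1) * g
                        v_adam[li][slot] = beta2 * v_adam[li][slot] + (1 - beta2) * g * g
                        mhat = m_adam[li][slot] / (1 - beta1 ** t)
                        vhat = v_adam[li][slot] / (1 - beta2 ** t)
                        params[li][slot] -= hp.learning_rate * mhat / (np.sqrt(vhat) + eps)
            rec = macro_recall(Xval, yval)
            if rec > best[0] + 1e-12:
                best = (rec, [[W.copy(), b.copy()] for W, b in params])
                patience_left = hp.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        self._params = best[1]
        self._hp = hp
        return self

    def predict_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._const is not None:
            return self._const.predict_scores(X)
        a = (X - self._mu) / self._sd
        for li, (W, b) in enumerate(self._params):
            z = a @ W + b
            a = np.maximum(z, 0.0) if li < len(self._params) - 1 else z
        z = a - a.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        return self._validate_scores(p, len(X))


class XGBBackend(_ScoresMixin):
    """Gradient-boosted tree classifier (xgboost) with per-sample class weights."""

    def __init__(self, n_estimators: int = 100, max_depth: int = 4, learning_rate: float = 0.3):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate

    def fit(self, X, y, class_weights=None, hyperparams=None, seed=0):
        import xgboost as xgb

        X, y, labels, class_weights = _check_fit_args(X, y, class_weights)
        self.labels_ = labels
        if len(labels) == 1:
            self._const = ConstantBackend().fit(X, y)
            return self
        self._const = None
        label_pos = {int(l): i for i, l in enumerate(labels)}
        yi = np.array([label_pos[int(v)] for v in y])
        w = np.array([class_weights[int(v)] for v in y], dtype=float)
        self._clf = xgb.XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            objective="multi:softprob" if len(labels) > 2 else "binary:logistic",
            random_state=int(seed) % (2**31),
            n_jobs=1,
            verbosity=0,
        )
        self._clf.fit(X, yi, sample_weight=w)
        return self

    def predict_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._const is not None:
            return self._const.predict_scores(X)
        proba = self._clf.predict_proba(X)
        if proba.ndim == 1:  # binary gives (n,)
            proba = np.column_stack([1 - proba, proba])
        return self._validate_scores(proba, len(X))


class RoundedRegressorBackend(_ScoresMixin):
    """Ridge regression treated as an ordinal predictor.

    The continuous prediction is rounded half away from zero, then clamped to
    the item's answer rank.  Scores are a one-hot encoding of the resulting
    label, so argmax and sampling both return the deterministic prediction.
    """

    def __init__(self, answer_min: int | None = None, answer_max: int | None = None, alpha: float = 1.0):
        self.answer_min = answer_min
        self.answer_max = answer_max
        self.alpha = alpha

    def fit(self, X, y, class_weights=None, hyperparams=None, seed=0):
        from sklearn.linear_model import Ridge

        X, y, labels, _ = _check_fit_args(X, y, class_weights)
        lo = self.answer_min if self.answer_min is not None else int(labels.min())
        hi = self.answer_max if self.answer_max is not None else int(labels.max())
        self.labels_ = np.arange(lo, hi + 1)
        self._lo, self._hi = lo, hi
        self._reg = Ridge(alpha=self.alpha).fit(X, y.astype(float))
        return self

    def predict_labels(self, X) -> np.ndarray:
        pred = round_half_away(self._reg.predict(np.asarray(X, dtype=float)))
        return np.clip(pred, self._lo, self._hi).astype(int)

    def predict_scores(self, X) -> np.ndarray:
        lab = self.predict_labels(X)
        scores = np.zeros((len(lab), len(self.labels_)))
        scores[np.arange(len(lab)), lab - self._lo] = 1.0
        return self._validate_scores(scores, len(lab))


_BACKENDS = {
    "linear": LinearBackend,
    "mlp": MLPBackend,
    "xgb": XGBBackend,
    "rounded": RoundedRegressorBackend,
}


def make_backend(kind: str, **kwargs):
    """Instantiate a backend by name: linear | mlp | xgb | rounded."""
    try:
        cls = _BACKENDS[kind]
    except KeyError:
        raise ValueError(f"unknown backend {kind!r}; choose from {sorted(_BACKENDS)}") from None
    return cls(**kwargs)
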