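"""Comparator regressors sharing the Conv_gMLP fit/predict contract.

Deep baselines (a ReLU MLP and a 1-D CNN) run on the package's autodiff
engine; gradient-boosting baselines wrap LightGBM and XGBoost.  Boosting
hyperparameters are validated against the search-space bounds the
evaluation module uses and clamped (with a warning) when out of range.

The CatBoost comparator is not provided: no CatBoost library is available
in the supported environment, and gradient boosting is a comparator here,
not the contribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import Adam, Parameter, Tensor, conv1d, maxpool1d

BASELINE_KINDS = ("mlp", "cnn1d", "lightgbm", "xgboost")

#: Hyperparameter bounds used for clamping (mirrors the TPE search spaces).
GBDT_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "lightgbm": {
        "num_leaves": (16, 96),
        "min_data_in_leaf": (2, 60),
        "feature_fraction": (0.75, 1.0),
        "learning_rate": (5e-3, 0.1),
    },
    "xgboost": {
        "learning_rate": (5e-3, 0.1),
        "depth": (3, 10),
        "min_child_weight": (1, 5),
        "colsample_bytree": (0.5, 1.0),
    },
}


@dataclass
class BaselineSpec:
    kind: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "catboost":
            raise ValueError("catboost baseline is not provided in this package")
        if self.kind not in BASELINE_KINDS:
            raise ValueError(f"kind must be one of {BASELINE_KINDS}")


def _clamp(kind: str, params: dict) -> dict:
    out = dict(params)
    for name, (lo, hi) in GBDT_BOUNDS[kind].items():
        if name in out and not lo <= out[name] <= hi:
            clamped = min(max(out[name], lo), hi)
            warnings.warn(
                f"{kind} hyperparameter {name}={out[name]} outside "
                f"[{lo}, {hi}]; clamped to {clamped}", stacklevel=3)
            out[name] = clamped
    for name in GBDT_BOUNDS[kind]:
        if name in out and isinstance(GBDT_BOUNDS[kind][name][0], int):
            out[name] = int(round(out[name]))
    return out


class _NetRegressor:
    """Shared minibatch-Adam trainer for the autodiff-backed baselines."""

    def __init__(self, learning_rate: float = 5e-4, batch_size: int = 96,
                 max_epochs: int = 200, patience: int = 20,
                 val_fraction: float = 0.1, seed: int = 0):
        self.learning_rate = learning_rate
        self.batch_size = int(batch_size)
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    # subclasses define _build(n_features) and _forward(X) -> Tensor (B,)
    def parameters(self) -> list[Parameter]:
        return self._params

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return np.concatenate([
            self._forward(X[i:i + batch_size]).data
            for i in range(0, len(X), batch_size)
        ])

    def fit(self, X: np.ndarray, y: np.ndarray, groups=None):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        y = np.asarray(y, dtype=np.float64).ravel()
        rng = np.random.default_rng(self.seed)
        self._build(X.shape[1], rng)

        idx = rng.permutation(len(X))
        n_val = max(1, int(round(self.val_fraction * len(X))))
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        if len(tr_idx) == 0:
            tr_idx = val_idx
        Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

        opt = Adam(self._params, lr=self.learning_rate)
        best, best_state, bad = math.inf, None, 0
        bs = max(2, min(self.batch_size, len(Xtr)))
        for _ in range(self.max_epochs):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), bs):
                sel = order[start:start + bs]
                pred = self._forward(Xtr[sel])
                loss = ((pred - Tensor(ytr[sel])) ** 2).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
            val_mae = float(np.mean(np.abs(self.predict(Xval) - yval)))
            if val_mae < best - 1e-9:
                best = val_mae
                best_state = [p.data.copy() for p in self._params]
                bad = 0
            else:
                bad += 1
                if bad >= self.patience:
                    break
        if best_state is not None:
            for p, d in zip(self._params, best_state):
                p.data = d
        return self


class MLPRegressorNet(_NetRegressor):
    """Fully connected ReLU network: num_layers hidden layers of num_ffn units."""

    def __init__(self, num_layers: int = 2, num_ffn: int = 128, **kwargs):
        super().__init__(**kwargs)
        self.num_layers = int(num_layers)
        self.num_ffn = int(num_ffn)

    def _build(self, n_features: int, rng: np.random.Generator) -> None:
        dims = [n_features] + [self.num_ffn] * self.num_layers + [1]
        self._weights, self._biases = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / math.sqrt(d_in)
            self._weights.append(Parameter(rng.uniform(-bound, bound, (d_in, d_out))))
            self._biases.append(Parameter(np.zeros(d_out)))
        self._params = self._weights + self._biases

    def _forward(self, X: np.ndarray) -> Tensor:
        h: Tensor = Tensor(X)
        last = len(self._weights) - 1
        for i, (w, b) in enumerate(zip(self._weights, self._biases)):
            h = h @ w + b
            if i < last:
                h = h.relu()
        return h.reshape(h.shape[0])

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self._params))


class CNN1DRegressorNet(_NetRegressor):
    """1-D CNN on the 480-feature vector treated as a length-480 sequence.

    Repo convention: two conv stages (32 then 64 filters, kernel 7, same
    padding, max-pool 2), followed by two linear+ReLU modules and a scalar
    head.
    """

    def __init__(self, channels: Sequence[int] = (32, 64), kernel: int = 7,
                 hidden: Sequence[int] = (128, 64), **kwargs):
        super().__init__(**kwargs)
        self.channels = tuple(channels)
        self.kernel = int(kernel)
        self.hidden = tuple(hidden)

    def _build(self, n_features: int, rng: np.random.Generator) -> None:
        self.n_features = n_features
        self._convs = []
        c_in, length = 1, n_features
        for c_out in self.channels:
            bound = 1.0 / math.sqrt(c_in * self.kernel)
            w = Parameter(rng.uniform(-bound, bound, (c_out, c_in, self.kernel)))
            b = Parameter(np.zeros(c_out))
            self._convs.append((w, b))
            c_in = c_out
            length //= 2  # pool halves the length per stage
        flat = c_in * length
        dims = [flat] + list(self.hidden) + [1]
        self._linears = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / math.sqrt(d_in)
            self._linears.append((
                Parameter(rng.uniform(-bound, bound, (d_in, d_out))),
                Parameter(np.zeros(d_out)),
            ))
        self._params = [t for pair in self._convs + self._linears for t in pair]

    def _forward(self, X: np.ndarray) -> Tensor:
        B = X.shape[0]
        h: Tensor = Tensor(X).reshape(B, 1, X.shape[1])
        for w, b in self._convs:
            h = conv1d(h, w, b, padding=self.kernel // 2).relu()
            h = maxpool1d(h, 2)
        h = h.reshape(B, h.shape[1] * h.shape[2])
        last = len(self._linears) - 1
        for i, (w, b) in enumerate(self._linears):
            h = h @ w + b
            if i < last:
                h = h.relu()
        return h.reshape(B)


def build_mlp(spec: BaselineSpec) -> MLPRegressorNet:
    if spec.kind != "mlp":
        raise ValueError("spec.kind must be 'mlp'")
    return MLPRegressorNet(**spec.hyperparams)


def build_cnn1d(spec: BaselineSpec) -> CNN1DRegressorNet:
    if spec.kind != "cnn1d":
        raise ValueError("spec.kind must be 'cnn1d'")
    return CNN1DRegressorNet(**spec.hyperparams)


def build_gbdt(spec: BaselineSpec):
    if spec.kind not in ("lightgbm", "xgboost"):
        raise ValueError("spec.kind must be 'lightgbm' or 'xgboost'")
    hp = _clamp(spec.kind, spec.hyperparams)
    n_estimators = int(hp.pop("n_estimators", 200))
    seed = int(hp.pop("seed", 0))
    if spec.kind == "lightgbm":
        from lightgbm import LGBMRegressor

        return _SkWrapper(LGBMRegressor(
            num_leaves=hp.get("num_leaves", 31),
            min_child_samples=hp.get("min_data_in_leaf", 20),
            colsample_bytree=hp.get("feature_fraction", 1.0),
            learning_rate=hp.get("learning_rate", 0.05),
            n_estimators=n_estimators, random_state=seed, verbose=-1,
        ))
    from xgboost import XGBRegressor

    return _SkWrapper(XGBRegressor(
        learning_rate=hp.get("learning_rate", 0.05),
        max_depth=int(hp.get("depth", 6)),
        min_child_weight=hp.get("min_child_weight", 1),
        colsample_bytree=hp.get("colsample_bytree", 1.0),
        n_estimators=n_estimators, random_state=seed, verbosity=0,
    ))


class _SkWrapper:
    """Adapter accepting (and ignoring) a ``groups`` kwarg in ``fit``."""

    def __init__(self, est):
        self.est = est

    def fit(self, X, y, groups=None):
        self.est.fit(np.asarray(X), np.asarray(y))
        return self

    def predict(self, X):
        return np.asarray(self.est.predict(np.asarray(X)), dtype=np.float64)


def build(spec: BaselineSpec):
    """Dispatch on ``spec.kind``; every return value has fit/predict."""
    if spec.kind == "mlp":
        return build_mlp(spec)
    if spec.kind == "cnn1d":
        return build_cnn1d(spec)
    return build_gbdt(spec)
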