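"""The convolutional gated-MLP (Conv_gMLP) severity regressor.

Architecture, for an input PLI feature vector x in R^(1 x d_feature):

1. **Channel expansion** — a kernel-size-1, stride-1 1-D convolution with
   ``d_channel`` kernels.  With a single input channel each kernel reduces
   to a scalar weight and bias, so row k of the output is ``w_k * x + b_k``
   and the result A has shape (d_channel, d_feature).  A is the activation
   map that gradient-based attribution targets.
2. **Stacked gMLP blocks** operating on X in R^(d_feature x d_channel)
   ("spatial" = the feature axis, "channel" = the expanded axis):

       shortcut = X
       X = norm(X)
       Z = GELU(X U)            # channel projection to width 2*d_ffn
       Z~ = SGU(Z)              # spatial gating, width halves to d_ffn
       Y = Z~ V                 # channel projection back to d_channel
       return Y + shortcut

   The Spatial Gating Unit splits Z along the channel axis into u and v,
   normalizes v, applies a spatial linear map ``W^T v + b`` (W is
   d_feature x d_feature, b broadcast over channels), and gates:
   ``u * (W^T v + b)``.  W is initialized near zero and b to one, so each
   block starts as (approximately) an identity-gated linear layer and
   learns cross-feature interactions gradually.
3. **Aggregation head** — average-pool over the feature (spatial) axis,
   then a linear map d_channel -> 1.

The SC ablation variant applies the spatial gating before the channel
projections inside each block (gate on the d_channel-wide stream, then
FFN); the proposed ordering (channel projection first) is variant CS.

Training minimizes mean squared error with Adam, carving a 10% validation
split (grouped by subject when group labels are given) from the training
data and early-stopping on validation MAE.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import Adam, Parameter, Tensor

NORMS = ("batch", "layer", "none")
VARIANTS = ("CS", "SC")


@dataclass
class ModelSpec:
    """Conv_gMLP architecture + training hyperparameters.

    Defaults are the configuration found best by hyperparameter search in
    the study this package operationalizes (d_channel 64, 8 layers,
    d_ffn 256, batch size 96, learning rate 5.5e-4, BatchNorm).
    """

    d_feature: int = 480
    d_channel: int = 64
    num_layers: int = 8
    d_ffn: int = 256
    norm: str = "batch"
    variant: str = "CS"
    init_eps: float = 1e-3
    seed: int = 0
    # training
    learning_rate: float = 5.5e-4
    batch_size: int = 96
    max_epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.1
    standardize: bool = False

    def __post_init__(self) -> None:
        for name in ("d_feature", "d_channel", "num_layers", "d_ffn"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.norm not in NORMS:
            raise ValueError(f"norm must be one of {NORMS}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.variant == "SC" and self.d_channel % 2:
            raise ValueError("variant SC requires even d_channel")


class _Norm:
    """Normalization applied to (B, S, C) activations.

    ``batch``: per C-channel statistics over the (batch, spatial) axes with
    running averages used at inference.  ``layer``: per-position statistics
    over the channel axis.  ``none``: identity.
    """

    def __init__(self, kind: str, width: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        self.kind = kind
        self.eps = eps
        self.momentum = momentum
        if kind in ("batch", "layer"):
            self.gamma = Parameter(np.ones(width))
            self.beta = Parameter(np.zeros(width))
        if kind == "batch":
            self.running_mean = np.zeros(width)
            self.running_var = np.ones(width)

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta] if self.kind != "none" else []

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if self.kind == "none":
            return x
        if self.kind == "layer":
            mu = x.mean(axis=-1, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
            xhat = (x - mu) * (var + self.eps) ** -0.5
            return xhat * self.gamma + self.beta
        # batch norm over (B, S) per channel
        if training:
            mu = x.mean(axis=(0, 1), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 1), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean[None, None, :])
            var = Tensor(self.running_var[None, None, :])
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


def _fan_in_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class _Block:
    """One gMLP block (CS or SC wiring)."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        S, C, F = spec.d_feature, spec.d_channel, spec.d_ffn
        self.spec = spec
        self.norm1 = _Norm(spec.norm, C)
        if spec.variant == "CS":
            self.U = Parameter(_fan_in_uniform(rng, C, (C, 2 * F)))
            self.bU = Parameter(np.zeros(2 * F))
            self.norm_v = _Norm(spec.norm, F)
            self.V = Parameter(_fan_in_uniform(rng, F, (F, C)))
        else:  # SC: gate the d_channel stream first, then the FFN
            half = C // 2
            self.U = Parameter(_fan_in_uniform(rng, half, (half, 2 * F)))
            self.bU = Parameter(np.zeros(2 * F))
            self.norm_v = _Norm(spec.norm, half)
            self.V = Parameter(_fan_in_uniform(rng, 2 * F, (2 * F, C)))
        self.bV = Parameter(np.zeros(C))
        self.W_sgu = Parameter(
            rng.uniform(-spec.init_eps, spec.init_eps, size=(S, S)))
        self.b_sgu = Parameter(np.ones(S))

    def parameters(self) -> list[Parameter]:
        ps = [self.U, self.bU, self.V, self.bV, self.W_sgu, self.b_sgu]
        return ps + self.norm1.parameters() + self.norm_v.parameters()

    def _sgu(self, z: Tensor, training: bool) -> Tensor:
        half = z.shape[-1] // 2
        u = z[:, :, :half]
        v = z[:, :, half:]
        v = self.norm_v(v, training)
        gate = self.W_sgu.T @ v + self.b_sgu.reshape(1, -1, 1)
        return u * gate

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        shortcut = x
        x = self.norm1(x, training)
        if self.spec.variant == "CS":
            z = (x @ self.U + self.bU).gelu()
            z = self._sgu(z, training)
            y = z @ self.V + self.bV
        else:
            z = self._sgu(x, training)
            z = (z @ self.U + self.bU).gelu()
            y = z @ self.V + self.bV
        return y + shortcut


class ConvGMLP:
    """Channel-expansion convolution + stacked gMLP blocks + linear head."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        C = spec.d_channel
        self.w_expand = Parameter(_fan_in_uniform(rng, 1, (C,)))
        self.b_expand = Parameter(np.zeros(C))
        self.blocks = [_Block(spec, rng) for _ in range(spec.num_layers)]
        self.w_head = Parameter(_fan_in_uniform(rng, C, (C,)))
        self.b_head = Parameter(np.zeros(1))
        self.last_activation: Tensor | None = None  # A, (B, C, S)
        self._x_mean = np.zeros(spec.d_feature)
        self._x_std = np.ones(spec.d_feature)

    # -- forward -------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        ps = [self.w_expand, self.b_expand, self.w_head, self.b_head]
        for blk in self.blocks:
            ps += blk.parameters()
        return ps

    def channel_expand(self, x: Tensor) -> Tensor:
        """Kernel-1 Conv1D: (B, S) -> (B, C, S), row k = w_k * x + b_k."""
        b, s = x.shape
        return (x.reshape(b, 1, s) * self.w_expand.reshape(1, -1, 1)
                + self.b_expand.reshape(1, -1, 1))

    def forward(self, x, training: bool = False,
                a_override: np.ndarray | None = None) -> Tensor:
        """Forward pass; ``a_override`` substitutes the channel-expansion
        activation map (used to validate attribution gradients)."""
        x = x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x))
        if x.shape[-1] != self.spec.d_feature:
            raise ValueError(
                f"expected {self.spec.d_feature} features, got {x.shape[-1]}")
        if self.spec.standardize:
            x = (x - self._x_mean) * (1.0 / self._x_std)
        if a_override is not None:
            a = Tensor(a_override, requires_grad=True)
        else:
            a = self.channel_expand(x)  # (B, C, S)
        self.last_activation = a
        h = a.transpose(0, 2, 1)  # (B, S, C)
        for blk in self.blocks:
            h = blk(h, training)
        pooled = h.mean(axis=1)  # average pool over the spatial axis
        out = pooled @ self.w_head + self.b_head
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite model output")
        return out

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        outs = [self.forward(X[i:i + batch_size]).data
                for i in range(0, len(X), batch_size)]
        return np.concatenate(outs)

    # -- (de)serialization --------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"p{i}"] = p.data.copy()
        for j, blk in enumerate(self.blocks):
            for name in ("norm1", "norm_v"):
                nrm = getattr(blk, name)
                if nrm.kind == "batch":
                    state[f"b{j}.{name}.rmean"] = nrm.running_mean.copy()
                    state[f"b{j}.{name}.rvar"] = nrm.running_var.copy()
        state["x_mean"] = self._x_mean.copy()
        state["x_std"] = self._x_std.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.array(state[f"p{i}"], dtype=np.float64)
        for j, blk in enumerate(self.blocks):
            for name in ("norm1", "norm_v"):
                nrm = getattr(blk, name)
                if nrm.kind == "batch":
                    nrm.running_mean = np.array(state[f"b{j}.{name}.rmean"])
                    nrm.running_var = np.array(state[f"b{j}.{name}.rvar"])
        self._x_mean = np.array(state["x_mean"])
        self._x_std = np.array(state["x_std"])

    # convenience sklearn-style interface used by the evaluation module
    def fit(self, X: np.ndarray, y: np.ndarray, groups=None):
        train(X, y, self.spec, groups=groups, model=self)
        return self


@dataclass
class TrainLog:
    """Per-epoch training record."""

    train_loss: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _val_split(n: int, groups, frac: float, rng: np.random.Generator):
    if groups is not None:
        uniq = np.unique(groups)
        rng.shuffle(uniq)
        n_val = max(1, int(round(frac * len(uniq))))
        val_groups = set(uniq[:n_val].tolist())
        val_mask = np.array([g in val_groups for g in groups])
    else:
        idx = rng.permutation(n)
        n_val = max(1, int(round(frac * n)))
        val_mask = np.zeros(n, dtype=bool)
        val_mask[idx[:n_val]] = True
    return ~val_mask, val_mask


def train(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec | None = None,
    *,
    groups: Sequence | None = None,
    model: ConvGMLP | None = None,
    verbose: bool = False,
) -> tuple[ConvGMLP, TrainLog]:
    """Fit a Conv_gMLP by Adam on the MSE loss with early stopping.

    A ``spec.val_fraction`` share of the training data (whole subjects when
    ``groups`` is given) is held out; the parameters of the best
    validation-MAE epoch are restored at the end.  Deterministic given the
    spec seed and inputs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(X) < 2:
        raise ValueError("need at least 2 training samples")
    if spec is None:
        spec = model.spec if model is not None else ModelSpec(d_feature=X.shape[1])
    if model is None:
        model = ConvGMLP(spec)
    rng = np.random.default_rng(spec.seed + 1)

    if spec.standardize:
        model._x_mean = X.mean(axis=0)
        model._x_std = X.std(axis=0) + 1e-12

    tr_mask, val_mask = _val_split(len(X), groups, spec.val_fraction, rng)
    Xtr, ytr = X[tr_mask], y[tr_mask]
    Xval, yval = X[val_mask], y[val_mask]
    if len(Xtr) == 0 or len(Xval) == 0:
        raise ValueError("validation split left an empty partition")

    # warm-start the head bias at the training-label mean so early epochs
    # fit residuals rather than the raw offset
    model.b_head.data[:] = ytr.mean()

    opt = Adam(model.parameters(), lr=spec.learning_rate)
    log = TrainLog()
    best = math.inf
    best_state: dict[str, np.ndarray] | None = None
    bad_epochs = 0
    bs = max(2, min(spec.batch_size, len(Xtr)))

    for epoch in range(spec.max_epochs):
        order = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(Xtr), bs):
            idx = order[start:start + bs]
            if len(idx) < 2 and spec.norm == "batch":
                continue  # batch statistics undefined for a single sample
            pred = model.forward(Xtr[idx], training=True)
            loss = ((pred - Tensor(ytr[idx])) ** 2).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_mae = float(np.mean(np.abs(model.predict(Xval) - yval)))
        log.train_loss.append(float(np.mean(losses)) if losses else math.nan)
        log.val_mae.append(val_mae)
        if verbose:
            print(f"epoch {epoch:3d}  train_mse={log.train_loss[-1]:.4f}  "
                  f"val_mae={val_mae:.4f}")
        if val_mae < best - 1e-9:
            best = val_mae
            best_state = model.state_dict()
            log.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= spec.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log
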