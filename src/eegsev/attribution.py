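"""Grad-RAM feature attribution for the trained regressor.

Grad-CAM's class score is replaced by a regression target that grows as
the prediction error shrinks,

    y_e = 1 / ((yhat - y)^2 + 1e-9),

so gradients are largest where the model is accurate.  With A the output
of the channel-expansion convolution (the model's only convolutional
layer, shape d_channel x d_feature), the weight of channel k is the mean
over the d_feature spatial positions of d(y_e)/dA_k, and the attribution
map is the rectified channel-weighted sum

    L = ReLU(sum_k alpha_k * A_k),

a nonnegative weight per PLI feature.  Rollups credit each pair feature's
weight to both member electrodes, sum electrodes into anatomical regions,
and sum features by frequency band; region totals therefore equal twice
the feature total while band totals conserve it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import IndexMap, default_index_map
from .model import ConvGMLP
from .montage import REGIONS

EPSILON = 1e-9


@dataclass
class AttributionResult:
    """Per-feature attribution weights with electrode/region/band rollups."""

    feature_weights: np.ndarray  # (n_features,), nonnegative
    channel_weights: np.ndarray  # (d_channel,)
    target_value: float
    electrode_scores: dict[str, float] = field(default_factory=dict)
    region_scores: dict[str, float] = field(default_factory=dict)
    band_scores: dict[str, float] = field(default_factory=dict)

    def ranked_features(self, index_map: IndexMap) -> list[tuple[int, tuple, float]]:
        """(feature_idx, (band, elec_i, elec_j), weight) sorted descending."""
        order = np.argsort(-self.feature_weights, kind="stable")
        return [(int(i), index_map[int(i)], float(self.feature_weights[int(i)]))
                for i in order]


def regression_target(y_hat: float, y: float) -> float:
    """y_e = 1 / ((yhat - y)^2 + 1e-9); strictly positive, decreasing in
    the absolute prediction error."""
    if not (np.isfinite(y_hat) and np.isfinite(y)):
        raise ValueError("non-finite input")
    return float(1.0 / ((y_hat - y) ** 2 + EPSILON))


def grad_ram(
    model: ConvGMLP,
    x: np.ndarray,
    y: float,
    index_map: IndexMap | None = None,
    regions=REGIONS,
) -> AttributionResult:
    """Attribution of one sample through the trained model.

    Differentiates the regression target with respect to the
    channel-expansion activation map A via the autodiff tape.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    out = model.forward(x[None, :], training=False)
    a = model.last_activation  # (1, C, S)
    diff = out - float(y)
    ye = (diff * diff + EPSILON) ** -1.0
    ye_scalar = ye.sum()
    ye_scalar.backward()
    if a.grad is None or not np.all(np.isfinite(a.grad)):
        raise FloatingPointError("non-finite or missing gradients on the conv map")

    grads = a.grad[0]  # (C, S)
    amap = a.data[0]
    alpha = grads.mean(axis=1)  # 1/Z sum over the d_feature positions
    feature_weights = np.maximum(alpha @ amap, 0.0)  # ReLU, (S,)

    if index_map is None and feature_weights.size == 480:
        index_map = default_index_map()
    if index_map is not None:
        elec, reg, band = aggregate(feature_weights, index_map, regions)
    else:  # non-montage feature width (e.g. toy dims): no rollups
        elec, reg, band = {}, {}, {}
    return AttributionResult(feature_weights, alpha, float(ye_scalar.data),
                             elec, reg, band)


def cohort_attribution(
    model: ConvGMLP,
    X: np.ndarray,
    y: np.ndarray,
    index_map: IndexMap | None = None,
    regions=REGIONS,
) -> AttributionResult:
    """Cohort-level attribution: the mean of per-sample feature maps."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    maps, alphas, targets = [], [], []
    for xi, yi in zip(X, y):
        res = grad_ram(model, xi, yi, index_map=None, regions=regions)
        maps.append(res.feature_weights)
        alphas.append(res.channel_weights)
        targets.append(res.target_value)
    feature_weights = np.mean(maps, axis=0)
    if index_map is None:
        index_map = default_index_map()
    elec, reg, band = aggregate(feature_weights, index_map, regions)
    return AttributionResult(feature_weights, np.mean(alphas, axis=0),
                             float(np.mean(targets)), elec, reg, band)


def aggregate(
    feature_weights: np.ndarray,
    index_map: IndexMap,
    regions=REGIONS,
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Roll feature weights up to electrodes, regions, and bands.

    Each pair feature's weight is credited to both member electrodes (an
    undirected connectivity feature has no single anatomical home), so the
    region total is twice the feature total; band totals conserve it.
    """
    feature_weights = np.asarray(feature_weights, dtype=np.float64).ravel()
    if len(feature_weights) != len(index_map):
        raise ValueError("feature_weights and index_map length mismatch")
    electrode_scores: dict[str, float] = {}
    band_scores: dict[str, float] = {}
    for w, (band, ei, ej) in zip(feature_weights, index_map):
        w = float(w)
        band_scores[band] = band_scores.get(band, 0.0) + w
        for e in (ei, ej):
            electrode_scores[e] = electrode_scores.get(e, 0.0) + w
    lookup = {e: r for r, members in regions.items() for e in members}
    region_scores = {r: 0.0 for r in regions}
    for e, s in electrode_scores.items():
        region_scores[lookup[e]] += s
    return electrode_scores, region_scores, band_scores
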