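"""Phase Lag Index functional connectivity.

Instantaneous phase is the argument of the analytic signal (Hilbert
transform).  For two phase series the Phase Lag Index is

    PLI = | < sign(sin(phi_x(t) - phi_y(t))) > |,

the absolute time-mean of the sign of the (sine of the) phase difference.
PLI is 0 when there is no consistently signed lag — including identical
phases and exact antiphase, where sin of the difference is 0 or changes
sign symmetrically — and 1 when the lag keeps a constant sign.  sign(0)
contributes 0, so PLI(x, x) = 0 exactly and zero-lag (volume-conduction
style) coupling is invisible by construction.

For the 16-channel montage and the four analysis bands this yields
16*15/2 = 120 electrode pairs per band and 4 * 120 = 480 features per
epoch.  The feature ordering is bands outermost (theta, alpha1, alpha2,
beta), pairs in row-major upper-triangle order; ``index_map`` records the
(band, electrode_i, electrode_j) triple of every column so the convention
travels with the data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import hilbert

from .montage import CHANNELS, electrode_pairs, n_pairs
from .preprocessing import BAND_NAMES, EpochSet

IndexMap = tuple[tuple[str, str, str], ...]


@dataclass
class PhaseEpoch:
    """Per-channel instantaneous phase of one band-limited epoch."""

    phases: np.ndarray  # (n_channels, n_samples), radians in (-pi, pi]
    band: str = ""
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=np.float64)
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases contain non-finite values")


@dataclass
class ConnectivityFeatures:
    """Per-epoch band x pair PLI features with an explicit column index."""

    values: np.ndarray  # (n_epochs, n_features), entries in [0, 1]
    index_map: IndexMap
    label: float = 0.0
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[1] != len(self.index_map):
            raise ValueError("index_map length must match feature columns")
        triples = set(self.index_map)
        if len(triples) != len(self.index_map):
            raise ValueError("index_map contains duplicate triples")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def mean_over_epochs(self) -> "ConnectivityFeatures":
        """Subject mode: average PLI over epochs into a single sample."""
        return replace(self, values=self.values.mean(axis=0, keepdims=True))


def default_index_map(
    ch_names: Sequence[str] = CHANNELS,
    bands: Sequence[str] = BAND_NAMES,
) -> IndexMap:
    pairs = electrode_pairs(len(ch_names))
    return tuple(
        (band, ch_names[i], ch_names[j]) for band in bands for i, j in pairs
    )


def instantaneous_phase(epoch: np.ndarray, band: str = "",
                        epoch_index: int = 0) -> PhaseEpoch:
    """Hilbert-transform instantaneous phase per channel, wrapped to (-pi, pi].

    Raises on constant (zero-variance) channels, whose phase is undefined.
    """
    x = np.asarray(epoch, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[-1] < 4:
        raise ValueError("need at least 4 samples for phase estimation")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    flat = np.ptp(x, axis=-1) == 0
    if np.any(flat):
        bad = [i for i, f in enumerate(flat) if f]
        raise ValueError(f"constant (zero-variance) channel(s): {bad}; phase undefined")
    phases = np.angle(hilbert(x, axis=-1))
    # np.angle returns [-pi, pi]; fold the closed lower edge onto +pi
    phases[phases == -np.pi] = np.pi
    return PhaseEpoch(phases, band, epoch_index)


def pli(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase Lag Index of two phase series; symmetric, in [0, 1]."""
    phase_x = np.asarray(phase_x, dtype=np.float64)
    phase_y = np.asarray(phase_y, dtype=np.float64)
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase series must have equal length")
    if phase_x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.sign(np.sin(phase_x - phase_y)))))


def connectivity_matrix(pe: PhaseEpoch, expected_channels: int | None = 16
                        ) -> np.ndarray:
    """Symmetric zero-diagonal PLI matrix over all channel pairs."""
    phases = pe.phases
    n_ch = phases.shape[0]
    if expected_channels is not None and n_ch != expected_channels:
        raise ValueError(f"expected {expected_channels} channels, got {n_ch}")
    iu = np.triu_indices(n_ch, 1)
    diffs = phases[iu[0]] - phases[iu[1]]
    vals = np.abs(np.mean(np.sign(np.sin(diffs)), axis=-1))
    mat = np.zeros((n_ch, n_ch))
    mat[iu] = vals
    mat[(iu[1], iu[0])] = vals
    return mat


def _epoch_pli_vector(epoch: np.ndarray) -> np.ndarray:
    phases = instantaneous_phase(epoch).phases
    iu = np.triu_indices(phases.shape[0], 1)
    diffs = phases[iu[0]] - phases[iu[1]]
    return np.abs(np.mean(np.sign(np.sin(diffs)), axis=-1))


def extract_features(
    band_epochs: Mapping[str, EpochSet],
    bands: Sequence[str] = BAND_NAMES,
    average_epochs: bool = False,
) -> ConnectivityFeatures:
    """Assemble the per-epoch band x pair PLI feature matrix.

    ``band_epochs`` maps band name -> band-filtered :class:`EpochSet`; all
    listed bands must be present with identical epoch counts.  With
    ``average_epochs`` the per-epoch vectors are averaged into one sample
    per subject.
    """
    missing = [b for b in bands if b not in band_epochs]
    if missing:
        raise ValueError(f"missing band(s): {missing}")
    sets = [band_epochs[b] for b in bands]
    counts = {s.n_epochs for s in sets}
    if len(counts) != 1:
        raise ValueError(f"inconsistent epoch counts across bands: {sorted(counts)}")
    n_epochs = counts.pop()
    first = sets[0]
    n_ch = first.epochs.shape[1]
    npair = n_pairs(n_ch)

    values = np.empty((n_epochs, len(bands) * npair))
    for b_idx, eset in enumerate(sets):
        cols = slice(b_idx * npair, (b_idx + 1) * npair)
        for e in range(n_epochs):
            values[e, cols] = _epoch_pli_vector(eset.epochs[e])

    index_map = default_index_map(first.ch_names, bands)
    feats = ConnectivityFeatures(values, index_map, first.label, first.subject_id)
    return feats.mean_over_epochs() if average_epochs else feats
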