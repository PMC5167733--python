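"""Observation model: source-to-sensor gain and spatial-mode reduction.

Real MEG lead fields require individual head models.  Here each source is
given a smooth synthetic topography on a unit-hemisphere sensor layout: the
gain column of a node is ``exp(-d^2 / 2 w^2)`` in the angular distance ``d``
from the sensor nearest the node's (normalized) MNI direction.  This keeps
the spatial mixing that the inversion has to disentangle without anatomy.

Dimensionality reduction follows the usual practice of projecting sensor
data onto a handful of leading spatial modes (left singular vectors); seven
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nmm import NODE_IDS, SourceTimeSeries

__all__ = [
    "MNI_SOURCES",
    "GainMatrix",
    "SpatialModes",
    "sensor_layout",
    "synthetic_gain",
    "project_to_sensors",
    "compute_modes",
]

#: activation maxima used as source fixtures: node -> (x, y, z mm, t-value)
MNI_SOURCES = {
    "SIc": (-57.0, -19.0, 49.0, 9.8),
    "SIIc": (-48.0, -28.0, 16.0, 10.5),
    "SIIi": (51.0, -25.0, 19.0, 10.2),
}

DEFAULT_N_CHANNELS = 102
DEFAULT_N_MODES = 7


@dataclass
class GainMatrix:
    """Linear source-to-sensor mapping, fT per a.u. of source activity."""

    values: np.ndarray              # (n_channels, n_nodes)
    channel_ids: tuple
    node_ids: tuple = NODE_IDS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.channel_ids):
            raise ValueError("row count must match channel_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gain entries must be finite")
        if np.any(np.all(self.values == 0, axis=0)):
            raise ValueError("gain must have no zero columns")


@dataclass
class SpatialModes:
    """Orthonormal spatial basis (leading left singular vectors)."""

    basis: np.ndarray               # (n_channels, n_modes)
    singular_values: np.ndarray = field(default=None)

    def __post_init__(self):
        self.basis = np.asarray(self.basis, dtype=float)
        g = self.basis.T @ self.basis
        if not np.allclose(g, np.eye(self.n_modes), atol=1e-8):
            raise ValueError("basis columns must be orthonormal")

    @property
    def n_modes(self) -> int:
        return self.basis.shape[1]

    def reduce(self, data: np.ndarray) -> np.ndarray:
        """Project channel-space data (channels x samples) onto the modes."""
        return self.basis.T @ np.asarray(data, dtype=float)


def sensor_layout(n_channels: int = DEFAULT_N_CHANNELS) -> np.ndarray:
    """Deterministic unit-hemisphere layout, (n_channels, 3).

    Fibonacci lattice restricted to the upper hemisphere: a reasonable
    stand-in for a helmet-shaped sensor array.
    """
    i = np.arange(n_channels)
    golden = (1 + np.sqrt(5)) / 2
    z = (i + 0.5) / n_channels          # upper hemisphere only
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(1 - z ** 2)
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def synthetic_gain(n_channels: int = DEFAULT_N_CHANNELS,
                   width: float = 0.5,
                   scale: float = 100.0,
                   seed: int | None = None,
                   jitter: float = 0.05,
                   node_ids: tuple = NODE_IDS) -> GainMatrix:
    """Smooth per-node sensor topographies centred near each MNI direction.

    ``width`` is the angular width (radians) of the Gaussian topography;
    ``scale`` converts source a.u. to fT; ``jitter`` adds a seeded
    multiplicative perturbation emulating between-subject lead-field
    variability (off when ``seed`` is None).
    """
    layout = sensor_layout(n_channels)
    cols = []
    for node in node_ids:
        x, y, z, _t = MNI_SOURCES[node]
        direction = np.array([x, y, z], dtype=float)
        direction /= np.linalg.norm(direction)
        # nearest sensor to the source direction anchors the topography
        anchor = layout[np.argmin(np.linalg.norm(layout - direction, axis=1))]
        ang = np.arccos(np.clip(layout @ anchor, -1.0, 1.0))
        cols.append(scale * np.exp(-ang ** 2 / (2.0 * width ** 2)))
    values = np.column_stack(cols)
    if seed is not None and jitter > 0:
        rng = np.random.default_rng(seed)
        values = values * (1.0 + jitter * rng.standard_normal(values.shape))
    channel_ids = tuple(f"MEG{i:04d}" for i in range(n_channels))
    return GainMatrix(values=values, channel_ids=channel_ids,
                      node_ids=tuple(node_ids))


def project_to_sensors(src: SourceTimeSeries | np.ndarray,
                       gain: GainMatrix) -> np.ndarray:
    """Sensor data ``y = G s``, (n_channels, n_samples)."""
    values = src.values if isinstance(src, SourceTimeSeries) else np.asarray(src)
    if values.shape[0] != gain.values.shape[1]:
        raise ValueError(
            f"source count {values.shape[0]} does not match gain columns "
            f"{gain.values.shape[1]}")
    return gain.values @ values


def compute_modes(data: np.ndarray, n_modes: int = DEFAULT_N_MODES) -> SpatialModes:
    """Leading left singular vectors of a (channels x samples) data matrix."""
    data = np.asarray(data, dtype=float)
    if n_modes > min(data.shape):
        raise ValueError(
            f"n_modes={n_modes} exceeds min(channels, samples)={min(data.shape)}")
    u, s, _vt = np.linalg.svd(data, full_matrices=False)
    return SpatialModes(basis=u[:, :n_modes], singular_values=s[:n_modes])
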