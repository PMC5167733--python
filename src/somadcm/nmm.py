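"""Neural-mass forward model of the three-node somatosensory network.

The network comprises contralateral primary somatosensory cortex (SIc),
contralateral secondary somatosensory cortex (SIIc) and ipsilateral SII
(SIIi).  Each node is a standard evoked-response neural-mass model with three
interacting subpopulations (spiny stellate, pyramidal, inhibitory
interneurons); the measured source signal is the pyramidal depolarization.
Thalamic drive is not modelled as a dynamical node: it enters as one or two
Gaussian input functions (a phasic component near stimulus onset and a
sustained component during the ongoing stimulus), gated onto SIc and/or SIIc
depending on the hypothesis:

* ``A`` — serial throughout: both components enter SIc only.
* ``B`` — serial then parallel: phasic to SIc; sustained to SIc and SIIc.
* ``C`` — parallel then serial: phasic to SIc and SIIc; sustained to SIc.
* ``D`` — parallel throughout: both components enter SIc and SIIc.

Extrinsic connectivity is identical across the four architectures:
bidirectional SIc–SIIc and SIIc–SIIi, plus a self-connection gain per node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._integrator import integrate_erp

__all__ = [
    "NODE_IDS",
    "InputComponent",
    "NodeDynamicsParams",
    "NetworkModel",
    "SourceTimeSeries",
    "ARCHITECTURES",
    "gaussian_input",
    "build_model",
    "simulate_sources",
]

NODE_IDS = ("SIc", "SIIc", "SIIi")

#: input gating per architecture: targets of the phasic / sustained component
ARCHITECTURES = {
    "A": ({"SIc"}, {"SIc"}),
    "B": ({"SIc"}, {"SIc", "SIIc"}),
    "C": ({"SIc", "SIIc"}, {"SIc"}),
    "D": ({"SIc", "SIIc"}, {"SIc", "SIIc"}),
}


@dataclass
class InputComponent:
    """One Gaussian thalamic drive component.

    onset_mean/onset_sd are in ms peri-stimulus time; amplitude is a
    dimensionless gain; targets name the nodes that receive the drive.
    """

    onset_mean: float
    onset_sd: float
    amplitude: float
    targets: frozenset
    label: str = "input"

    def __post_init__(self):
        self.targets = frozenset(self.targets)
        if self.onset_sd <= 0:
            raise ValueError("onset_sd must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not self.targets:
            raise ValueError("targets must be non-empty")
        unknown = self.targets - set(NODE_IDS)
        if unknown:
            raise ValueError(f"unknown target nodes: {sorted(unknown)}")


@dataclass
class NodeDynamicsParams:
    """Biophysical constants shared by all nodes (prior means; re-estimated
    on the log scale during inversion)."""

    H_e: float = 3.25    # excitatory synaptic gain, mV
    H_i: float = 29.4    # inhibitory synaptic gain, mV
    tau_e: float = 10.0  # excitatory time constant, ms
    tau_i: float = 16.0  # inhibitory time constant, ms
    gamma_1: float = 50.0
    gamma_2: float = 40.0
    gamma_3: float = 12.0
    gamma_4: float = 12.0
    sigmoid_slope: float = 0.56    # per mV
    firing_scale: float = 0.005    # maximal population firing rate 2*e0, 1/ms
    input_scale: float = 0.1       # firing-equivalent gain on thalamic drive
    extrinsic_delay: float = 16.0  # ms
    intrinsic_delay: float = 2.0   # ms

    def __post_init__(self):
        for name in ("H_e", "H_i", "tau_e", "tau_i",
                     "extrinsic_delay", "intrinsic_delay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# admissible extrinsic edges, (target, source) index pairs
_FWD_EDGES = ((1, 0), (2, 1))   # SIc->SIIc, SIIc->SIIi
_BWD_EDGES = ((0, 1), (1, 2))   # SIIc->SIc, SIIi->SIIc
_LAT_EDGES = _FWD_EDGES + _BWD_EDGES

DEFAULT_FORWARD = 30.0
DEFAULT_BACKWARD = 10.0


@dataclass
class NetworkModel:
    """Architecture + parameters of one candidate model."""

    architecture: str
    forward_conn: np.ndarray
    backward_conn: np.ndarray
    lateral_conn: np.ndarray
    self_conn: np.ndarray
    input_map: list  # of (InputComponent, {target: gain})
    params: NodeDynamicsParams = field(default_factory=NodeDynamicsParams)
    node_ids: tuple = NODE_IDS

    def __post_init__(self):
        n = len(self.node_ids)
        for name in ("forward_conn", "backward_conn", "lateral_conn"):
            m = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, m)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"{name} must have zero diagonal")
            if np.any(m < 0):
                raise ValueError(f"{name} must be non-negative")
        allowed = {"forward_conn": _FWD_EDGES, "backward_conn": _BWD_EDGES,
                   "lateral_conn": _LAT_EDGES}
        for name, edges in allowed.items():
            m = getattr(self, name)
            mask = np.zeros((n, n), dtype=bool)
            for i, j in edges:
                mask[i, j] = True
            if np.any(m[~mask] != 0):
                raise ValueError(
                    f"{name}: only SIc-SIIc and SIIc-SIIi edges may be nonzero")
        self.self_conn = np.asarray(self.self_conn, dtype=float)
        if self.self_conn.shape != (n,):
            raise ValueError("self_conn must have one entry per node")
        if np.any(self.self_conn < 0):
            raise ValueError("self_conn must be non-negative")
        if not any("SIc" in gains for _, gains in self.input_map):
            raise ValueError("at least one input must target SIc")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "node_ids": list(self.node_ids),
            "forward_conn": self.forward_conn.tolist(),
            "backward_conn": self.backward_conn.tolist(),
            "lateral_conn": self.lateral_conn.tolist(),
            "self_conn": self.self_conn.tolist(),
            "input_map": [
                {"onset_mean": c.onset_mean, "onset_sd": c.onset_sd,
                 "amplitude": c.amplitude, "targets": sorted(c.targets),
                 "label": c.label, "gains": dict(gains)}
                for c, gains in self.input_map
            ],
            "params": vars(self.params).copy(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        input_map = [
            (InputComponent(e["onset_mean"], e["onset_sd"], e["amplitude"],
                            frozenset(e["targets"]), e.get("label", "input")),
             dict(e["gains"]))
            for e in d["input_map"]
        ]
        return cls(
            architecture=d["architecture"],
            forward_conn=np.asarray(d["forward_conn"], dtype=float),
            backward_conn=np.asarray(d["backward_conn"], dtype=float),
            lateral_conn=np.asarray(d["lateral_conn"], dtype=float),
            self_conn=np.asarray(d["self_conn"], dtype=float),
            input_map=input_map,
            params=NodeDynamicsParams(**d["params"]),
            node_ids=tuple(d["node_ids"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "NetworkModel":
        return cls.from_dict(json.loads(s))

    def copy(self) -> "NetworkModel":
        d = self.to_dict()
        return NetworkModel.from_dict(d)

    # -- helpers ----------------------------------------------------------
    def input_amplitude_matrix(self) -> np.ndarray:
        """(n_components, n_nodes) effective drive amplitude per node."""
        n = len(self.node_ids)
        amp = np.zeros((len(self.input_map), n))
        for c, (comp, gains) in enumerate(self.input_map):
            for target, gain in gains.items():
                amp[c, self.node_ids.index(target)] = comp.amplitude * gain
        return amp


@dataclass
class SourceTimeSeries:
    """Per-node pyramidal depolarization on a uniform ms grid (a.u.)."""

    times: np.ndarray
    values: np.ndarray          # (n_nodes, n_samples)
    node_ids: tuple = NODE_IDS
    states: np.ndarray | None = None   # (n_nodes, 9, n_samples), optional

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.node_ids), self.times.size):
            raise ValueError("values must be (n_nodes, n_samples)")


def gaussian_input(t, comp: InputComponent):
    """Thalamic drive level at time ``t`` (ms); vectorized over ``t``."""
    t = np.asarray(t, dtype=float)
    out = comp.amplitude * np.exp(
        -((t - comp.onset_mean) ** 2) / (2.0 * comp.onset_sd ** 2))
    return out if out.ndim else float(out)


def default_components(architecture: str,
                       phasic_amplitude: float = 1.0,
                       sustained_amplitude: float = 1.0,
                       target_gains: dict | None = None) -> list:
    """Phasic (30 +/- 16 ms) and sustained (170 +/- 70 ms) components with
    the gating prescribed by the architecture.

    ``target_gains`` optionally scales the drive per target node (applied to
    both components), e.g. ``{"SIIc": 0.5}`` halves the direct SII input.
    """
    tg = dict(target_gains or {})
    phasic_targets, sustained_targets = ARCHITECTURES[architecture]
    phasic = InputComponent(30.0, 16.0, phasic_amplitude,
                            frozenset(phasic_targets), label="phasic")
    sustained = InputComponent(170.0, 70.0, sustained_amplitude,
                               frozenset(sustained_targets), label="sustained")
    return [
        (phasic, {t: tg.get(t, 1.0) for t in sorted(phasic.targets)}),
        (sustained, {t: tg.get(t, 1.0) for t in sorted(sustained.targets)}),
    ]


def build_model(architecture: str,
                params: NodeDynamicsParams | None = None,
                component_params: dict | None = None,
                phasic_only: bool = False) -> NetworkModel:
    """Construct the candidate model for one architecture label.

    ``component_params`` may override ``phasic_amplitude`` /
    ``sustained_amplitude`` and the extrinsic connection strengths
    (``forward_strength``, ``backward_strength``, ``self_gain``).
    ``phasic_only`` drops the sustained component (the simplified
    stimulus-initiation models).
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(
            f"unknown architecture {architecture!r}; expected one of "
            f"{sorted(ARCHITECTURES)}")
    cp = dict(component_params or {})
    fwd = cp.pop("forward_strength", DEFAULT_FORWARD)
    bwd = cp.pop("backward_strength", DEFAULT_BACKWARD)
    self_gain = cp.pop("self_gain", 1.0)
    input_map = default_components(
        architecture,
        phasic_amplitude=cp.pop("phasic_amplitude", 1.0),
        sustained_amplitude=cp.pop("sustained_amplitude", 1.0),
        target_gains=cp.pop("target_gains", None),
    )
    if cp:
        raise ValueError(f"unknown component_params: {sorted(cp)}")
    if phasic_only:
        input_map = input_map[:1]
    n = len(NODE_IDS)
    F = np.zeros((n, n))
    B = np.zeros((n, n))
    for i, j in _FWD_EDGES:
        F[i, j] = fwd
    for i, j in _BWD_EDGES:
        B[i, j] = bwd
    return NetworkModel(
        architecture=architecture,
        forward_conn=F,
        backward_conn=B,
        lateral_conn=np.zeros((n, n)),
        self_conn=np.full(n, float(self_gain)),
        input_map=input_map,
        params=params or NodeDynamicsParams(),
    )


def simulate_sources(model: NetworkModel, times,
                     internal_dt: float = 0.5,
                     keep_states: bool = False) -> SourceTimeSeries:
    """Integrate the network from rest over ``times`` (ms, uniform grid).

    Fixed-step RK4 at ``internal_dt`` (ms) starting at ``times[0]``; the
    solution is linearly interpolated onto the requested grid.  Conduction
    delays are honoured through the stored solution history.  Deterministic.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two time points")
    steps = np.diff(times)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("times must be strictly increasing and uniform")
    p = model.params
    amp = model.input_amplitude_matrix()
    mu = np.array([c.onset_mean for c, _ in model.input_map], dtype=float)
    sd = np.array([c.onset_sd for c, _ in model.input_map], dtype=float)
    if amp.size == 0:
        amp = np.zeros((1, len(model.node_ids)))
        mu = np.array([0.0])
        sd = np.array([1.0])
    dt = min(float(internal_dt), float(steps[0]))
    t0 = times[0]
    n_steps = int(np.ceil((times[-1] - t0) / dt + 1e-9))
    hist, ok = integrate_erp(
        model.forward_conn, model.backward_conn, model.lateral_conn,
        model.self_conn, amp, mu, sd,
        p.H_e, p.H_i, p.tau_e, p.tau_i,
        p.gamma_1, p.gamma_2, p.gamma_3, p.gamma_4, p.sigmoid_slope,
        p.firing_scale, p.input_scale,
        p.extrinsic_delay, p.intrinsic_delay,
        t0, dt, n_steps)
    if not ok:
        raise FloatingPointError(
            "neural-mass integration diverged; parameter regime "
            f"(H_e={p.H_e}, H_i={p.H_i}, tau_e={p.tau_e}, tau_i={p.tau_i}, "
            f"slope={p.sigmoid_slope}) is unstable")
    grid = t0 + dt * np.arange(n_steps + 1)
    n = len(model.node_ids)
    values = np.empty((n, times.size))
    for i in range(n):
        values[i] = np.interp(times, grid, hist[:, 9 * i + 8])
    states = None
    if keep_states:
        states = np.empty((n, 9, times.size))
        for i in range(n):
            for s in range(9):
                states[i, s] = np.interp(times, grid, hist[:, 9 * i + s])
    return SourceTimeSeries(times=times, values=values,
                            node_ids=model.node_ids, states=states)
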