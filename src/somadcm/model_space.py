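"""Competing-model sets and peri-stimulus window schemes.

Two complementary analyses are supported:

* ``full_dual_input`` — the four dual-input architectures A-D fitted over
  incremental windows that all begin 1 ms post-onset, with lengths from
  40 ms to 260 ms (18 by default).
* ``initiation`` — simplified two-model comparison (serial vs parallel)
  with the phasic input only, over 10 incremental windows by default, or
  sliding fixed-length 60 ms windows to localize the processing switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nmm import build_model, NetworkModel

__all__ = [
    "WindowSpec",
    "AnalysisPlan",
    "incremental_windows",
    "fixed_windows",
    "build_plan",
]

SAMPLE_STEP_MS = 2.0        # 500 Hz epoch grid
EPOCH_END_MS = 300.0


@dataclass(frozen=True, order=True)
class WindowSpec:
    """Post-onset analysis window [start, start + length] ms (closed)."""

    start: float
    length: float

    def __post_init__(self):
        if self.start < 0:
            raise ValueError("window start must be >= 0 (post-onset)")
        if self.length <= 0:
            raise ValueError("window length must be positive")
        if self.start + self.length > EPOCH_END_MS:
            raise ValueError(
                f"window [{self.start}, {self.start + self.length}] exceeds "
                f"the {EPOCH_END_MS} ms epoch")

    @property
    def stop(self) -> float:
        return self.start + self.length

    def as_tuple(self):
        return (self.start, self.length)


@dataclass
class AnalysisPlan:
    """Pure-data description of one analysis: models x windows."""

    analysis: str
    model_labels: list
    models: list                      # of NetworkModel
    windows: list                     # of WindowSpec
    mode: str = "incremental"         # or "fixed"
    #: whether input onset/width are free parameters during inversion; the
    #: initiation comparison fixes them so both models share one stimulus-
    #: onset input (a free onset would let it morph into a sustained drive)
    estimate_timing: bool = True

    def __post_init__(self):
        if len(self.models) < 2:
            raise ValueError("need at least 2 models")
        if not self.windows:
            raise ValueError("need at least one window")
        self.windows = sorted(self.windows)


def _snap(x: float) -> float:
    return round(x / SAMPLE_STEP_MS) * SAMPLE_STEP_MS


def incremental_windows(n: int = 18, min_len: float = 40.0,
                        max_len: float = 260.0,
                        start: float = 1.0) -> list:
    """``n`` windows all starting at ``start`` ms, lengths evenly spaced
    from ``min_len`` to ``max_len`` and snapped to the sample grid."""
    if n < 2:
        raise ValueError("need at least 2 windows")
    if min_len >= max_len:
        raise ValueError("min_len must be below max_len")
    lengths = np.linspace(min_len, max_len, n)
    out = []
    for i, ln in enumerate(lengths):
        ln = min_len if i == 0 else (max_len if i == n - 1 else _snap(ln))
        out.append(WindowSpec(start=start, length=float(ln)))
    return out


def fixed_windows(length: float = 60.0, step: float = 30.0,
                  span: tuple = (0.0, 300.0)) -> list:
    """Sliding windows of one fixed length stepped across ``span``."""
    lo, hi = span
    if length > hi - lo:
        raise ValueError("length exceeds span")
    if step <= 0:
        raise ValueError("step must be positive")
    out = []
    s = lo
    while s + length <= hi + 1e-9:
        out.append(WindowSpec(start=float(s), length=float(length)))
        s += step
    return out


def build_plan(analysis: str, windows: list | None = None,
               mode: str = "incremental",
               component_params: dict | None = None) -> AnalysisPlan:
    """Construct one of the two analysis plans.

    ``full_dual_input``: four architectures, both input components, 18
    incremental windows by default.  ``initiation``: serial (A) vs parallel
    (D gating of the phasic component) with the sustained component dropped,
    10 incremental windows by default (or fixed windows with
    ``mode='fixed'``).
    """
    if analysis == "full_dual_input":
        labels = ["A", "B", "C", "D"]
        models = [build_model(a, component_params=dict(component_params or {}))
                  for a in labels]
        if windows is None:
            windows = incremental_windows(18)
    elif analysis == "initiation":
        labels = ["serial", "parallel"]
        models = [
            build_model("A", component_params=dict(component_params or {}),
                        phasic_only=True),
            build_model("D", component_params=dict(component_params or {}),
                        phasic_only=True),
        ]
        for m, lab in zip(models, labels):
            m.architecture = lab
        if windows is None:
            windows = (incremental_windows(10) if mode == "incremental"
                       else fixed_windows())
    else:
        raise ValueError(
            f"unknown analysis {analysis!r}; expected 'full_dual_input' or "
            "'initiation'")
    return AnalysisPlan(analysis=analysis, model_labels=labels,
                        models=models, windows=list(windows), mode=mode,
                        estimate_timing=(analysis == "full_dual_input"))
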