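"""Sensor-space preprocessing: filtering, epoching, artifact projection.

The chain mirrors standard evoked-field practice: zero-phase band-pass
(0.5-100 Hz), decimation to 500 Hz, epoching from 50 ms before to 300 ms
after stimulus onset (stimulus markers are assumed onset-corrected for the
40 ms pneumatic delay), baseline correction over the pre-stimulus window,
and signal-space projection of stereotyped artifact topographies (cardiac,
ocular) estimated by PCA of labelled artifact segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "EpochSet",
    "ERF",
    "bandpass",
    "downsample_epoch_baseline",
    "artifact_project",
    "average_erf",
    "reject_trials",
]

logger = logging.getLogger(__name__)

EPOCH_START_MS = -50.0
EPOCH_END_MS = 300.0
TARGET_RATE = 500.0


@dataclass
class Recording:
    """Continuous multi-channel record with stimulus-onset markers (s)."""

    sample_rate: float
    data: np.ndarray                    # (n_channels, n_samples)
    event_times: np.ndarray             # stimulus onsets, s
    artifact_events: dict = field(default_factory=dict)  # label -> times (s)
    channel_ids: tuple = ()

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.data = np.asarray(self.data, dtype=float)
        self.event_times = np.asarray(self.event_times, dtype=float)
        duration = self.data.shape[1] / self.sample_rate
        if self.event_times.size and (self.event_times.min() < 0
                                      or self.event_times.max() > duration):
            raise ValueError("event_times must lie within the record")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sample_rate


@dataclass
class EpochSet:
    """Trial-level epochs, (n_channels, n_samples, n_trials)."""

    times: np.ndarray                   # ms relative to stimulus onset
    data: np.ndarray
    channel_ids: tuple = ()

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != self.times.size:
            raise ValueError("data must be (channels, samples, trials)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


@dataclass
class ERF:
    """Trial-averaged event-related field."""

    times: np.ndarray
    data: np.ndarray                    # (n_channels, n_samples)
    n_trials_averaged: int
    channel_ids: tuple = ()

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[1] != self.times.size:
            raise ValueError("data must be (channels, samples)")


def bandpass(rec: Recording, hp: float = 0.5, lp: float = 100.0) -> Recording:
    """Zero-phase band-pass: 4th-order Butterworth high- then low-pass,
    applied forward and backward (no phase distortion)."""
    nyq = rec.sample_rate / 2.0
    if lp >= nyq or hp >= nyq:
        raise ValueError(f"cutoffs ({hp}, {lp}) must be below Nyquist {nyq}")
    sos_hp = signal.butter(4, hp, btype="highpass", fs=rec.sample_rate,
                           output="sos")
    sos_lp = signal.butter(4, lp, btype="lowpass", fs=rec.sample_rate,
                           output="sos")
    out = signal.sosfiltfilt(sos_hp, rec.data, axis=1)
    out = signal.sosfiltfilt(sos_lp, out, axis=1)
    return Recording(sample_rate=rec.sample_rate, data=out,
                     event_times=rec.event_times,
                     artifact_events=rec.artifact_events,
                     channel_ids=rec.channel_ids)


def epoch_times(rate: float = TARGET_RATE) -> np.ndarray:
    """Closed-interval epoch grid [-50, 300] ms (176 samples at 500 Hz)."""
    n = int(round((EPOCH_END_MS - EPOCH_START_MS) / 1000.0 * rate)) + 1
    return EPOCH_START_MS + 1000.0 / rate * np.arange(n)


def downsample_epoch_baseline(rec: Recording,
                              target_rate: float = TARGET_RATE) -> EpochSet:
    """Decimate to ``target_rate`` and cut baseline-corrected epochs.

    The band-pass (low-pass well below the new Nyquist) is assumed to have
    been applied already and acts as the anti-alias filter.  Trials whose
    epoch would extend past the record edge are dropped with a warning.
    Baseline is the half-open pre-stimulus window [-50, 0) ms.
    """
    if not rec.event_times.size:
        raise ValueError("recording has no stimulus events")
    step = rec.sample_rate / target_rate
    if abs(step - round(step)) > 1e-9:
        raise ValueError(
            f"sample_rate {rec.sample_rate} must be an integer multiple of "
            f"{target_rate}")
    data = rec.data[:, ::int(round(step))]
    times = epoch_times(target_rate)
    n_samp = times.size
    pre = int(round(-EPOCH_START_MS / 1000.0 * target_rate))
    epochs = []
    for t_ev in rec.event_times:
        onset = int(round(t_ev * target_rate))
        lo, hi = onset - pre, onset - pre + n_samp
        if lo < 0 or hi > data.shape[1]:
            logger.warning("dropping trial at %.3f s: epoch outside record",
                           t_ev)
            continue
        epochs.append(data[:, lo:hi])
    if not epochs:
        raise ValueError("no complete epochs inside the record")
    cube = np.stack(epochs, axis=2)
    baseline = times < 0.0
    cube = cube - cube[:, baseline, :].mean(axis=1, keepdims=True)
    return EpochSet(times=times, data=cube, channel_ids=rec.channel_ids)


def artifact_topographies(rec: Recording, segment_half_width: float = 0.2
                          ) -> dict:
    """Leading PCA topography per artifact class from labelled segments.

    Segments of +/- ``segment_half_width`` s around each labelled artifact
    event are concatenated; the first left singular vector is the artifact's
    sensor pattern.
    """
    topos = {}
    for label, times in rec.artifact_events.items():
        times = np.asarray(times, dtype=float)
        if not times.size:
            continue
        half = int(round(segment_half_width * rec.sample_rate))
        segs = []
        for t_ev in times:
            c = int(round(t_ev * rec.sample_rate))
            lo, hi = max(c - half, 0), min(c + half, rec.data.shape[1])
            if hi > lo:
                segs.append(rec.data[:, lo:hi])
        if not segs:
            continue
        cat = np.concatenate(segs, axis=1)
        cat = cat - cat.mean(axis=1, keepdims=True)
        if not np.any(cat):
            raise ValueError(f"artifact segments for {label!r} have zero "
                             "variance")
        u, _s, _vt = np.linalg.svd(cat, full_matrices=False)
        topos[label] = u[:, 0]
    return topos


def artifact_project(epochs: EpochSet, topographies: dict) -> EpochSet:
    """Orthogonally project the data away from each artifact topography.

    Projects onto the orthogonal complement of the joint span of the
    topographies (``I - U U^T`` with U an orthonormal basis of the span);
    the spatial rank drops by exactly one per (independent) class.
    """
    n_ch = epochs.data.shape[0]
    cols = []
    for label, u in topographies.items():
        u = np.asarray(u, dtype=float)
        if np.linalg.norm(u) == 0:
            raise ValueError(f"degenerate topography for {label!r}")
        cols.append(u / np.linalg.norm(u))
    P = np.eye(n_ch)
    if cols:
        U, _r = np.linalg.qr(np.column_stack(cols))
        P = P - U @ U.T
    flat = epochs.data.reshape(epochs.data.shape[0], -1)
    cleaned = (P @ flat).reshape(epochs.data.shape)
    return EpochSet(times=epochs.times, data=cleaned,
                    channel_ids=epochs.channel_ids)


def reject_trials(epochs: EpochSet, z_thresh: float = 6.0) -> EpochSet:
    """Automatic stand-in for visual inspection: drop trials whose peak
    amplitude is an outlier (z-score of per-trial max |amplitude|)."""
    peaks = np.abs(epochs.data).max(axis=(0, 1))
    z = (peaks - peaks.mean()) / (peaks.std() + 1e-30)
    keep = z < z_thresh
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("rejecting %d/%d trials (amplitude z > %.1f)",
                       dropped, epochs.n_trials, z_thresh)
    return EpochSet(times=epochs.times, data=epochs.data[:, :, keep],
                    channel_ids=epochs.channel_ids)


def average_erf(epochs: EpochSet) -> ERF:
    """Arithmetic mean over trials."""
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    return ERF(times=epochs.times, data=epochs.data.mean(axis=2),
               n_trials_averaged=epochs.n_trials,
               channel_ids=epochs.channel_ids)
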