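"""Filtering, epoching, baseline correction and artifact projection."""

import numpy as np
import pytest

from somadcm.preprocess import (EpochSet, Recording, artifact_project,
                                artifact_topographies, average_erf, bandpass,
                                downsample_epoch_baseline, epoch_times,
                                reject_trials)


def make_recording(n_ch=4, duration=10.0, rate=2000.0, seed=0, events=(2.0, 5.0)):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_ch, int(duration * rate)))
    return Recording(sample_rate=rate, data=data,
                     event_times=np.asarray(events, dtype=float))


class TestBandpass:
    @staticmethod
    def _tone_amplitude(x, freq, rate):
        # projection onto the tone; immune to onset transients of other bands
        n = np.arange(x.size)
        z = x * np.exp(-2j * np.pi * freq * n / rate)
        return 2 * np.abs(z.mean())

    def test_passband_tone_preserved(self):
        rate = 2000.0
        t = np.arange(0, 20, 1 / rate)
        rec = Recording(rate, np.sin(2 * np.pi * 10 * t)[None, :], [5.0])
        out = bandpass(rec).data[0]
        mid = slice(8000, 32000)       # avoid filter edge effects
        amp = self._tone_amplitude(out[mid], 10.0, rate)
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_dc_removed(self):
        rec = make_recording()
        rec.data += 5.0
        out = bandpass(rec).data
        assert np.abs(out.mean(axis=1)).max() < 0.05

    def test_stopband_attenuation(self):
        rate = 2000.0
        t = np.arange(0, 20, 1 / rate)
        rec = Recording(rate, np.sin(2 * np.pi * 200 * t)[None, :], [5.0])
        out = bandpass(rec).data[0]
        mid = slice(8000, 32000)
        atten = 20 * np.log10(self._tone_amplitude(out[mid], 200.0, rate))
        assert atten < -20.0

    def test_cutoff_above_nyquist_rejected(self):
        rec = make_recording(rate=150.0, events=(2.0,))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, lp=100.0)


class TestEpoching:
    def test_epoch_grid_176_samples(self):
        t = epoch_times()
        assert t.size == 176
        assert t[0] == -50.0 and t[-1] == 300.0

    def test_event_count_preserved(self):
        rng = np.random.default_rng(3)
        events = 1.0 + np.cumsum(rng.uniform(2.0, 3.8, 154))
        rec = make_recording(n_ch=2, duration=events[-1] + 1.0, events=events)
        ep = downsample_epoch_baseline(rec)
        assert ep.n_trials == 154
        assert ep.data.shape == (2, 176, 154)

    def test_constant_channel_zero_after_baseline(self):
        rec = make_recording(n_ch=1)
        rec.data[:] = 3.7
        ep = downsample_epoch_baseline(rec)
        assert np.abs(ep.data).max() < 1e-12

    def test_baseline_window_mean_zero(self):
        rec = make_recording(n_ch=3, seed=5)
        ep = downsample_epoch_baseline(rec)
        base = ep.data[:, ep.times < 0, :].mean(axis=1)
        assert np.abs(base).max() < 1e-10

    def test_edge_trial_dropped_with_warning(self, caplog):
        rec = make_recording(events=(0.01, 5.0))
        with caplog.at_level("WARNING"):
            ep = downsample_epoch_baseline(rec)
        assert ep.n_trials == 1
        assert "dropping trial" in caplog.text

    def test_no_events_rejected(self):
        rec = make_recording(events=())
        with pytest.raises(ValueError, match="no stimulus events"):
            downsample_epoch_baseline(rec)


class TestArtifactProjection:
    def _epochs(self, data):
        times = epoch_times()
        return EpochSet(times=times, data=data)

    def test_pure_artifact_removed(self):
        u = np.array([3.0, 0.0, 4.0]) / 5.0
        w = np.sin(np.linspace(0, 6, 176))
        data = np.einsum("c,s,t->cst", u, w, np.ones(5))
        out = artifact_project(self._epochs(data), {"cardiac": u})
        assert np.abs(out.data).max() < 1e-12

    def test_orthogonal_data_unchanged(self):
        u = np.array([1.0, 0.0, 0.0])
        rng = np.random.default_rng(0)
        data = np.zeros((3, 176, 4))
        data[1:] = rng.standard_normal((2, 176, 4))
        out = artifact_project(self._epochs(data), {"cardiac": u})
        assert np.allclose(out.data, data, atol=1e-12)

    def test_rank_reduction_exactly_one_per_class(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((6, 176, 3))
        out = artifact_project(self._epochs(data),
                               {"cardiac": rng.standard_normal(6),
                                "ocular": rng.standard_normal(6)})
        flat = out.data.reshape(6, -1)
        s = np.linalg.svd(flat, compute_uv=False)
        assert s[3] / s[0] > 1e-10      # rank 4 kept
        assert s[4] / s[0] < 1e-10      # ranks 5, 6 projected out

    def test_degenerate_topography_rejected(self):
        data = np.zeros((3, 176, 2))
        with pytest.raises(ValueError, match="degenerate"):
            artifact_project(self._epochs(data), {"x": np.zeros(3)})

    def test_topography_estimated_from_segments(self):
        """PCA of labelled artifact segments recovers the planted pattern."""
        rate = 2000.0
        rng = np.random.default_rng(2)
        u = rng.standard_normal(8)
        u /= np.linalg.norm(u)
        data = 0.1 * rng.standard_normal((8, int(20 * rate)))
        beats = np.arange(1.0, 19.0, 1.0)
        half = int(0.05 * rate)
        wave = np.hanning(2 * half)
        for t_ev in beats:
            c = int(t_ev * rate)
            data[:, c - half:c + half] += 3.0 * np.outer(u, wave)
        rec = Recording(rate, data, [10.0], artifact_events={"cardiac": beats})
        topo = artifact_topographies(rec)["cardiac"]
        assert abs(np.dot(topo, u)) > 0.99


class TestAveraging:
    def test_identical_trials(self):
        times = epoch_times()
        trial = np.random.default_rng(0).standard_normal((3, 176))
        data = np.repeat(trial[:, :, None], 10, axis=2)
        erf = average_erf(EpochSet(times=times, data=data))
        assert np.allclose(erf.data, trial)
        assert erf.n_trials_averaged == 10

    def test_noise_suppression_scales_with_trials(self):
        """Averaging 154 iid-noise trials reduces noise power ~154-fold."""
        times = epoch_times()
        rng = np.random.default_rng(4)
        data = rng.standard_normal((10, 176, 154))
        erf = average_erf(EpochSet(times=times, data=data))
        ratio = np.var(data) / np.var(erf.data)
        assert ratio == pytest.approx(154, rel=0.2)

    def test_empty_rejected(self):
        times = epoch_times()
        with pytest.raises(ValueError):
            average_erf(EpochSet(times=times, data=np.zeros((2, 176, 0))))

    def test_outlier_trial_rejected(self, caplog):
        times = epoch_times()
        rng = np.random.default_rng(6)
        data = rng.standard_normal((4, 176, 40))
        data[:, :, 7] *= 500.0
        with caplog.at_level("WARNING"):
            kept = reject_trials(EpochSet(times=times, data=data), z_thresh=4.0)
        assert kept.n_trials == 39
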