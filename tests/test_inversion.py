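"""Variational-Laplace inversion: oracles, invariants, windowing."""

import numpy as np
import pytest

from somadcm.inversion import (InversionSettings, ModelParameterization,
                               PriorDensity, invert, variational_laplace,
                               window_data)
from somadcm.model_space import WindowSpec
from somadcm.nmm import build_model, simulate_sources
from somadcm.observation import project_to_sensors
from somadcm.preprocess import ERF
from somadcm.synthetic import (GroundTruth, sample_subject, subject_gain,
                               synthesize_epochs)
from somadcm.preprocess import average_erf


def conjugate_problem(seed=0, T=40, d=2, sigma=0.5):
    """Linear-Gaussian toy y = G theta + eps with its exact solution."""
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((T, d))
    theta_true = rng.standard_normal(d)
    y = (G @ theta_true + sigma * rng.standard_normal(T))[None, :]
    C0 = np.diag(rng.uniform(0.5, 2.0, d))
    m0 = np.zeros(d)
    iC0 = np.linalg.inv(C0)
    S = np.linalg.inv(G.T @ G / sigma ** 2 + iC0)
    m = S @ (G.T @ y[0] / sigma ** 2 + iC0 @ m0)
    cov_y = sigma ** 2 * np.eye(T) + G @ C0 @ G.T
    _s, logdet = np.linalg.slogdet(cov_y)
    logZ = -0.5 * (T * np.log(2 * np.pi) + logdet
                   + y[0] @ np.linalg.solve(cov_y, y[0]))
    prior = PriorDensity(mean=m0, cov=C0, noise_mean=np.log(1 / sigma ** 2),
                         noise_var=1e-12)
    return G, y, prior, m, S, logZ


class TestConjugateOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_analytic_posterior_and_evidence(self, seed):
        G, y, prior, m, S, logZ = conjugate_problem(seed)
        post, ev = variational_laplace(lambda th: (G @ th)[None, :], y, prior,
                                       InversionSettings(tol=1e-8))
        assert abs(ev.free_energy - logZ) < 1e-3
        assert np.abs(post.mean - m).max() < 1e-6
        assert np.abs(post.cov - S).max() < 1e-6

    def test_free_energy_splits_into_accuracy_minus_complexity(self):
        G, y, prior, *_ = conjugate_problem(3)
        _post, ev = variational_laplace(lambda th: (G @ th)[None, :], y, prior)
        assert ev.free_energy == pytest.approx(ev.accuracy - ev.complexity,
                                               abs=1e-6)

    def test_f_monotone_over_accepted_iterations(self):
        G, y, prior, *_ = conjugate_problem(4)
        # mildly nonlinear forward so several iterations are needed
        fwd = lambda th: (G @ th + 0.1 * (G @ th) ** 2)[None, :]
        _post, ev = variational_laplace(fwd, y, prior,
                                        InversionSettings(tol=1e-8))
        f = np.array(ev.f_history)
        assert f.size >= 2
        assert np.all(np.diff(f) > -1e-9)

    def test_irrelevant_parameter_leaves_evidence_unchanged(self):
        """A parameter pinned by a near-zero prior variance must not move
        the free energy."""
        G, y, prior, m, S, logZ = conjugate_problem(5)
        st = InversionSettings(tol=1e-8)
        _p1, ev1 = variational_laplace(lambda th: (G @ th)[None, :], y, prior,
                                       st)
        G2 = np.column_stack([G, np.zeros(G.shape[0])])
        prior2 = PriorDensity(
            mean=np.r_[prior.mean, 0.0],
            cov=np.diag(np.r_[np.diag(prior.cov), 1e-12]),
            noise_mean=prior.noise_mean, noise_var=prior.noise_var)
        _p2, ev2 = variational_laplace(lambda th: (G2 @ th)[None, :], y,
                                       prior2, st)
        assert abs(ev2.free_energy - ev1.free_energy) < 1e-3


class TestNMMInversion:
    def test_noiseless_data_at_prior_mean_recovers_prior_mean(self, gain102,
                                                              epoch_grid):
        model = build_model("C")
        src = simulate_sources(model, epoch_grid)
        erf = ERF(times=epoch_grid, data=project_to_sensors(src, gain102),
                  n_trials_averaged=1)
        rd = window_data(erf, WindowSpec(1.0, 260.0), gain102)
        post, ev = invert(model, rd, settings=InversionSettings(max_iter=64))
        par = ModelParameterization(model)
        prior_sd = par.prior_sd
        assert np.all(np.abs(post.mean) < 0.1 * prior_sd)

    def test_true_architecture_beats_alternative_across_replicates(self):
        """C-generated single-subject data yield F(C) > F(A) in >= 9/10
        seeded replicates."""
        st = InversionSettings(max_iter=64)
        wins = 0
        for rep in range(10):
            gt = GroundTruth(architecture="C", snr=5.0)
            spec = sample_subject(gt, 1000 + rep)
            gain = subject_gain(gt, 1000 + rep)
            erf = average_erf(synthesize_epochs(spec, gain))
            rd = window_data(erf, WindowSpec(1.0, 260.0), gain)
            _pc, evc = invert(build_model("C"), rd, settings=st)
            _pa, eva = invert(build_model("A"), rd, settings=st)
            wins += evc.free_energy > eva.free_energy
        assert wins >= 9

    def test_input_amplitude_recovery_across_subjects(self):
        """Posterior input amplitudes track the per-subject ground truth
        (r > 0.8 over 20 simulated subjects)."""
        st = InversionSettings(max_iter=64)
        gt = GroundTruth(architecture="C", snr=5.0, between_subject_sd=0.3)
        truth, est = [], []
        for s in range(20):
            spec = sample_subject(gt, 500 + s)
            gain = subject_gain(gt, 500 + s)
            erf = average_erf(synthesize_epochs(spec, gain))
            rd = window_data(erf, WindowSpec(1.0, 260.0), gain)
            post, _ev = invert(build_model("C"), rd, settings=st)
            truth.append(spec.model.input_map[0][0].amplitude)
            est.append(np.exp(post["amp_phasic_SIc"]))
        r = np.corrcoef(truth, est)[0, 1]
        assert r > 0.8


@pytest.fixture(scope="module")
def erf(gain102, sources_c, epoch_grid):
    return ERF(times=epoch_grid,
               data=project_to_sensors(sources_c, gain102),
               n_trials_averaged=1)


class TestWindowData:

    def test_sample_count_under_closed_interval_rule(self, erf, gain102):
        rd = window_data(erf, WindowSpec(1.0, 40.0), gain102)
        assert rd.y.shape == (7, 20)

    def test_full_window_retains_all_post_onset_samples(self, erf, gain102,
                                                        epoch_grid):
        rd = window_data(erf, WindowSpec(0.0, 300.0), gain102)
        assert rd.y.shape[1] == (epoch_grid >= 0).sum()

    def test_windows_nest_before_reduction(self, erf, epoch_grid):
        m100 = (epoch_grid >= 1) & (epoch_grid <= 101)
        m200 = (epoch_grid >= 1) & (epoch_grid <= 201)
        a = erf.data[:, m100]
        b = erf.data[:, m200]
        assert np.array_equal(a, b[:, :a.shape[1]])

    def test_unit_rms_scaling(self, erf, gain102):
        rd = window_data(erf, WindowSpec(1.0, 100.0), gain102)
        assert np.sqrt(np.mean(rd.y ** 2)) == pytest.approx(1.0)

def test_window_outside_epoch_range_rejected(gain102, sources_c, epoch_grid):
    short = ERF(times=epoch_grid[epoch_grid <= 100],
                data=project_to_sensors(sources_c, gain102)[:,
                                                            epoch_grid <= 100],
                n_trials_averaged=1)
    with pytest.raises(ValueError, match="outside"):
        window_data(short, WindowSpec(50.0, 100.0), gain102)
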