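"""Forward neural-mass model: inputs, architectures, integration."""

import numpy as np
import pytest

from somadcm.nmm import (InputComponent, NetworkModel, NodeDynamicsParams,
                         build_model, gaussian_input, simulate_sources)


class TestGaussianInput:
    def test_peak_at_mean(self):
        comp = InputComponent(30.0, 16.0, 1.0, {"SIc"})
        assert gaussian_input(30.0, comp) == pytest.approx(1.0)

    def test_one_sd_closed_form(self):
        comp = InputComponent(30.0, 16.0, 1.0, {"SIc"})
        assert gaussian_input(46.0, comp) == pytest.approx(np.exp(-0.5))

    def test_sustained_symmetry_and_max(self):
        comp = InputComponent(170.0, 70.0, 2.0, {"SIc"})
        t = np.arange(100.0, 240.1, 2.0)
        v = gaussian_input(t, comp)
        assert np.allclose(v, v[::-1], atol=1e-12)
        assert v.max() == pytest.approx(2.0)

    @pytest.mark.parametrize("kwargs", [
        {"onset_sd": 0.0}, {"amplitude": -1.0}, {"targets": set()},
    ])
    def test_invalid_component(self, kwargs):
        base = dict(onset_mean=30.0, onset_sd=16.0, amplitude=1.0,
                    targets={"SIc"})
        base.update(kwargs)
        with pytest.raises(ValueError):
            InputComponent(**base)


class TestBuildModel:
    @pytest.mark.parametrize("arch,phasic,sustained", [
        ("A", {"SIc"}, {"SIc"}),
        ("B", {"SIc"}, {"SIc", "SIIc"}),
        ("C", {"SIc", "SIIc"}, {"SIc"}),
        ("D", {"SIc", "SIIc"}, {"SIc", "SIIc"}),
    ])
    def test_input_gating(self, arch, phasic, sustained):
        m = build_model(arch)
        by_label = {c.label: set(g) for c, g in m.input_map}
        assert by_label["phasic"] == phasic
        assert by_label["sustained"] == sustained

    @pytest.mark.parametrize("arch", list("ABCD"))
    def test_ipsilateral_sii_never_direct_target(self, arch):
        m = build_model(arch)
        for comp, gains in m.input_map:
            assert "SIIi" not in gains

    def test_connectivity_skeleton_identical_across_architectures(self):
        ms = [build_model(a) for a in "ABCD"]
        for m in ms[1:]:
            assert np.array_equal(m.forward_conn, ms[0].forward_conn)
            assert np.array_equal(m.backward_conn, ms[0].backward_conn)
            assert np.array_equal(m.self_conn, ms[0].self_conn)

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            build_model("E")

    def test_disallowed_edge_rejected(self):
        m = build_model("A")
        F = m.forward_conn.copy()
        F[2, 0] = 5.0      # SIc -> SIIi is not part of the network
        with pytest.raises(ValueError, match="SIc-SIIc"):
            NetworkModel(architecture="A", forward_conn=F,
                         backward_conn=m.backward_conn,
                         lateral_conn=m.lateral_conn,
                         self_conn=m.self_conn, input_map=m.input_map)

    def test_serialization_round_trip(self):
        m = build_model("C", component_params={"target_gains": {"SIIc": 0.5}})
        m2 = NetworkModel.from_json(m.to_json())
        assert m2.to_dict() == m.to_dict()


class TestSimulateSources:
    def test_zero_input_zero_output(self, epoch_grid):
        m = build_model("A", component_params={
            "phasic_amplitude": 0.0, "sustained_amplitude": 0.0})
        s = simulate_sources(m, epoch_grid)
        assert np.abs(s.values).max() == 0.0

    def test_kernel_oracle_isolated_node(self):
        """Stellate response of an uncoupled node matches the closed-form
        second-order synaptic kernel h(t) = (H_e/tau_e) t exp(-t/tau_e)."""
        p = NodeDynamicsParams(gamma_1=0.0)   # no recurrent drive to stellate
        n = 3
        comp = InputComponent(20.0, 1.0, 1e-3, {"SIc"}, label="phasic")
        m = NetworkModel(
            architecture="A",
            forward_conn=np.zeros((n, n)), backward_conn=np.zeros((n, n)),
            lateral_conn=np.zeros((n, n)), self_conn=np.ones(n),
            input_map=[(comp, {"SIc": 1.0})], params=p)
        times = np.arange(0.0, 120.1, 0.5)
        s = simulate_sources(m, times, keep_states=True)
        x1 = s.states[0, 0]                      # stellate depolarization
        # oracle: discrete convolution of the Gaussian drive with the kernel
        u = p.input_scale * gaussian_input(times, comp)
        h = (p.H_e / p.tau_e) * times * np.exp(-times / p.tau_e)
        expect = np.convolve(u, h)[:times.size] * 0.5   # dt of the grid
        assert np.sqrt(np.mean((x1 - expect) ** 2)) < 0.02 * np.abs(expect).max()
        # peak location tau_e after the (narrow) input, height ~ A*H_e/e
        i_pk = np.argmax(x1)
        assert abs(times[i_pk] - (comp.onset_mean + p.tau_e)) <= 2.0
        area = p.input_scale * comp.amplitude * comp.onset_sd * np.sqrt(2 * np.pi)
        assert x1[i_pk] == pytest.approx(area * p.H_e / np.e, rel=0.02)

    def test_step_refinement_invariance(self, model_c, epoch_grid):
        a = simulate_sources(model_c, epoch_grid, internal_dt=0.5).values
        b = simulate_sources(model_c, epoch_grid, internal_dt=0.25).values
        rel = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b ** 2))
        assert rel < 0.005

    def test_small_signal_linearity(self, epoch_grid):
        eps = 1e-3
        lo = build_model("A", component_params={
            "phasic_amplitude": eps, "sustained_amplitude": 0.0})
        hi = build_model("A", component_params={
            "phasic_amplitude": 2 * eps, "sustained_amplitude": 0.0})
        a = simulate_sources(lo, epoch_grid).values
        b = simulate_sources(hi, epoch_grid).values
        assert np.abs(b - 2 * a).max() < 0.01 * np.abs(b).max()

    def test_parallel_input_advances_sii_onset(self, epoch_grid):
        """Direct thalamic input to SIIc (architecture D) produces a strictly
        earlier SIIc onset than purely serial routing (A)."""
        post = epoch_grid[epoch_grid >= 0]

        def onset(arch):
            v = np.abs(simulate_sources(build_model(arch), post).values[1])
            return post[np.argmax(v >= 0.05 * v.max())]

        assert onset("D") < onset("A")

    def test_nonuniform_grid_rejected(self, model_c):
        with pytest.raises(ValueError, match="uniform"):
            simulate_sources(model_c, np.array([0.0, 1.0, 3.0, 4.0]))

    def test_divergent_regime_raises(self, epoch_grid):
        p = NodeDynamicsParams(H_e=3.25e5, gamma_1=5e4)
        m = build_model("A", params=p)
        with pytest.raises(FloatingPointError, match="diverged"):
            simulate_sources(m, epoch_grid)
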