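"""Fuzzy ODE integration: steady states, oscillations, correspondence
with the discrete fixed points, and parameter sweeps."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import expit

from boolfuzz import (
    BooleanNetwork,
    FuzzyConfig,
    MembershipSpec,
    boolean_correspondence,
    find_steady_state,
    integrate,
    is_damped_oscillation,
    local_maxima,
    ode_rhs,
    parameter_sweep,
    random_network,
)
from boolfuzz.continuous import binary_vertices, steady_state_defect
from boolfuzz.expressions import Var


def self_activator():
    return BooleanNetwork(("A",), {"A": Var("A")}, ())


class TestOdeRhs:
    def test_zero_at_converged_steady_state(self, bpc):
        cfg = FuzzyConfig(
            membership=MembershipSpec(beta=60.0), clamp_inputs={"LPS": 0.0}
        )
        st = find_steady_state(bpc, cfg, [0, 1, 0, 0, 0], t_max=100)
        assert st.converged
        assert np.max(np.abs(ode_rhs(bpc, cfg, st.levels))) < 1e-6

    def test_self_activator_vertices_in_step_limit(self):
        net = self_activator()
        cfg = FuzzyConfig(membership=MembershipSpec(beta=2000.0))
        assert ode_rhs(net, cfg, [1.0])[0] == pytest.approx(0.0, abs=1e-9)
        assert ode_rhs(net, cfg, [0.0])[0] == pytest.approx(0.0, abs=1e-9)

    def test_decay_rate_halves_steady_level(self):
        """For a fixed input function value, doubling alpha halves the
        steady level q^s = mu / alpha."""
        net = self_activator()
        spec = MembershipSpec(beta=8.0)
        st1 = find_steady_state(
            net, FuzzyConfig(membership=spec), [1.0], t_max=200
        )
        st2 = find_steady_state(
            net, FuzzyConfig(alpha={"A": 2.0}, membership=spec), [1.0],
            t_max=200,
        )
        mu1 = expit(8.0 * (st1.levels[0] - 0.5))
        mu2 = expit(8.0 * (st2.levels[0] - 0.5))
        assert st1.levels[0] == pytest.approx(mu1 / 1.0, abs=1e-5)
        assert st2.levels[0] == pytest.approx(mu2 / 2.0, abs=1e-5)
        assert st2.levels[0] < st1.levels[0]

    def test_clamped_input_has_zero_derivative(self, bpc):
        cfg = FuzzyConfig(
            membership=MembershipSpec(beta=8.0), clamp_inputs={"LPS": 1.0}
        )
        dq = ode_rhs(bpc, cfg, [1.0, 0.3, 0.4, 0.5, 0.6])
        assert dq[bpc.index("LPS")] == 0.0

    def test_config_network_mismatch(self, bpc):
        with pytest.raises(ValueError):
            ode_rhs(bpc, FuzzyConfig(), [0.0] * bpc.n)  # LPS unclamped


class TestIntegrate:
    def test_bpc_b_cell_endpoint_beta60(self, bpc):
        """Starting all-inactive except AP-1 at beta = 60, the system
        reaches the full B-cell profile: Pax5/Bcl6 high, AP-1/Blimp-1
        silenced."""
        cfg = FuzzyConfig(
            membership=MembershipSpec(beta=60.0), clamp_inputs={"LPS": 0.0}
        )
        q0 = [0.0, 1.0, 0.0, 0.0, 0.0]
        traj = integrate(bpc, cfg, q0, t_max=60.0)
        final = dict(zip(bpc.nodes, traj.final))
        assert final["Pax5"] > 0.9 and final["Bcl6"] > 0.9
        assert final["AP1"] < 0.1 and final["Blimp1"] < 0.1

    def test_steady_start_stays_constant(self, toggle):
        cfg = FuzzyConfig(membership=MembershipSpec(beta=200.0))
        traj = integrate(toggle, cfg, [1.0, 0.0], t_max=5.0)
        assert np.allclose(traj.levels, traj.levels[0], atol=1e-9)

    def test_grid_refinement_stability(self, bpc):
        """Halving dt moves the converged levels by less than 1e-6."""
        cfg = FuzzyConfig(
            membership=MembershipSpec(beta=15.0), clamp_inputs={"LPS": 0.0}
        )
        q0 = [0.0, 1.0, 0.0, 0.0, 0.0]
        a = integrate(bpc, cfg, q0, t_max=50.0, dt=0.01)
        b = integrate(bpc, cfg, q0, t_max=50.0, dt=0.005)
        assert np.max(np.abs(a.final - b.final)) < 1e-6

    def test_trajectory_frame_layout(self, toggle):
        cfg = FuzzyConfig(membership=MembershipSpec(beta=8.0))
        frame = integrate(toggle, cfg, [1, 0], t_max=1.0, dt=0.1).to_frame()
        assert list(frame.columns) == ["time", "A", "B"]
        assert len(frame) == 11

    def test_invalid_grid_rejected(self, toggle):
        cfg = FuzzyConfig(membership=MembershipSpec(beta=8.0))
        with pytest.raises(ValueError):
            integrate(toggle, cfg, [0, 0], t_max=0.0)
        with pytest.raises(ValueError):
            integrate(toggle, cfg, [0, 0], t_max=1.0, dt=-0.1)


class TestFindSteadyState:
    def test_self_activator_matches_bisection_oracle(self):
        """1-D case: integration lands on the root of q = mu(q) found
        independently by bracketed bisection."""
        net = self_activator()
        cfg = FuzzyConfig(membership=MembershipSpec(beta=6.0))
        st = find_steady_state(net, cfg, [1.0], t_max=200)
        assert st.converged
        root = brentq(
            lambda q: expit(6.0 * (q - 0.5)) - q, 0.5 + 1e-9, 1.0
        )
        assert st.levels[0] == pytest.approx(root, abs=1e-6)

    def test_negative_ring_sustains_oscillation(self, negring3):
        """The fuzzified negative circuit at large beta never settles:
        flagged oscillatory, not converged."""
        cfg = FuzzyConfig(membership=MembershipSpec(beta=60.0))
        st = find_steady_state(negring3, cfg, [1.0, 0.0, 0.0], t_max=300)
        assert not st.converged
        assert st.oscillatory

    def test_converged_state_is_self_consistent(self, bpc, toggle):
        """Every converged steady state satisfies q = mu[w(q)] / alpha
        within 10x the integrator tolerance."""
        for net, clamp in ((bpc, {"LPS": 1.0}), (toggle, {})):
            cfg = FuzzyConfig(
                membership=MembershipSpec(beta=15.0), clamp_inputs=clamp
            )
            q0 = np.zeros(net.n)
            q0[-1] = 1.0
            st = find_steady_state(net, cfg, q0, tolerance=1e-8, t_max=200)
            assert st.converged
            assert steady_state_defect(net, cfg, st.levels) < 1e-7

    def test_residual_history_recorded(self, negring3):
        cfg = FuzzyConfig(membership=MembershipSpec(beta=60.0))
        st = find_steady_state(
            negring3, cfg, [1.0, 0.0, 0.0], t_max=100, hold_time=10.0
        )
        assert len(st.window_residuals) >= 3


class TestOscillationDetection:
    def test_damped_sine_detected(self):
        t = np.linspace(0, 40, 2000)
        series = 0.3 + 0.2 * np.exp(-0.1 * t) * np.cos(t)
        assert is_damped_oscillation(series)

    def test_monotone_relaxation_not_damped(self):
        t = np.linspace(0, 10, 500)
        assert not is_damped_oscillation(1 - np.exp(-t))

    def test_growing_oscillation_not_damped(self):
        t = np.linspace(0, 40, 2000)
        series = 0.5 + 0.1 * np.exp(0.05 * t) * np.sin(t)
        assert not is_damped_oscillation(series)

    def test_local_maxima_values(self):
        series = np.array([0.0, 1.0, 0.0, 0.8, 0.0, 0.6, 0.0])
        assert local_maxima(series).tolist() == [1.0, 0.8, 0.6]


class TestNfkbDampedOscillation:
    """Fuzzy NF-kB at beta = 3 under constant TNFa: the discrete limit
    cycles become a transient that settles at a regulated steady state;
    slowing the IkBa transcription node (smaller alpha) shifts the loop
    between underdamped ringing and overdamped relaxation."""

    def test_sweep_records_damped_oscillations(self, nfkb):
        cfg = FuzzyConfig(
            membership=MembershipSpec(beta=3.0), clamp_inputs={"TNFa": 1.0}
        )
        q0 = [1.0, 0.0, 0.0, 0.0, 0.0]
        damped = []
        for a_t in (0.2, 0.5, 1.0):
            run = FuzzyConfig(
                alpha={"tIkBa": a_t},
                membership=cfg.membership,
                clamp_inputs=cfg.clamp_inputs,
            )
            traj = integrate(nfkb, run, q0, t_max=200.0)
            p65 = traj.node_series("p65_RelA")
            st = find_steady_state(nfkb, run, q0, t_max=400)
            assert st.converged  # always a stable regulated state
            damped.append(is_damped_oscillation(p65))
        assert any(damped)  # ringing recorded within the sweep

    def test_printed_slow_transcription_point_converges(self, nfkb):
        cfg = FuzzyConfig(
            alpha={"tIkBa": 0.2},
            membership=MembershipSpec(beta=3.0),
            clamp_inputs={"TNFa": 1.0},
        )
        st = find_steady_state(nfkb, cfg, [1, 0, 0, 0, 0], t_max=400)
        assert st.converged and not st.oscillatory

    def test_oscillation_amplitude_differs_with_alpha(self, nfkb):
        table = parameter_sweep(
            nfkb,
            FuzzyConfig(
                membership=MembershipSpec(beta=3.0),
                clamp_inputs={"TNFa": 1.0},
            ),
            "alpha:tIkBa",
            [0.2, 1.0],
            [1, 0, 0, 0, 0],
        )
        assert not np.isclose(
            table["p65_RelA"].iloc[0], table["p65_RelA"].iloc[1], atol=1e-3
        )


class TestCorrespondence:
    @pytest.mark.parametrize("name", ["bpc", "toggle"])
    def test_fixture_fixed_points_confirmed(self, name, request):
        net = request.getfixturevalue(name)
        report = boolean_correspondence(net, beta_large=200.0)
        assert report.ok
        assert not report.missing

    def test_toggle_symmetric_start_is_threshold_state(self, toggle):
        """The exactly symmetric vertices relax onto the w = 1/2
        no-contradiction saddle, reported as threshold states rather
        than mismatches."""
        report = boolean_correspondence(toggle, beta_large=200.0)
        assert len(report.confirmed) == 2
        assert len(report.threshold_states) == 2
        assert not report.rounding_mismatches

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_random_networks_no_mismatch(self, seed):
        net = random_network(6, seed=seed)
        report = boolean_correspondence(net, beta_large=200.0)
        assert report.ok


class TestParameterSweep:
    def test_bpc_beta_sweep_three_outcomes(self, bpc):
        cfg = FuzzyConfig(
            membership=MembershipSpec(beta=60.0), clamp_inputs={"LPS": 0.0}
        )
        table = parameter_sweep(
            bpc, cfg, "beta", [8.0, 15.0, 60.0], [0, 1, 0, 0, 0]
        )
        assert len(table) == 3
        assert table["converged"].all()
        # only the printed beta = 60 endpoint is asserted quantitatively
        row = table[table["beta"] == 60.0].iloc[0]
        assert row["Pax5"] > 0.9 and row["AP1"] < 0.1

    def test_single_value_sweep_equals_direct_run(self, bpc):
        cfg = FuzzyConfig(
            membership=MembershipSpec(beta=15.0), clamp_inputs={"LPS": 0.0}
        )
        q0 = [0, 1, 0, 0, 0]
        table = parameter_sweep(bpc, cfg, "beta", [15.0], q0)
        direct = find_steady_state(bpc, cfg, q0)
        for i, nm in enumerate(bpc.nodes):
            assert table[nm].iloc[0] == direct.levels[i]

    def test_unknown_parameter_and_empty_values(self, bpc):
        cfg = FuzzyConfig(
            membership=MembershipSpec(beta=8.0), clamp_inputs={"LPS": 0.0}
        )
        with pytest.raises(ValueError):
            parameter_sweep(bpc, cfg, "gamma", [1.0], [0] * 5)
        with pytest.raises(ValueError):
            parameter_sweep(bpc, cfg, "beta", [], [0] * 5)


def test_binary_vertices_cover_free_space(bpc):
    verts = binary_vertices(bpc, {"LPS": 1})
    assert verts.shape == (16, 5)
    assert set(verts[:, bpc.index("LPS")]) == {1.0}
    assert len({tuple(v) for v in verts}) == 16
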