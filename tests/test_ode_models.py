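"""Right-hand sides, the quasi-steady-state reduction, and integration."""

import numpy as np
import pytest
from scipy.optimize import root

from taexcite.bifurcation import with_stress_parameter
from taexcite.metrics import detect_excitations
from taexcite.ode_models import (
    MINIMAL,
    IntegrationError,
    ModelVariant,
    antitoxin_qss,
    dilution_factor,
    hill_cleavage,
    integrate,
    mrna_qss,
    rhs_full,
    rhs_normalized,
    rhs_reduced,
    rhs_tat,
    to_normalized_state,
    translation_factor,
)
from taexcite.parameters import StressSchedule, denormalize
from taexcite.phase_plane import find_fixed_points, nullcline_x


class TestHillCleavage:
    def test_midpoint_zero_and_steepness(self):
        assert hill_cleavage(2.0, 2.0, 2) == pytest.approx(0.5)
        assert hill_cleavage(0.0, 2.0, 2) == 0.0
        assert hill_cleavage(4.0, 2.0, 2) == pytest.approx(0.8)  # 4/(4+1)

    def test_monotone(self):
        x = np.linspace(0, 10, 200)
        h = hill_cleavage(x, 1.5, 2)
        assert np.all(np.diff(h) > 0)
        assert h[-1] < 1.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            hill_cleavage(-1.0, 2.0, 2)
        with pytest.raises(ValueError):
            hill_cleavage(1.0, 0.0, 2)


class TestFullModel:
    def test_zero_state_only_transcribes(self, p_ref):
        d = rhs_full(np.zeros(4), p_ref)
        assert d == pytest.approx([p_ref.r_F * p_ref.D, 0.0, 0.0, 0.0])

    def test_cleavage_half_maximal_at_threshold(self, p_ref):
        M = 10.0
        with_cleave = rhs_full((M, 0, p_ref.K_t, 0), p_ref)[0]
        no_cleave = rhs_full((M, 0, p_ref.K_t, 0), p_ref,
                             ModelVariant(representation="full-4d", cleavage=False))[0]
        assert no_cleave - with_cleave == pytest.approx(p_ref.d_large * M / 2)

    def test_negative_state_rejected(self, p_ref):
        with pytest.raises(ValueError):
            rhs_full((1.0, -0.1, 0.0, 0.0), p_ref)

    def test_newton_equilibrium_residual(self, p_ref, q_ref):
        """The dimensional fixed point solved by Newton zeroes the rhs."""
        fp = find_fixed_points(q_ref)[0]
        eps = p_ref.epsilon
        scale = eps / p_ref.d_m
        guess = np.array([
            mrna_qss(fp.x, q_ref) * p_ref.r_F * scale,
            antitoxin_qss(fp.x, q_ref) * scale,
            fp.x * scale, fp.y * scale])
        sol = root(lambda s: rhs_full(np.clip(s, 0, None), p_ref), guess,
                   method="hybr", tol=1e-13)
        assert sol.success
        assert np.max(np.abs(rhs_full(sol.x, p_ref))) < 1e-10


class TestNormalizedModel:
    def test_mrna_equilibrium_without_toxin(self, q_ref):
        # dm/dtau = 0 at x = 0 gives m = 1/eps
        d = rhs_normalized((1.0 / q_ref.epsilon, 0, 0, 0), q_ref)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_correspondence_with_full_model(self, q_at):
        """Full dimensional and normalized trajectories map onto each other."""
        q = q_at(delta_a=1.5)
        p = denormalize(q)
        fp = find_fixed_points(q)[0]
        kick = 2.0 * q.kappa
        x0n = (mrna_qss(kick, q), antitoxin_qss(kick, q), kick, fp.y)
        scale = np.array([p.r_F * p.epsilon / p.d_m] + [p.epsilon / p.d_m] * 3)
        tn = integrate(ModelVariant(representation="normalized-4d"), q, x0n,
                       t_end=40.0, n_points=800)
        tf = integrate(ModelVariant(representation="full-4d"), p,
                       np.array(x0n) * scale, t_end=40.0 / p.d_m, n_points=800)
        mapped = to_normalized_state(tf.states, p)
        rel = np.abs(mapped - tn.states) / np.maximum(np.abs(tn.states), 1e-12)
        assert rel.max() < 1e-6

    def test_decay_without_production_or_binding(self, q_ref):
        """With alpha = gamma = 0, toxin decays at eps*delta_c plus complex release."""
        from dataclasses import replace
        q = replace(q_ref, alpha=1e-300, gamma=1e-300)
        x0, y0 = 2.0, 0.0
        traj = integrate(MINIMAL, q, (x0, y0), t_end=20.0, n_points=400)
        expected = x0 * np.exp(-q.epsilon * q.delta_c * traj.t)
        assert np.max(np.abs(traj["x"] - expected) / expected) < 1e-6


class TestQSSA:
    def test_mrna_limits(self, q_ref):
        eps, beta = q_ref.epsilon, q_ref.beta
        assert mrna_qss(0.0, q_ref) == pytest.approx(1 / eps)
        assert mrna_qss(1e9, q_ref) == pytest.approx(1 / (eps * beta), rel=1e-6)
        assert mrna_qss(q_ref.kappa, q_ref) == pytest.approx(
            (1 / eps) / (1 + (beta - 1) / 2))

    def test_antitoxin_decreasing(self, q_ref):
        x = np.logspace(-3, 2, 300)
        a = antitoxin_qss(x, q_ref)
        assert np.all(np.diff(a) < 0)
        assert antitoxin_qss(0.0, q_ref) == pytest.approx(
            q_ref.gamma * mrna_qss(0.0, q_ref) / q_ref.delta_a)

    def test_qss_matches_4d_equilibrium(self, q_ref):
        """m(x), a(x) agree with the 4D equilibrium at pinned toxin level."""
        for x in (0.01, 0.1, 1.0):
            # solve dm = da = dy = 0 at fixed x
            def partial(s):
                m, a, y = s
                d = rhs_normalized((m, a, x, y), q_ref)
                return [d[0], d[1], d[3]]
            sol = root(partial, (mrna_qss(x, q_ref), antitoxin_qss(x, q_ref), 1.0))
            assert np.max(np.abs(partial(sol.x))) < 1e-10
            assert sol.x[0] == pytest.approx(mrna_qss(x, q_ref), rel=1e-3)
            assert sol.x[1] == pytest.approx(antitoxin_qss(x, q_ref), rel=1e-3)

    def test_reduced_vanishes_on_nullcline(self, q_ref):
        checked = 0
        for x in (0.05, 0.2, 1.0, 5.0):
            y = nullcline_x(x, q_ref)
            if y >= 0:   # the curve continues below the physical quadrant at small x
                assert abs(rhs_reduced((x, y), q_ref)[0]) < 1e-9
                checked += 1
        assert checked >= 3


class TestTATModel:
    def test_total_complex_identity(self, q_at):
        """c = y + 2z obeys the same balance as the 2D complex equation."""
        q = q_at(delta_a=3.0)
        var = ModelVariant(representation="reduced-3d-tat")
        rng = np.random.default_rng(7)
        for _ in range(30):
            x, y, z = rng.uniform(0.01, 5.0, 3)
            dx, dy, dz = rhs_tat((x, y, z), q, var)
            a = antitoxin_qss(x, q, y=y, variant=var)
            dc_expected = (q.alpha * (a + y) * x
                           - q.epsilon * (q.delta_c + q.delta_AT) * (y + 2 * z))
            assert dy + 2 * dz == pytest.approx(dc_expected, rel=1e-12)

    def test_tat_decay_returns_two_toxins(self, q_ref):
        """The delta_AT loss of z appears as 2*delta_AT*z gain in x."""
        from dataclasses import replace
        q = replace(q_ref, alpha=1e-300, gamma=1e-300, delta_c=1e-300)
        z0 = 3.0
        dx, dy, dz = rhs_tat((0.0, 0.0, z0), q)
        assert dx == pytest.approx(2 * q.epsilon * q.delta_AT * z0, rel=1e-9)
        assert dz == pytest.approx(-q.epsilon * q.delta_AT * z0, rel=1e-9)


class TestInhibition:
    def test_neutral_parameters_change_nothing(self, q_ref):
        var = ModelVariant(translation_inhibition=True, growth_inhibition=True,
                           S_m=1.0, B_m=0.0, S_t=1.0, B_t=0.0)
        s = (0.3, 5.0)
        assert rhs_reduced(s, q_ref, var) == pytest.approx(rhs_reduced(s, q_ref))

    def test_strong_toxin_shuts_down(self):
        var = ModelVariant(translation_inhibition=True, growth_inhibition=True,
                           B_m=1.0, B_t=1.0)
        assert translation_factor(1e12, var) == pytest.approx(0.0, abs=1e-9)
        assert dilution_factor(1e12, var) == pytest.approx(0.0, abs=1e-9)


class TestIntegration:
    def test_stationary_at_fixed_point(self, q_ref):
        fp = find_fixed_points(q_ref)[0]
        traj = integrate(MINIMAL, q_ref, (fp.x, fp.y), t_end=100.0)
        assert np.max(np.abs(traj["x"] - fp.x)) < 1e-6
        assert np.max(np.abs(traj["y"] - fp.y)) < 1e-4

    def test_triggered_excitation_rises_and_returns(self, q_at):
        """A super-threshold perturbation spikes and falls back below kappa."""
        q = q_at(delta_a=1.5)
        fp = find_fixed_points(q)[0]
        traj = integrate(MINIMAL, q, (2 * q.kappa, fp.y), t_end=60.0,
                         n_points=3000)
        assert traj["x"].max() > 10 * fp.x
        assert traj["x"][-1] < q.kappa
        assert np.min(traj.states) > -1e-9   # non-negativity

    def test_tolerance_convergence(self, q_at):
        q = q_at(delta_a=1.5)
        fp = find_fixed_points(q)[0]
        times = []
        for rtol in (1e-8, 5e-9):
            # start below kappa but beyond the excitation threshold branch
            traj = integrate(MINIMAL, q, (0.9 * q.kappa, fp.y), t_end=60.0,
                             rtol=rtol, n_points=6000)
            ev = detect_excitations(traj, q.kappa)
            times.append(ev[-1].duration)
        assert abs(times[0] - times[1]) / times[1] < 0.01

    def test_stress_window_triggers_response(self, q_ref):
        """Doubling antitoxin degradation inside a window moves the state."""
        fp = find_fixed_points(q_ref)[0]
        sched = StressSchedule(((100.0, 300.0, 2.5, 1.0),))
        traj = integrate(MINIMAL, q_ref, (fp.x, fp.y), t_end=400.0,
                         stress_schedule=sched, n_points=2000)
        before = traj["y"][traj.t < 100].min()
        during = traj["y"][(traj.t > 250) & (traj.t < 300)].min()
        assert during < 0.7 * before   # complexes deplete under stress
        assert np.max(np.abs(traj["x"][traj.t < 99] - fp.x)) < 1e-6

    def test_invalid_inputs(self, q_ref):
        with pytest.raises(ValueError):
            integrate(MINIMAL, q_ref, (1.0, 1.0), t_end=-5.0)
        with pytest.raises(ValueError):
            integrate(MINIMAL, q_ref, (1.0, -1.0), t_end=5.0)
        with pytest.raises(ValueError):
            integrate(MINIMAL, q_ref, (1.0, 1.0, 1.0), t_end=5.0)

    def test_trajectory_csv_roundtrip(self, tmp_path, q_ref):
        import json
        import pandas as pd
        fp = find_fixed_points(q_ref)[0]
        traj = integrate(MINIMAL, q_ref, (fp.x, fp.y), t_end=10.0, n_points=50)
        out = tmp_path / "traj.csv"
        traj.write_csv(out)
        df = pd.read_csv(out)
        assert list(df.columns) == ["time", "x", "y"]
        sidecar = json.loads((tmp_path / "traj.csv.json").read_text())
        assert sidecar["solver"] == "LSODA"
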