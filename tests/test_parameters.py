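"""Unit conversions, the normalization table, stress transforms, and I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taexcite.parameters import (
    InvalidParameterError,
    NormalizedParameterSet,
    ParameterSet,
    StressSchedule,
    StressWindow,
    apply_stress,
    denormalize,
    halflife_to_rate,
    load_parameters,
    mazef_normalized,
    mazef_parameters,
    molar_rate_to_count_rate,
    normalize,
    round_sig,
    save_parameters,
    volume_factor,
)

NP_FLOAT_FIELDS = ("delta_c", "delta_a", "delta_AT", "beta", "alpha",
                   "gamma", "epsilon", "kappa")


class TestConversions:
    def test_volume_factor_ecoli(self):
        # 0.6 um^3 cell: 3.612e8 molecules per cell per molar
        assert volume_factor(0.6e-18) == pytest.approx(3.612e8, rel=1e-12)

    def test_volume_factor_linear_and_invalid(self):
        assert volume_factor(1.2e-18) == pytest.approx(2 * volume_factor(0.6e-18))
        with pytest.raises(InvalidParameterError):
            volume_factor(0.0)

    def test_association_rate_conversion(self):
        # 1.32e5 /M/s at the E. coli volume -> 0.000365 per molecule per s
        k = molar_rate_to_count_rate(1.32e5, 0.6e-18)
        assert round_sig(k, 3) == pytest.approx(3.65e-4)

    def test_conversion_edge_cases(self):
        assert molar_rate_to_count_rate(0.0) == 0.0
        assert molar_rate_to_count_rate(volume_factor(0.6e-18), 0.6e-18) == pytest.approx(1.0)
        with pytest.raises(InvalidParameterError):
            molar_rate_to_count_rate(-1.0)

    def test_halflife_to_rate(self):
        # 5.7 min mRNA half-life gives the ~0.002 /s decay rate
        assert halflife_to_rate(5.7 * 60) == pytest.approx(0.002, abs=5e-5)
        assert halflife_to_rate(math.log(2.0)) == pytest.approx(1.0)
        # 40 min cell cycle
        assert halflife_to_rate(2400.0) == pytest.approx(2.888e-4, rel=1e-3)
        with pytest.raises(InvalidParameterError):
            halflife_to_rate(0.0)


class TestNormalization:
    @pytest.mark.parametrize("field,expected", [
        ("gamma", 7.38),
        ("alpha", 6.74),
        ("epsilon", 0.0738),
        ("kappa", 0.407),
        ("beta", 100.0),
        ("delta_a", 1.16),
        ("delta_c", 1.96),
    ])
    def test_reference_table_values(self, field, expected):
        """The printed dimensionless values, at 3 significant figures."""
        q = normalize(mazef_parameters())
        assert round_sig(getattr(q, field), 3) == pytest.approx(expected)

    def test_dc_presets_differ(self):
        # the rounded dilution rate does not reproduce delta_c = 1.96
        q_printed = normalize(mazef_parameters(d_c="printed"))
        assert round_sig(q_printed.delta_c, 3) != 1.96
        with pytest.raises(InvalidParameterError):
            mazef_parameters(d_c="nonsense")

    def test_antitoxin_degradation_chain(self):
        # d_a = 8 x dilution rate of a 40-min cell cycle
        p = mazef_parameters()
        assert p.d_a == pytest.approx(8 * halflife_to_rate(2400.0))
        assert round_sig(p.d_a, 3) == pytest.approx(2.31e-3)

    def test_delta_AT_to_delta_a_ratio(self, q_ref):
        assert q_ref.delta_AT / q_ref.delta_a == pytest.approx(
            0.1 / q_ref.epsilon, rel=1e-12)

    @given(st.floats(0.05, 0.9), st.floats(1e-4, 1e-1), st.floats(0.2, 0.99),
           st.floats(1e-5, 1e-2), st.floats(1e-5, 1e-2))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_identity(self, eps, d_m, F, d_c, d_a):
        """normalize(denormalize(q)) reproduces q to 1e-12 relative error."""
        p = ParameterSet(d_m=d_m, b_2=eps * 0.122, F=F, d_c=d_c, d_a=d_a)
        q = normalize(p)
        q2 = normalize(denormalize(q, d_m=d_m, b_1=p.b_1, D=p.D))
        for f in NP_FLOAT_FIELDS:
            assert getattr(q2, f) == pytest.approx(getattr(q, f), rel=1e-12)

    @given(st.floats(0.5, 20.0))
    @settings(max_examples=30, deadline=None)
    def test_time_unit_invariance(self, lam):
        """Rescaling every rate leaves pure rate-ratio parameters unchanged."""
        p = mazef_parameters()
        scaled = ParameterSet(
            r_F=p.r_F * lam, d_m=p.d_m * lam, d_large=p.d_large * lam,
            K_t=p.K_t, n=p.n, b_1=p.b_1 * lam, b_2=p.b_2 * lam,
            a_T=p.a_T * lam, d_c=p.d_c * lam, d_a=p.d_a * lam, F=p.F)
        q0, q1 = normalize(p), normalize(scaled)
        for f in ("epsilon", "beta", "delta_a", "delta_c", "delta_AT"):
            assert getattr(q1, f) == pytest.approx(getattr(q0, f), rel=1e-12)


class TestStress:
    def test_dimensional_stress_doubles_d_a(self, p_ref):
        stressed = apply_stress(p_ref, da_factor=2.0)
        assert round_sig(stressed.d_a, 3) == pytest.approx(4.62e-3)
        assert stressed.d_a2 == pytest.approx(2 * p_ref.d_a2)  # F fixed
        assert stressed.b_2 == p_ref.b_2

    def test_identity_stress(self, p_ref, q_ref):
        assert apply_stress(p_ref, 1.0, 1.0) == p_ref
        assert apply_stress(q_ref, 1.0, 1.0) == q_ref

    def test_normalized_stress_scales_delta_AT(self, q_ref):
        stressed = apply_stress(q_ref, da_factor=2.0)
        assert stressed.delta_a == pytest.approx(2 * q_ref.delta_a)
        assert stressed.delta_AT == pytest.approx(2 * q_ref.delta_AT)
        assert stressed.F_ratio == pytest.approx(q_ref.F_ratio)

    def test_invalid_factor(self, p_ref):
        with pytest.raises(InvalidParameterError):
            apply_stress(p_ref, da_factor=-1.0)


class TestStressSchedule:
    def test_windows_and_segments(self):
        sched = StressSchedule(((10.0, 20.0, 2.0, 1.0), (30.0, 40.0, 1.0, 1.5)))
        assert sched.factors_at(15.0) == (2.0, 1.0)
        assert sched.factors_at(25.0) == (1.0, 1.0)
        segs = sched.segments(0.0, 50.0)
        assert [s[:2] for s in segs] == [(0.0, 10.0), (10.0, 20.0), (20.0, 30.0),
                                         (30.0, 40.0), (40.0, 50.0)]

    def test_overlap_rejected(self):
        with pytest.raises(InvalidParameterError):
            StressSchedule(((0.0, 20.0, 2.0, 1.0), (10.0, 30.0, 2.0, 1.0)))
        with pytest.raises(InvalidParameterError):
            StressWindow(10.0, 5.0)

    def test_rescaled_times(self):
        sched = StressSchedule(((1000.0, 2000.0, 2.0, 1.0),))
        tau = sched.rescaled(0.002)
        assert tau.windows[0].t_start == pytest.approx(2.0)
        assert tau.windows[0].da_factor == 2.0


class TestValidationAndIO:
    @pytest.mark.parametrize("kwargs", [
        {"b_2": 0.2},            # toxin translated faster than antitoxin
        {"F": 1.5},
        {"F": 0.0},
        {"n": 0},
        {"d_m": -0.002},
    ])
    def test_invalid_parameter_sets(self, kwargs):
        with pytest.raises((InvalidParameterError, ValueError)):
            ParameterSet(**kwargs)

    def test_invalid_normalized(self):
        with pytest.raises(InvalidParameterError):
            NormalizedParameterSet(epsilon=1.5)
        with pytest.raises(InvalidParameterError):
            NormalizedParameterSet(beta=0.5)

    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_io_roundtrip(self, tmp_path, suffix, p_ref, q_ref):
        for obj in (p_ref, q_ref):
            path = tmp_path / f"params{suffix}"
            save_parameters(obj, path)
            back = load_parameters(path)
            assert type(back) is type(obj)
            assert back == obj

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("parameter_type: ParameterSet\nd_m: 0.002\nbogus: 1\n")
        with pytest.raises(InvalidParameterError, match="bogus"):
            load_parameters(path)

    def test_bundled_reference_file_matches_presets(self):
        import importlib.resources as ir
        path = ir.files("taexcite") / "data" / "mazef_reference.yaml"
        p = load_parameters(path)
        ref = mazef_parameters()
        for f in ("r_F", "d_m", "d_large", "K_t", "b_1", "b_2", "d_c", "d_a", "F"):
            assert getattr(p, f) == pytest.approx(getattr(ref, f), rel=1e-9)
        assert normalize(p).rounded().gamma == 7.38


def test_round_sig_half_away_from_zero():
    assert round_sig(0.40665, 3) == 0.407
    assert round_sig(6.735, 3) == 6.74
    assert round_sig(0.0, 3) == 0.0
    assert round_sig(-6.735, 3) == -6.74
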