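"""Forward-model tests: bending envelope, linking variance, topoisomer sum."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnamech.constants import K_B_ERG_PER_K
from dnamech.wlc_model import (
    ContourLength,
    MechanicalParams,
    TopoisomerSpec,
    bend_jfactor,
    jfactor_model,
    linking_variance,
    twist_factor,
    writhe_variance,
)

DNA1 = MechanicalParams.from_scaled(51.5, 10.52, 2.27)


class TestBendJFactor:
    def test_short_chain_closure_forbidden(self):
        # 20 bp is far below the persistence length: exponential suppression
        assert bend_jfactor(20, DNA1) < 1e-30
        assert bend_jfactor(20, DNA1) < 1e-36 * bend_jfactor(205, DNA1)

    def test_strictly_increasing_through_200bp_range(self):
        n = np.arange(150, 251)
        j = bend_jfactor(n, DNA1)
        assert np.all(np.diff(j) > 0)

    def test_depends_on_reduced_length_times_volume_prefactor(self):
        # doubling L and P fixes L/P; the number density scales as 1/P^3
        j1 = bend_jfactor(ContourLength(200), DNA1)
        p2 = MechanicalParams.from_scaled(2 * 51.5, 10.52, 2.27)
        j2 = bend_jfactor(ContourLength(400), p2)
        assert j2 == pytest.approx(j1 / 8.0, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            bend_jfactor(-5, DNA1)
        with pytest.raises(ValueError):
            MechanicalParams.from_scaled(-1.0, 10.5, 2.0)

    def test_long_chain_validity_warning(self):
        with pytest.warns(UserWarning, match="L/P"):
            bend_jfactor(1000, DNA1)


class TestLinkingVariance:
    def test_infinite_torsional_stiffness_leaves_writhe_floor(self):
        stiff = MechanicalParams.from_scaled(51.5, 10.52, 1e9)
        var = linking_variance(205, stiff)
        floor = writhe_variance(205 * 0.34 / 51.5)
        assert var == pytest.approx(floor, rel=1e-6)

    def test_monotone_in_length(self):
        n = np.arange(150, 401)
        var = linking_variance(n, DNA1)
        assert np.all(np.diff(var) > 0)

    def test_monotone_nonincreasing_in_torsional_rigidity(self):
        cs = np.linspace(0.5, 4.0, 30)
        vars_ = [
            linking_variance(205, MechanicalParams.from_scaled(51.5, 10.52, c))
            for c in cs
        ]
        assert np.all(np.diff(vars_) < 0)

    def test_twist_term_scaling(self):
        # subtracting the writhe floor leaves exactly L kT/(4 pi^2 C)
        var = linking_variance(205, DNA1)
        floor = writhe_variance(205 * 0.34 / 51.5)
        L_cm = 205 * 0.34 * 1e-7
        expected = L_cm * K_B_ERG_PER_K * 295.15 / (4 * np.pi**2 * 2.27e-19)
        assert var - floor == pytest.approx(expected, rel=1e-12)


class TestTwistFactor:
    def test_phase_extrema(self):
        # integer Lk0 maximizes the factor, half-integer minimizes it
        spec = TopoisomerSpec(var_override_turns2=0.01)
        g0 = 10.5
        params = MechanicalParams.from_scaled(51.5, g0, 2.27)
        integer_n = 20 * g0          # Lk0 = 20
        half_n = 19.5 * g0           # Lk0 = 19.5
        grid = np.linspace(integer_n - 2, integer_n + 2, 81)
        f = twist_factor(grid, params, spec)
        assert twist_factor(integer_n, params, spec) == pytest.approx(f.max(), rel=1e-9)
        assert twist_factor(half_n, params, spec) < f.min() + 1e-9

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            TopoisomerSpec(window=6)

    @pytest.mark.parametrize("var, tol", [(0.02, 1e-12), (0.13, 1e-9), (0.5, 1e-5)])
    def test_seven_topoisomers_suffice(self, var, tol):
        # brute-force wider sums as oracle for the 7-integer truncation;
        # realistic ~200-bp linking variances are <= ~0.13 turns^2
        spec7 = TopoisomerSpec(window=7, var_override_turns2=var)
        spec15 = TopoisomerSpec(window=15, var_override_turns2=var)
        spec101 = TopoisomerSpec(window=101, var_override_turns2=var)
        n = np.linspace(201, 211, 41)
        f7 = twist_factor(n, DNA1, spec7)
        f15 = twist_factor(n, DNA1, spec15)
        f101 = twist_factor(n, DNA1, spec101)
        assert np.max(np.abs(f15 - f7) / f15) < tol
        assert np.max(np.abs(f101 - f15) / f101) < max(tol, 1e-9)

    def test_published_phase_ordering(self, presets):
        # fitted natural-DNA parameters put 211 bp in phase and 205 bp out
        assert jfactor_model(211, DNA1) > jfactor_model(205, DNA1)


class TestJFactorModel:
    def test_minimum_at_205_bp_for_natural_dna(self):
        n = np.arange(201, 212)
        j = jfactor_model(n, DNA1)
        assert n[np.argmin(j)] == 205
        # 205/10.52 = 19.49, the nearest half-integer linking number
        assert abs((205 / 10.52) % 1.0 - 0.5) < 0.02

    def test_phase_averaging_limit(self):
        # huge linking-number variance flattens the oscillation
        flat = TopoisomerSpec(var_override_turns2=1e4)
        n = np.arange(201, 212)
        j = jfactor_model(n, DNA1, flat)
        assert j.max() / j.min() < 1.5
        sharp = jfactor_model(n, DNA1)
        assert sharp.max() / sharp.min() > 10

    def test_rank_order_matches_published_data(self, dna1_dataset):
        from scipy.stats import spearmanr

        j = jfactor_model(dna1_dataset.n_bp, DNA1)
        rho = spearmanr(j, dna1_dataset.J_nM).statistic
        assert rho > 0.95

    def test_oscillation_period_equals_helical_repeat(self):
        n = np.arange(195.0, 220.0, 0.01)
        j = np.asarray(jfactor_model(n, DNA1))
        interior = (j[1:-1] > j[:-2]) & (j[1:-1] > j[2:])
        peaks = n[1:-1][interior]
        spacing = np.diff(peaks)
        assert np.all(np.abs(spacing - 10.52) < 0.2)


class TestInvariants:
    @settings(derandomize=True, max_examples=60)
    @given(
        P=st.floats(20, 90),
        g0=st.floats(10.0, 11.0),
        c19=st.floats(0.3, 5.0),
        n_bp=st.integers(160, 380),
    )
    def test_positivity(self, P, g0, c19, n_bp):
        params = MechanicalParams.from_scaled(P, g0, c19)
        assert bend_jfactor(n_bp, params) > 0
        assert twist_factor(n_bp, params) > 0
        assert linking_variance(n_bp, params) > 0
        assert jfactor_model(n_bp, params) > 0

    def test_torsion_unit_consistency(self, presets):
        # every published (C, Pt) pair satisfies C = kT Pt at 295.15 K
        for _, row in presets.iterrows():
            params = MechanicalParams.from_scaled(
                row["P_nm"], row["gamma0_bp_per_turn"], row["C_1e19_erg_cm"]
            )
            assert params.twist_persistence_nm == pytest.approx(
                row["Pt_nm"], abs=0.31
            )

    def test_params_serialization_roundtrip(self):
        d = DNA1.to_dict()
        back = MechanicalParams.from_dict(d)
        assert back.P_nm == DNA1.P_nm
        assert back.gamma0_bp_per_turn == DNA1.gamma0_bp_per_turn
        assert back.C_erg_cm == pytest.approx(DNA1.C_erg_cm, rel=1e-12)
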