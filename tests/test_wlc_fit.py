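"""Estimation tests: weighted least squares, grid oracle, Monte Carlo."""
import numpy as np
import pytest

from conftest import make_synthetic_dataset
from dnamech.datasets import jfactor_rows
from dnamech.wlc_fit import (
    JFactorDataset,
    ParameterBounds,
    derive_pt,
    fit_wlc,
    mc_uncertainty,
)
from dnamech.wlc_model import MechanicalParams, TopoisomerSpec, jfactor_model


class TestDatasetInvariants:
    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            JFactorDataset("x", [201, 203, 205], [1, 2, 3], [0.1, 0.1, 0.1])

    def test_unsorted_lengths_rejected(self):
        with pytest.raises(ValueError):
            JFactorDataset("x", [205, 203, 201, 207], [1, 2, 3, 4], [0.1] * 4)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            JFactorDataset("x", [201, 203, 205, 207], [1, -2, 3, 4], [0.1] * 4)


class TestFitWLC:
    def test_noiseless_self_consistency(self):
        truth = MechanicalParams.from_scaled(48.0, 10.55, 1.8)
        data = make_synthetic_dataset(truth, np.arange(201, 212), noise=0.0, seed=0)
        # 1%-of-J sds, exact means: truth must be recovered almost exactly
        data = JFactorDataset(data.label, data.n_bp, data.J_nM, 0.01 * data.J_nM)
        fit = fit_wlc(data, seed=2)
        assert fit.converged
        assert fit.cost < 1e-10
        assert fit.params.P_nm == pytest.approx(48.0, rel=1e-4)
        assert fit.params.gamma0_bp_per_turn == pytest.approx(10.55, abs=1e-4)
        assert fit.params.C_erg_cm == pytest.approx(1.8e-19, rel=1e-3)

    def test_grid_search_oracle_brackets_optimum(self):
        # coarse brute-force grid over the published DNA 6 data: the
        # optimizer must do at least as well as the best grid node
        data = JFactorDataset.from_dataframe(jfactor_rows("DNA6"))
        fit = fit_wlc(data, seed=3)
        P = np.arange(30.0, 70.1, 1.0)
        G = np.arange(10.2, 10.85, 0.02)
        C = np.arange(0.3, 4.01, 0.1)
        best = np.inf
        w = 1.0 / data.J_sd_nM
        for g in G:
            for c in C:
                params = [MechanicalParams.from_scaled(p, g, c) for p in P]
                for pa in params:
                    r = (np.asarray(jfactor_model(data.n_bp, pa)) - data.J_nM) * w
                    best = min(best, float(r @ r))
        assert fit.cost <= best + 1e-9

    def test_init_outside_bounds_rejected(self):
        init = MechanicalParams.from_scaled(200.0, 10.5, 2.0)
        data = JFactorDataset("x", [201, 203, 205, 207], [1, 2, 3, 4], [0.1] * 4)
        with pytest.raises(ValueError, match="bounds"):
            fit_wlc(data, init=init)

    def test_parameter_recovery_under_noise(self):
        # closed loop at the stated study conditions: 6 lengths, 10% noise
        rng = np.random.default_rng(42)
        errs_P, errs_g, errs_C = [], [], []
        for rep in range(20):
            truth = MechanicalParams.from_scaled(
                rng.uniform(40, 60), rng.uniform(10.3, 10.8), rng.uniform(0.6, 3.3)
            )
            data = make_synthetic_dataset(
                truth, np.arange(201, 212, 2), noise=0.10, seed=1000 + rep
            )
            fit = fit_wlc(data, seed=rep)
            errs_P.append(abs(fit.params.P_nm - truth.P_nm) / truth.P_nm)
            errs_g.append(
                abs(fit.params.gamma0_bp_per_turn - truth.gamma0_bp_per_turn)
            )
            errs_C.append(abs(fit.params.C_erg_cm - truth.C_erg_cm) / truth.C_erg_cm)
        assert np.median(errs_P) < 0.05
        assert np.median(errs_g) < 0.05
        assert np.median(errs_C) < 0.15


class TestMonteCarlo:
    def test_same_seed_bit_identical(self, dna1_dataset, dna1_fit):
        a = mc_uncertainty(dna1_dataset, dna1_fit, n_sim=25, seed=11)
        b = mc_uncertainty(dna1_dataset, dna1_fit, n_sim=25, seed=11)
        assert a == b

    def test_degenerate_noise_gives_zero_spread(self):
        truth = MechanicalParams.from_scaled(50.0, 10.5, 2.0)
        n_bp = np.arange(201, 212, 2.0)
        j = np.asarray(jfactor_model(n_bp, truth))
        data = JFactorDataset("x", n_bp, j, np.full_like(j, 1e-12))
        fit = fit_wlc(data, seed=0)
        mc = mc_uncertainty(data, fit, n_sim=10, seed=0)
        assert all(v < 1e-6 for v in mc.sd.values())
        assert all(abs(v) < 1e-6 for v in mc.relative_bias.values())

    def test_n_sim_lower_bound(self, dna1_dataset, dna1_fit):
        with pytest.raises(ValueError):
            mc_uncertainty(dna1_dataset, dna1_fit, n_sim=1)

    def test_sd_scales_linearly_with_noise(self):
        # linearized error propagation: halving every sigma roughly halves
        # each parameter sd in the small-noise regime
        truth = MechanicalParams.from_scaled(50.0, 10.5, 2.0)
        n_bp = np.arange(201, 212, 1.0)
        j = np.asarray(jfactor_model(n_bp, truth))
        full = JFactorDataset("x", n_bp, j, 0.04 * j)
        half = JFactorDataset("x", n_bp, j, 0.02 * j)
        fit_full = fit_wlc(full, seed=0)
        fit_half = fit_wlc(half, seed=0)
        mc_full = mc_uncertainty(full, fit_full, n_sim=300, seed=5)
        mc_half = mc_uncertainty(half, fit_half, n_sim=300, seed=5)
        for key in mc_full.sd:
            ratio = mc_full.sd[key] / mc_half.sd[key]
            assert ratio == pytest.approx(2.0, rel=0.25)


class TestDerivePt:
    def test_published_pairs(self):
        p = MechanicalParams.from_scaled(51.5, 10.52, 2.27)
        assert derive_pt(p) == pytest.approx(55.7, abs=0.1)
        p5 = MechanicalParams.from_scaled(41.8, 10.69, 0.85)
        assert derive_pt(p5) == pytest.approx(20.9, abs=0.1)

    def test_vanishing_rigidity_limit(self):
        p = MechanicalParams.from_scaled(51.5, 10.52, 1e-20)
        assert derive_pt(p) < 1e-18
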