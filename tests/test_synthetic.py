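"""Generators: determinism, truth sidecars, closed-loop recovery."""
import numpy as np
import pytest

from dnamech.cd_hdr import compute_hdr
from dnamech.ligation_kinetics import fit_timecourse, simulate_ligation
from dnamech.melt_thermo import extrapolate_zero_dye, fit_two_state
from dnamech.synthetic_data import (
    GeneratorConfig,
    gen_cd_pairs,
    gen_jfactor_dataset,
    gen_meltcurves,
    gen_timecourse,
    preset_rates,
)
from dnamech.wlc_fit import fit_wlc


class TestDeterminism:
    def test_jfactor_same_seed_identical(self):
        a, ta = gen_jfactor_dataset(GeneratorConfig(seed=123))
        b, tb = gen_jfactor_dataset(GeneratorConfig(seed=123))
        assert np.array_equal(a.J_nM, b.J_nM)
        assert np.array_equal(a.J_sd_nM, b.J_sd_nM)
        assert ta == tb

    def test_different_seeds_differ(self):
        a, _ = gen_jfactor_dataset(GeneratorConfig(seed=1))
        b, _ = gen_jfactor_dataset(GeneratorConfig(seed=2))
        assert not np.array_equal(a.J_nM, b.J_nM)

    def test_timecourse_and_melt_same_seed_identical(self):
        t1, _ = gen_timecourse(GeneratorConfig(seed=5))
        t2, _ = gen_timecourse(GeneratorConfig(seed=5))
        assert np.array_equal(t1.conc_nM, t2.conc_nM)
        m1, _ = gen_meltcurves(GeneratorConfig(seed=5))
        m2, _ = gen_meltcurves(GeneratorConfig(seed=5))
        assert all(np.array_equal(a.signal, b.signal) for a, b in zip(m1, m2))


class TestJFactorGenerator:
    def test_noiseless_preset_minimum_at_205(self):
        data, truth = gen_jfactor_dataset(GeneratorConfig(seed=0, jfactor_noise=0.0))
        assert data.n_bp[np.argmin(data.J_nM)] == 205
        assert truth["params"]["P_nm"] == 51.5

    def test_truth_record_carries_clean_values(self):
        data, truth = gen_jfactor_dataset(GeneratorConfig(seed=7, jfactor_noise=0.1))
        clean = np.array(truth["J_true_nM"])
        assert np.all(data.J_nM > 0)
        # noisy means scatter around the clean forward values
        assert np.median(np.abs(data.J_nM / clean - 1.0)) < 0.3

    def test_noisy_refit_recovers_preset_bending_stiffness(self):
        # 20% noise: the fit still recovers the preset P within 5% median
        errs = []
        for rep in range(10):
            data, truth = gen_jfactor_dataset(
                GeneratorConfig(seed=2000 + rep, jfactor_noise=0.20)
            )
            fit = fit_wlc(data, seed=rep)
            errs.append(abs(fit.params.P_nm - 51.5) / 51.5)
        assert np.median(errs) < 0.05


class TestTimecourseGenerator:
    def test_zero_noise_matches_forward_model(self):
        cfg = GeneratorConfig(seed=0, timecourse_noise_nM=0.0, preset="DNA5")
        tc, truth = gen_timecourse(cfg)
        rates = preset_rates("DNA5", 201)
        clean = simulate_ligation(rates, 1.0, np.asarray(cfg.times_s))
        assert tc.conc_nM == pytest.approx(clean.conc_nM, abs=1e-12)

    def test_mass_balance_before_noise(self):
        rates = preset_rates("DNA1", 201, k_sink=1e-3)
        clean = simulate_ligation(rates, 1.0, np.arange(60.0, 901.0, 60.0))
        assert np.max(np.abs(clean.monomer_equivalents() - 1.0)) < 1e-9

    def test_preset_rate_ratio_recovered_by_fit(self):
        # DNA 5 published pair (403, 177) x 1e-4 -> J ~ 2.28 nM
        cfg = GeneratorConfig(seed=0, preset="DNA5", timecourse_noise_nM=0.0)
        tc, _ = gen_timecourse(cfg)
        fit = fit_timecourse(tc)
        assert fit.jfactor_nM == pytest.approx(2.28, abs=0.02)


class TestMeltGenerator:
    def test_zero_noise_zero_slope_shares_tm(self):
        cfg = GeneratorConfig(seed=0, melt_noise=0.0, dye_Tm_slope_C=0.0)
        curves, _ = gen_meltcurves(cfg)
        assert len(curves) == 12  # four dye levels in triplicate
        tms = {round(fit_two_state(c).Tm_C, 6) for c in curves[::3]}
        assert len(tms) == 1

    def test_linear_dye_effect_extrapolates_exactly(self):
        cfg = GeneratorConfig(seed=0, melt_noise=0.0, dye_Tm_slope_C=5.0)
        curves, truth = gen_meltcurves(cfg)
        fits = [(c.dye, fit_two_state(c)) for c in curves]
        zero = extrapolate_zero_dye(fits)
        assert zero.Tm_C == pytest.approx(truth["Tm0_C"], abs=1e-3)

    def test_replicate_spread_within_experimental_band(self):
        # 1% noise: replicate Tm spread stays below the reported 0.3-0.7 C
        # experimental spreads (synthetic curves carry no instrument drift)
        cfg = GeneratorConfig(seed=3, melt_noise=0.01, dye_Tm_slope_C=0.0)
        curves, _ = gen_meltcurves(cfg)
        tms = [fit_two_state(c).Tm_C for c in curves[:3]]
        assert np.std(tms) < 0.7


class TestCDGenerator:
    @pytest.mark.parametrize("target,group", [(0.25, "B-type"), (-1.0, "Z-type")])
    def test_targets_hit_exactly(self, target, group):
        spectra, _ = gen_cd_pairs(GeneratorConfig(seed=0), targets={"x": target})
        res = compute_hdr(spectra["x"])
        assert res.hdr == pytest.approx(target, abs=1e-6)
        assert res.group == group

    def test_truth_record_lists_groups(self):
        _, truth = gen_cd_pairs(GeneratorConfig(seed=0))
        assert truth["groups"]["DNA9"] == "A-type"
        assert truth["groups"]["DNA6"] == "Z-type"
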