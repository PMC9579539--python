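import numpy as np
import pytest

from bcellpipe.datatypes import ElisaCurve, KineticParameters
from bcellpipe.kinetics import (
    FitOptions,
    PreprocessParams,
    compare_groups,
    elisa_auc,
    fit_langmuir,
    langmuir_predict,
    preprocess_sensorgram,
)
from bcellpipe.synthetic import (
    LogisticParams,
    SprConfig,
    simulate_elisa,
    simulate_sensorgram,
)

from .oracles import integrate_binding_ode

TRUE = dict(ka=1e5, kd=1e-3, rmax=100.0)


class TestPreprocess:
    def test_constant_offset_removed(self):
        with_offset = preprocess_sensorgram(
            simulate_sensorgram(SprConfig(noise_sd=0.0, baseline_offset=50.0), 0))
        without = preprocess_sensorgram(
            simulate_sensorgram(SprConfig(noise_sd=0.0, baseline_offset=0.0), 0))
        np.testing.assert_allclose(with_offset.df["ru"].to_numpy(),
                                   without.df["ru"].to_numpy(), atol=1e-9)

    def test_time_rezeroed_at_injection(self):
        cfg = SprConfig(noise_sd=0.0, baseline_s=25.0)
        clean = preprocess_sensorgram(simulate_sensorgram(cfg, 0),
                                      PreprocessParams(spike_window_s=0.0))
        for conc in clean.concentrations:
            assert clean.trace(conc)["time_s"].iloc[0] == pytest.approx(0.0)

    def test_spike_window_drops_boundary_samples(self):
        cfg = SprConfig(noise_sd=0.0, spike_amplitude=40.0)
        clean = preprocess_sensorgram(simulate_sensorgram(cfg, 0),
                                      PreprocessParams(spike_window_s=2.0))
        t = clean.df["time_s"].to_numpy()
        assert not ((t >= 0) & (t < 2.0)).any()
        ta = cfg.association_s
        assert not ((t >= ta) & (t < ta + 2.0)).any()

    def test_missing_baseline_rejected(self):
        cfg = SprConfig(baseline_s=0.0)
        raw = simulate_sensorgram(cfg, 0)
        with pytest.raises(ValueError, match="pre-injection"):
            preprocess_sensorgram(raw)


class TestLangmuirPredict:
    def test_zero_time_association_is_zero(self):
        p = KineticParameters(**TRUE)
        assert langmuir_predict(p, 1e-6, np.array([0.0]), "assoc")[0] == 0.0

    def test_plateau_is_half_rmax_at_c_equal_kd(self):
        p = KineticParameters(**TRUE)  # KD = 1e-8 M
        r = langmuir_predict(p, 1e-8, np.array([1e9]), "assoc")[0]
        assert r == pytest.approx(TRUE["rmax"] / 2)

    def test_dissociation_half_life(self):
        p = KineticParameters(**TRUE)
        t_half = np.log(2) / p.kd
        assert t_half == pytest.approx(693.1, abs=0.1)
        r0 = langmuir_predict(p, 1e-6, np.array([60.0]), "assoc")[0]
        r = langmuir_predict(p, 1e-6, np.array([60.0 + t_half]), "dissoc", t_assoc=60.0)[0]
        assert r == pytest.approx(r0 / 2, rel=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            langmuir_predict(KineticParameters(**TRUE), 1e-6, np.array([-1.0]), "assoc")

    def test_agrees_with_ode_integration(self):
        # invariant: closed form vs dR/dt = ka C (Rmax - R) - kd R to 1e-6 RU
        p = KineticParameters(**TRUE)
        t_a = np.linspace(0, 60, 121)
        t_d = np.linspace(0, 900, 301)
        for conc in (100e-6, 800e-9, 32e-9):
            r_a, r_d = integrate_binding_ode(p.ka, p.kd, p.rmax, conc, t_a, t_d, 60.0)
            np.testing.assert_allclose(
                langmuir_predict(p, conc, t_a, "assoc"), r_a, atol=1e-6)
            np.testing.assert_allclose(
                langmuir_predict(p, conc, t_d + 60.0, "dissoc", t_assoc=60.0),
                r_d, atol=1e-6)

    def test_req_monotone_in_concentration(self):
        p = KineticParameters(**TRUE)
        concs = np.logspace(-9, -4, 12)
        plateaus = [langmuir_predict(p, c, np.array([1e9]), "assoc")[0] for c in concs]
        assert (np.diff(plateaus) > 0).all()


class TestFitLangmuir:
    def test_noise_free_recovery(self, noise_free_sensorgrams):
        _, raw = noise_free_sensorgrams
        fit = fit_langmuir(preprocess_sensorgram(raw))
        assert fit.ka == pytest.approx(TRUE["ka"], rel=1e-4)
        assert fit.kd == pytest.approx(TRUE["kd"], rel=1e-4)
        assert fit.rmax == pytest.approx(TRUE["rmax"], rel=1e-4)

    def test_kd_over_ka_identity(self):
        p = KineticParameters(ka=1e5, kd=1e-3, rmax=50.0)
        assert p.kD == 1e-8

    def test_noisy_recovery_within_ten_percent(self):
        cfg = SprConfig(noise_sd=1.0)
        for seed in range(3):
            fit = fit_langmuir(preprocess_sensorgram(simulate_sensorgram(cfg, seed)))
            assert fit.ka == pytest.approx(TRUE["ka"], rel=0.10)
            assert fit.kd == pytest.approx(TRUE["kd"], rel=0.10)

    def test_consistency_as_noise_vanishes(self):
        errors = []
        for noise in (1.0, 0.1, 0.01):
            fit = fit_langmuir(preprocess_sensorgram(
                simulate_sensorgram(SprConfig(noise_sd=noise), seed=0)))
            errors.append(abs(fit.ka - TRUE["ka"]) / TRUE["ka"])
        assert errors[2] < errors[0]
        assert errors[2] < 1e-3

    def test_kd_invariant_under_rmax_rescale(self):
        fits = []
        for rmax in (50.0, 200.0):
            cfg = SprConfig(noise_sd=0.0, rmax=rmax)
            fits.append(fit_langmuir(preprocess_sensorgram(simulate_sensorgram(cfg, 0))))
        assert fits[0].kD == pytest.approx(fits[1].kD, rel=1e-6)

    def test_reports_standard_errors_and_rms(self):
        fit = fit_langmuir(preprocess_sensorgram(
            simulate_sensorgram(SprConfig(noise_sd=1.0), seed=1)))
        assert fit.ka_se > 0 and fit.kd_se > 0
        assert fit.residual_rms == pytest.approx(1.0, rel=0.2)

    def test_per_curve_mode(self, noise_free_sensorgrams):
        _, raw = noise_free_sensorgrams
        fit = fit_langmuir(preprocess_sensorgram(raw), FitOptions(per_curve=True))
        assert fit.ka == pytest.approx(TRUE["ka"], rel=1e-3)


class TestElisaAuc:
    def test_all_zero_od_gives_zero(self):
        curve = ElisaCurve(dilution=2.0 ** np.arange(8), od450=np.zeros(8))
        assert elisa_auc(curve) == 0.0

    def test_constant_od_rectangle(self):
        curve = ElisaCurve(dilution=2.0 ** np.arange(8), od450=np.ones(8))
        assert elisa_auc(curve) == pytest.approx(7 * np.log10(2), abs=1e-12)
        assert elisa_auc(curve) == pytest.approx(2.107, abs=0.001)

    def test_matches_dense_grid_quadrature(self):
        # oracle: fine-grid numerical integration of the same logistic curve
        params = LogisticParams(od_max=2.0, ec50=0.05, hill=1.2)
        curve = simulate_elisa(params=params, noise_sd=0.0)
        dense = simulate_elisa(params=params, noise_sd=0.0, points=8,
                               dilution_factor=2.0)
        x = np.linspace(0, 7 * np.log10(2), 20_001)
        conc = 1.0 / (10.0 ** x)
        od = params.od_background + (params.od_max - params.od_background) / (
            1 + (params.ec50 / conc) ** params.hill)
        exact = np.trapezoid(od, x)
        assert elisa_auc(curve) == pytest.approx(exact, rel=0.02)

    def test_non_monotone_dilution_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ElisaCurve(dilution=np.array([1.0, 4.0, 2.0]), od450=np.ones(3))


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        result = compare_groups({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert result["p"] == pytest.approx(1.0)

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(0)
        result = compare_groups({
            "a": list(rng.normal(0, 1, 10)),
            "b": list(rng.normal(10, 1, 10)),
        })
        assert result["p"] < 0.001

    def test_matches_textbook_f_formula(self):
        # oracle: explicit between/within mean squares
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0], "c": [5.0, 5.0, 8.0]}
        values = np.concatenate([np.asarray(v) for v in groups.values()])
        grand = values.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f = (ss_between / 2) / (ss_within / 6)
        result = compare_groups(groups)
        assert result["F"] == pytest.approx(f, rel=1e-12)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0]})
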