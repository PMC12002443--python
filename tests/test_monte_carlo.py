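import numpy as np
import pytest
from scipy import stats

import pyhttk as h
from pyhttk.monte_carlo import (
    sample_censored_truncated,
    sample_invitro_uv,
    sample_population_physiology,
)


class TestCensoredTruncated:
    def test_degenerate_cv_limit(self):
        rng = np.random.default_rng(0)
        draws = sample_censored_truncated(5.0, cv=1e-12, n=100, rng=rng)
        np.testing.assert_allclose(draws, 5.0, rtol=1e-6)

    def test_mean_matches_truncated_normal_moment(self):
        """Sample mean within 3 SE of the analytic truncated-normal mean."""
        baseline, cv, n = 10.0, 0.3, 10_000
        rng = np.random.default_rng(1)
        draws = sample_censored_truncated(baseline, cv, n=n, rng=rng)
        sd = cv * baseline
        a = (0.0 - baseline) / sd
        expected = stats.truncnorm.mean(a, np.inf, loc=baseline, scale=sd)
        se = stats.truncnorm.std(a, np.inf, loc=baseline, scale=sd) / np.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se

    def test_censoring_saturation(self):
        rng = np.random.default_rng(2)
        baseline, cv = 1.0, 0.1
        lod = baseline + 5 * cv * baseline + 1.0  # above every plausible draw
        draws = sample_censored_truncated(baseline, cv, lod=lod, n=500, rng=rng)
        assert np.all((draws >= 0) & (draws < lod))
        # uniform replacement: mean ~ lod/2
        assert abs(draws.mean() - lod / 2) < lod * 0.1

    def test_invalid_cv(self):
        with pytest.raises(ValueError):
            sample_censored_truncated(1.0, cv=0.0)


class TestPopulationSampler:
    def test_zero_variance_reference_individuals(self):
        spec = h.PopulationSpec(cv_bw=1e-12, cv_flow=1e-12, cv_gfr=1e-12,
                                cv_hepatocellularity=1e-12)
        rng = np.random.default_rng(3)
        pop = sample_population_physiology("Human", spec, 50, rng)
        phys = h.load_physiology("Human")
        np.testing.assert_allclose(pop["BW"], phys.BW, rtol=1e-9)
        np.testing.assert_allclose(pop["flow_factor"], 1.0, rtol=1e-9)

    def test_median_bw_matches_reference(self):
        rng = np.random.default_rng(4)
        pop = sample_population_physiology("Human", h.PopulationSpec(), 10_000, rng)
        phys = h.load_physiology("Human")
        assert np.median(pop["BW"]) == pytest.approx(phys.BW, rel=0.02)

    def test_nonhuman_population_rejected(self):
        with pytest.raises(ValueError, match="non-human"):
            sample_population_physiology(
                "Rat", h.PopulationSpec(), 10, np.random.default_rng(0)
            )


class TestInvitroSampler:
    def _chem(self, clint, fup):
        return h.ChemicalRecord(
            dtxsid="X", MW=200.0, logP=2.0,
            Clint={"Human": clint}, fup={"Human": fup},
        )

    def test_p_no_effect_one_gives_all_zero(self):
        chem = self._chem(h.UncertainValue(10.0, 5.0, 20.0, 1.0), h.UncertainValue(0.1))
        out = sample_invitro_uv(chem, h.MCConfig(n=100), 100, np.random.default_rng(5))
        assert np.all(out["Clint"] == 0.0)

    def test_clint_quantile_matched_lognormal(self):
        """(13, 9.2, 16.2) tuple: recovered median and 95% interval."""
        chem = self._chem(
            h.UncertainValue(13.0, 9.2, 16.2, 0.0), h.UncertainValue(0.1)
        )
        n = 100_000
        out = sample_invitro_uv(chem, h.MCConfig(n=n), n, np.random.default_rng(6))
        cl = out["Clint"]
        assert np.median(cl) == pytest.approx(13.0, rel=0.02)
        assert np.quantile(cl, 0.025) == pytest.approx(9.2, rel=0.03)
        assert np.quantile(cl, 0.975) == pytest.approx(16.2, rel=0.03)

    def test_fup_draws_bounded(self):
        chem = self._chem(h.UncertainValue(5.0), h.UncertainValue(0.2, 0.1, 0.4))
        out = sample_invitro_uv(chem, h.MCConfig(n=5000), 5000, np.random.default_rng(7))
        assert np.all((out["fup"] > 0) & (out["fup"] <= 1.0))
        assert np.median(out["fup"]) == pytest.approx(0.2, rel=0.05)


class TestCreateMcSamples:
    def test_all_variance_off_equals_baseline(self, lib, chem):
        cfg = h.MCConfig(n=20, seed=8, invitrouv=False)
        baseline = h.parameterize_model("pbtk", chem, lib=lib)
        samples = h.create_mc_samples("pbtk", chem, config=cfg, lib=lib, baseline=baseline)
        for col in samples.table.columns:
            np.testing.assert_array_equal(samples.table[col], baseline[col])
        assert set(samples.provenance.values()) == {"baseline"}

    def test_same_seed_identical_table(self, lib, chem):
        cfg = h.MCConfig(n=50, seed=9)
        a = h.create_mc_samples("pbtk", chem, config=cfg, lib=lib)
        b = h.create_mc_samples("pbtk", chem, config=cfg, lib=lib)
        assert a.table.equals(b.table)

    def test_calcpc_recomputes_kp_from_row_fup(self, lib, chem):
        """Spot-check: per-row Kp equals a fresh partition prediction at
        that row's fup."""
        from pyhttk.partition import lump_tissues, predict_partitioning_schmitt
        from pyhttk.parameterize import load_tissue_table

        cfg = h.MCConfig(n=10, seed=10)
        samples = h.create_mc_samples("pbtk", chem, config=cfg, lib=lib)
        tissues = load_tissue_table()
        info = h.get_model("pbtk")
        for i in range(10):
            fup_i = samples.table.at[i, "fup"]
            kp = predict_partitioning_schmitt(chem, float(fup_i), tissues)
            lumped, _, _ = lump_tissues(kp, tissues, info.lumping_scheme)
            for comp, val in lumped.items():
                assert samples.table.at[i, f"K{comp}2pu"] == pytest.approx(val, rel=1e-12)
        assert samples.provenance["Kliver2pu"] == "recalc"

    def test_step1_overlap_warns(self, lib, chem):
        cfg = h.MCConfig(n=5, seed=11, vary_params={"fup": 0.2}, invitrouv=True)
        with pytest.warns(UserWarning, match="overwritten"):
            h.create_mc_samples("pbtk", chem, config=cfg, lib=lib)

    def test_httkpop_overwrites_physiology(self, lib, chem):
        cfg = h.MCConfig(n=30, seed=12, httkpop=True, invitrouv=False)
        samples = h.create_mc_samples("pbtk", chem, config=cfg, lib=lib)
        assert samples.provenance["BW"] == "pop"
        assert samples.table["BW"].nunique() == 30
        # untouched chemical parameters stay baseline
        assert samples.provenance["MW"] == "baseline"


class TestMcCss:
    def test_zero_variance_equals_analytic_exactly(self, lib, chem):
        cfg = h.MCConfig(n=7, seed=13, invitrouv=False, quantiles=(0.05, 0.5, 0.95))
        out = h.calc_mc_css("pbtk", chem, config=cfg, lib=lib)
        det = h.calc_analytic_css("pbtk", chem=chem, lib=lib)
        assert np.all(out["draws"] == det)
        assert all(v == det for v in out["quantiles"].values())

    def test_quantiles_monotone(self, lib, chem):
        cfg = h.MCConfig(n=300, seed=14, quantiles=(0.05, 0.5, 0.95))
        out = h.calc_mc_css("pbtk", chem, config=cfg, lib=lib)
        q = out["quantiles"]
        assert q[0.05] <= q[0.5] <= q[0.95]

    def test_rmsle_nomc_finite_across_library(self, lib):
        """noMC benchmark: MC medians vs analytic Css across chemicals."""
        from pyhttk.evaluate import rmsle

        ids = list(h.get_cheminfo(lib, model="pbtk")["dtxsid"])[:10]
        med, ana = [], []
        for cid in ids:
            chem = lib[cid]
            try:
                a = h.calc_analytic_css("pbtk", chem=chem, lib=lib)
            except ZeroDivisionError:
                continue
            out = h.calc_mc_css(
                "pbtk", chem, config=h.MCConfig(n=100, seed=15), lib=lib
            )
            if a > 0 and np.isfinite(out["median"]) and out["median"] > 0:
                med.append(out["median"])
                ana.append(a)
        val = rmsle(med, ana)
        assert np.isfinite(val)
        assert val < 1.0  # medians track the deterministic values


class TestOralEquivalent:
    def test_inversion_identity_zero_variance(self, lib, chem):
        det = h.calc_analytic_css("pbtk", chem=chem, lib=lib)  # Css at 1 mg/kg/day
        cfg = h.MCConfig(n=5, seed=16, invitrouv=False, quantiles=(0.5,))
        out = h.calc_mc_oral_equiv(det, "pbtk", chem, config=cfg, lib=lib)
        assert out["median_dose"] == pytest.approx(1.0, rel=1e-12)

    def test_linearity_in_target(self, lib, chem):
        cfg = h.MCConfig(n=50, seed=17)
        a = h.calc_mc_oral_equiv(1.0, "pbtk", chem, config=cfg, lib=lib)
        b = h.calc_mc_oral_equiv(2.0, "pbtk", chem, config=cfg, lib=lib)
        assert b["median_dose"] == pytest.approx(2 * a["median_dose"], rel=1e-9)

    def test_high_quantile_gives_lower_dose(self, lib, chem):
        cfg = h.MCConfig(n=200, seed=18, quantiles=(0.5, 0.95))
        out = h.calc_mc_oral_equiv(1.0, "pbtk", chem, config=cfg, lib=lib)
        assert out["quantile_doses"][0.95] <= out["quantile_doses"][0.5]


class TestMcTk:
    def test_zero_variance_sd_zero(self, lib, chem, oral_regimen):
        cfg = h.MCConfig(n=3, seed=19, invitrouv=False)
        out = h.calc_mc_tk("pbtk", chem, config=cfg, lib=lib,
                           times=np.linspace(0, 1, 13), regimen=oral_regimen)
        assert np.all(out["Cplasma"]["sd"] == 0.0)
        single = h.solve_model("pbtk", chem=chem, lib=lib,
                               times=np.linspace(0, 1, 13), regimen=oral_regimen,
                               rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(out["Cplasma"]["mean"], single.column("Cplasma"),
                                   rtol=1e-9)

    def test_single_draw_flagged(self, lib, chem, oral_regimen):
        cfg = h.MCConfig(n=1, seed=20)
        out = h.calc_mc_tk("pbtk", chem, config=cfg, lib=lib,
                           times=np.linspace(0, 1, 7), regimen=oral_regimen)
        assert out["n"] == 1
        assert out.get("sd_undefined") is True
        assert np.all(out["Cplasma"]["sd"] == 0.0)

    def test_mean_converges_with_draws(self, lib, chem, oral_regimen):
        """Monte Carlo convergence: a small-n mean lies within 3 SE of a
        larger-n reference mean."""
        times = np.linspace(0, 1, 7)
        small = h.calc_mc_tk("pbtk", chem, config=h.MCConfig(n=30, seed=21),
                             lib=lib, times=times, regimen=oral_regimen)
        big = h.calc_mc_tk("pbtk", chem, config=h.MCConfig(n=120, seed=22),
                           lib=lib, times=times, regimen=oral_regimen)
        k = -1  # final time point
        se = np.hypot(small["Cplasma"]["sd"][k] / np.sqrt(30),
                      big["Cplasma"]["sd"][k] / np.sqrt(120))
        assert abs(small["Cplasma"]["mean"][k] - big["Cplasma"]["mean"][k]) < 4 * se
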