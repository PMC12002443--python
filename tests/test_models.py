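import dataclasses

import numpy as np
import pytest

import pyhttk as h
from pyhttk.models import registry
from pyhttk.models.dosing import build_event_schedule
from pyhttk.models.solve import solver_params


class TestRegistry:
    def test_builtins_registered(self):
        assert set(h.list_models()) >= {"1compartment", "3compartmentss", "pbtk", "gas_pbtk"}

    def test_lookup_returns_same_info(self):
        info = h.get_model("pbtk")
        assert info.name == "pbtk"
        assert h.get_model("pbtk") is info

    def test_duplicate_registration_rejected(self):
        info = h.get_model("pbtk")
        with pytest.raises(KeyError, match="already registered"):
            h.register_model(info)

    def test_unknown_model(self):
        with pytest.raises(KeyError, match="unknown model"):
            h.get_model("nope")


class TestValidateModel:
    @pytest.mark.parametrize("model", ["pbtk", "1compartment", "gas_pbtk"])
    def test_builtins_validate_clean(self, model, lib, chem, volatile_chem):
        rec = volatile_chem if model == "gas_pbtk" else chem
        p = solver_params(h.parameterize_model(model, rec, lib=lib))
        assert h.validate_model(h.get_model(model), probe_params=p) == []

    @pytest.mark.parametrize("model", ["pbtk", "1compartment", "gas_pbtk"])
    @pytest.mark.parametrize("swap", [(0, 1), (2, 5), (-1, -2)])
    def test_any_output_permutation_detected(self, model, swap, lib, chem, volatile_chem):
        """A permuted output declaration must fail the sentinel probe."""
        rec = volatile_chem if model == "gas_pbtk" else chem
        info = h.get_model(model)
        names = list(info.derivative_output_names)
        i, j = swap
        names[i], names[j] = names[j], names[i]
        bad = dataclasses.replace(info, derivative_output_names=tuple(names))
        p = solver_params(h.parameterize_model(model, rec, lib=lib))
        failures = h.validate_model(bad, probe_params=p)
        assert any("ordering" in f for f in failures)

    def test_missing_unit_detected(self, lib, chem):
        info = h.get_model("pbtk")
        units = dict(info.compartment_units)
        units.pop("Cplasma")
        bad = dataclasses.replace(info, compartment_units=units)
        failures = h.validate_model(bad)
        assert any("compartment_units" in f for f in failures)

    def test_route_without_target_detected(self):
        info = h.get_model("pbtk")
        bad = dataclasses.replace(info, dose_targets={"oral": "Agutlumen"})
        failures = h.validate_model(bad)
        assert any("'iv'" in f for f in failures)


class TestEvaluateDerivative:
    def test_zero_state_zero_derivative(self, lib, chem, pbtk_params):
        p = solver_params(pbtk_params)
        dydt, aux = h.models.evaluate_derivative(
            "pbtk", 0.0, np.zeros(len(h.get_model("pbtk").state_vars)), p
        )
        assert np.all(dydt == 0.0)

    def test_closed_system_conserves_mass(self, lib, chem, pbtk_params):
        """No elimination, no input: compartment amounts sum to a constant."""
        p = solver_params(pbtk_params)
        p = dict(p, Clint_w=0.0, GFR=0.0)
        info = h.get_model("pbtk")
        rng = np.random.default_rng(4)
        y = rng.uniform(0.1, 5.0, len(info.state_vars))
        dydt, _ = h.models.evaluate_derivative("pbtk", 0.0, y, p)
        idx = {sv: i for i, sv in enumerate(info.state_vars)}
        mass_states = [
            i for sv, i in idx.items()
            if sv not in ("AUC",)
        ]
        assert np.sum(dydt[mass_states]) == pytest.approx(0.0, abs=1e-9)

    def test_pbtk_matches_independent_perfusion_limited_rhs(self, pbtk_params):
        """Duplicate-implementation oracle of the textbook rate laws."""
        p = solver_params(pbtk_params)
        info = h.get_model("pbtk")
        rng = np.random.default_rng(11)
        y = rng.uniform(0.0, 10.0, len(info.state_vars))
        dydt, _ = h.models.evaluate_derivative("pbtk", 0.0, y, p)

        # independent, deliberately verbose re-derivation
        agl, agut, aliv, akid, alung, arest, aart, aven = y[:8]
        fup, r = p["fup"], p["Rblood2plasma"]
        c = {
            "gut": agut / p["Vgut"], "liver": aliv / p["Vliver"],
            "kidney": akid / p["Vkidney"], "lung": alung / p["Vlung"],
            "rest": arest / p["Vrest"],
        }
        cart, cven = aart / p["Vart"], aven / p["Vven"]
        out = {k: c[k] * r / (p[f"K{k}2pu"] * fup) for k in c}
        fa = p["Fabs"] * p["Fgut"]
        exp = np.empty(8)
        exp[0] = -p["ka"] * agl
        exp[1] = p["ka"] * fa * agl + p["Qgut"] * (cart - out["gut"])
        exp[2] = (p["Qliver"] * cart + p["Qgut"] * out["gut"]
                  - (p["Qliver"] + p["Qgut"]) * out["liver"]
                  - p["Clint_w"] * c["liver"] / p["Kliver2pu"])
        exp[3] = p["Qkidney"] * (cart - out["kidney"]) - p["GFR"] * c["kidney"] / p["Kkidney2pu"]
        exp[4] = p["Qcardiac"] * (cven - out["lung"])
        exp[5] = p["Qrest"] * (cart - out["rest"])
        exp[6] = p["Qcardiac"] * (out["lung"] - cart)
        exp[7] = ((p["Qliver"] + p["Qgut"]) * out["liver"] + p["Qkidney"] * out["kidney"]
                  + p["Qrest"] * out["rest"] - p["Qcardiac"] * cven)
        # reorder venous/arterial rows to the model's state ordering
        model_rows = [0, 1, 2, 3, 4, 5, 6, 7]
        np.testing.assert_allclose(dydt[[6, 7]], exp[[6, 7]], rtol=1e-10)
        np.testing.assert_allclose(dydt[:6], exp[:6], rtol=1e-10)

    def test_nonfinite_state_rejected(self, pbtk_params):
        p = solver_params(pbtk_params)
        y = np.zeros(len(h.get_model("pbtk").state_vars))
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            h.models.evaluate_derivative("pbtk", 0.0, y, p)


class TestEventSchedule:
    def test_three_daily_doses_equally_split(self):
        info = h.get_model("pbtk")
        reg = h.DoseRegimen(route="oral", daily_dose=1.0, doses_per_day=3,
                            input_units="mg/kg/day")
        times = np.linspace(0, 1, 25)
        events, _, grid = build_event_schedule(reg, info, BW=70.0, MW=100.0, times=times)
        day0 = [r for r in events.rows if r[1] < 1.0]
        assert [r[1] for r in day0] == pytest.approx([0.0, 1 / 3, 2 / 3])
        per_dose_umol = (1.0 / 3) * 70.0 * 1000 / 100.0
        assert all(r[2] == pytest.approx(per_dose_umol) for r in day0)

    def test_empty_regimen(self):
        info = h.get_model("pbtk")
        times = np.linspace(0, 1, 5)
        events, forcing, grid = build_event_schedule(
            h.DoseRegimen(route="oral"), info, 70.0, 100.0, times
        )
        assert events.rows == []
        np.testing.assert_array_equal(grid, times)

    def test_intermediate_dose_time_in_grid_not_output(self, lib, chem):
        times = np.linspace(0, 1, 5)  # 0.25 steps
        reg = h.DoseRegimen(route="oral", dosing_matrix=((0.1, 1.0),),
                            input_units="mg/kg")
        info = h.get_model("pbtk")
        events, _, grid = build_event_schedule(reg, info, 70.0, 100.0, times)
        assert 0.1 in grid
        res = h.solve_model("pbtk", chem=chem, lib=lib, times=times, regimen=reg)
        assert 0.1 not in res.times
        assert res.times.size == times.size

    def test_unsupported_route_names_supported(self):
        info = h.get_model("1compartment")
        with pytest.raises(ValueError, match="oral"):
            build_event_schedule(
                h.DoseRegimen(route="inhalation"), info, 70.0, 100.0, np.linspace(0, 1, 3)
            )


class TestSolveModel:
    def test_zero_dose_all_zero(self, lib, chem):
        res = h.solve_model("pbtk", chem=chem, lib=lib,
                            times=np.linspace(0, 1, 9),
                            regimen=h.DoseRegimen(route="oral", initial_dose=0.0))
        assert np.all(res.column("Cplasma") == 0.0)

    def test_one_compartment_iv_matches_closed_form(self, lib, chem):
        p = h.parameterize_model("1compartment", chem, lib=lib)
        times = np.linspace(0, 2, 49)
        res = h.solve_model(
            "1compartment", params=p, times=times,
            regimen=h.DoseRegimen(route="iv", initial_dose=1.0, input_units="mg/kg"),
            rtol=1e-8, atol=1e-12,
        )
        dose_umol = 1.0 * p["BW"] * 1000.0 / p["MW"]
        closed = dose_umol / p["Vdist"] * np.exp(-p["kelim"] * 24.0 * times)
        np.testing.assert_allclose(res.column("Cplasma"), closed, rtol=1e-3)

    def test_linearity_dose_doubling(self, lib, chem, oral_regimen):
        times = np.linspace(0, 2, 25)
        kw = dict(lib=lib, times=times, rtol=1e-9, atol=1e-13)
        r1 = h.solve_model("pbtk", chem=chem, regimen=oral_regimen, **kw)
        r2 = h.solve_model(
            "pbtk", chem=chem,
            regimen=h.DoseRegimen(route="oral", initial_dose=2.0, input_units="mg/kg"),
            **kw,
        )
        ratio = r2.column("Cplasma")[1:] / r1.column("Cplasma")[1:]
        np.testing.assert_allclose(ratio, 2.0, rtol=1e-6)

    def test_output_units_converted(self, lib, chem, oral_regimen):
        times = np.linspace(0, 1, 9)
        res = h.solve_model("pbtk", chem=chem, lib=lib, times=times, regimen=oral_regimen,
                            output_units={"Cplasma": "mg/L"})
        res_uM = h.solve_model("pbtk", chem=chem, lib=lib, times=times, regimen=oral_regimen)
        assert res.units["Cplasma"] == "mg/L"
        np.testing.assert_allclose(
            res.column("Cplasma"), res_uM.column("Cplasma") * chem.MW / 1000.0, rtol=1e-12
        )

    def test_solver_convergence_under_tolerance_refinement(self, lib, chem, oral_regimen):
        """Global error shrinks with the local tolerance (LSODA amplifies the
        local tolerance by a bounded factor over the integration)."""
        times = np.linspace(0, 2, 25)
        runs = {
            rt: h.solve_model("pbtk", chem=chem, lib=lib, times=times,
                              regimen=oral_regimen, rtol=rt, atol=rt * 1e-4)
            for rt in (1e-5, 1e-7, 1e-10)
        }
        ref = runs[1e-10].column("Cplasma")[1:]
        err = {
            rt: np.max(np.abs(r.column("Cplasma")[1:] - ref) / ref)
            for rt, r in runs.items()
            if rt != 1e-10
        }
        assert err[1e-7] < err[1e-5]
        assert err[1e-7] < 100 * 1e-7

    def test_steady_state_only_model_not_solvable(self, chem, lib):
        with pytest.raises(ValueError, match="steady-state only"):
            h.solve_model("3compartmentss", chem=chem, lib=lib)

    def test_gas_oral_dose_reproduces_pbtk(self, lib, nonvolatile_chem):
        """With no air exposure and the mucus compartment bypassed, the gas
        model must collapse to the oral PBTK kinetics."""
        times = np.linspace(0, 2, 25)
        reg = h.DoseRegimen(route="oral", initial_dose=1.0, input_units="mg/kg")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            rp = h.solve_model("pbtk", chem=nonvolatile_chem, lib=lib, times=times, regimen=reg)
            rg = h.solve_model(
                "gas_pbtk", chem=nonvolatile_chem, lib=lib, times=times, regimen=reg,
                options={"mucus_deposition_fraction": 0.0},
            )
        cp, cg = rp.column("Cplasma")[1:], rg.column("Cplasma")[1:]
        np.testing.assert_allclose(cg, cp, rtol=0.02)


class TestMassBalance:
    def test_zero_dose_defect_zero(self, lib, chem):
        res = h.solve_model("pbtk", chem=chem, lib=lib, times=np.linspace(0, 1, 9),
                            regimen=h.DoseRegimen(route="oral", initial_dose=0.0))
        rep = h.check_mass_balance(res)
        assert rep.max_relative_defect == 0.0 and rep.passed

    @pytest.mark.parametrize("model", ["pbtk", "1compartment", "gas_pbtk"])
    def test_randomized_regimens_balance(self, model, lib, chem, volatile_chem):
        """Mass-balance defect < 1e-6 across randomized dosing for all builtins."""
        rng = np.random.default_rng(5)
        rec = volatile_chem if model == "gas_pbtk" else chem
        for trial in range(3):
            route = rng.choice(["oral", "iv"])
            regimen = h.DoseRegimen(
                route=route,
                initial_dose=float(rng.uniform(0.1, 5.0)),
                daily_dose=float(rng.uniform(0.5, 2.0)),
                doses_per_day=int(rng.integers(1, 4)),
                input_units="mg/kg" if route == "iv" else "mg/kg",
            )
            if model == "gas_pbtk" and trial == 2:
                regimen = h.DoseRegimen(
                    route="inhalation",
                    forcing_series=((0.0, 5.0, "ppmv"), (0.5, 0.0, "ppmv")),
                )
            res = h.solve_model(model, chem=rec, lib=lib,
                                times=np.linspace(0, 2, 25), regimen=regimen,
                                rtol=1e-10, atol=1e-14)
            rep = h.check_mass_balance(res)
            assert rep.max_relative_defect < 1e-6, (model, trial)

    def test_fault_injection_detected(self, lib, chem, oral_regimen):
        res = h.solve_model("pbtk", chem=chem, lib=lib,
                            times=np.linspace(0, 1, 9), regimen=oral_regimen,
                            rtol=1e-10, atol=1e-14)
        administered = res.administered(1.0)
        # corrupt one compartment by +1 µmol
        res.metadata["state_records"][-1][1] += 1.0
        rep = h.check_mass_balance(res)
        assert not rep.passed
        assert rep.per_time[-1] == pytest.approx(1.0 / administered, rel=1e-6)
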