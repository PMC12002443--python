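import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pyhttk as h
from pyhttk.chem import (
    SchemaError,
    MissingDataError,
    format_uncertainty_tuple,
    write_library,
)


class TestParseUncertaintyTuple:
    def test_single_value_fup(self):
        uv = h.parse_uncertainty_tuple("0.02", "fup")
        assert uv.point == 0.02 and not uv.has_bounds

    def test_fup_3tuple_median_first(self):
        uv = h.parse_uncertainty_tuple("0.02,0.01,0.05", "fup")
        assert (uv.point, uv.l95, uv.u95) == (0.02, 0.01, 0.05)

    def test_clint_4tuple_median_first_then_bounds_then_pvalue(self):
        uv = h.parse_uncertainty_tuple("13,9.2,16.2,0.0012", "clint")
        assert uv.point == 13.0
        assert uv.l95 == 9.2
        assert uv.u95 == 16.2
        assert uv.p_no_effect == 0.0012

    def test_bounds_out_of_order_rejected(self):
        with pytest.raises(ValueError):
            h.parse_uncertainty_tuple("1,2,0.5,0.1", "clint")

    @pytest.mark.parametrize(
        "s,kind",
        [("1,2", "fup"), ("1,2,3", "clint"), ("1,2,3,4,5", "clint"), ("a,b,c", "fup")],
    )
    def test_wrong_arity_or_nonnumeric(self, s, kind):
        with pytest.raises(ValueError):
            h.parse_uncertainty_tuple(s, kind)

    @settings(deadline=None, derandomize=True)
    @given(
        point=st.floats(0.001, 0.5),
        spread=st.floats(1.01, 3.0),
        p0=st.one_of(st.none(), st.floats(0.0, 1.0)),
    )
    def test_format_parse_round_trip(self, point, spread, p0):
        uv = h.UncertainValue(point, point / spread, min(point * spread, 1.0), p0)
        kind = "clint" if p0 is not None else "fup"
        assert h.parse_uncertainty_tuple(format_uncertainty_tuple(uv), kind) == uv


class TestLibraryIO:
    def test_row_count_preserved(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "DTXSID,MW,logP,Clint.Human,fup.Human\n"
            "D1,100,2.0,10,0.1\nD2,200,1.0,5,0.2\nD3,300,0.5,1,0.3\n"
        )
        lib = h.load_library(p)
        assert len(lib) == 3

    def test_nonnumeric_mw_cites_row(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("DTXSID,MW\nD1,100\nD2,abc\n")
        with pytest.raises(SchemaError, match="row 3"):
            h.load_library(p)

    def test_missing_mandatory_column_named(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("DTXSID,logP\nD1,2\n")
        with pytest.raises(SchemaError, match="MW"):
            h.load_library(p)

    def test_clint_tuple_parsed_from_csv(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text('DTXSID,MW,Clint.Human\nD1,100,"13,9.2,16.2,0.0012"\n')
        lib = h.load_library(p)
        uv = lib["D1"].Clint["Human"]
        assert (uv.point, uv.l95, uv.u95, uv.p_no_effect) == (13, 9.2, 16.2, 0.0012)

    def test_write_load_round_trip(self, lib, tmp_path):
        p = tmp_path / "round.csv"
        write_library(lib, p)
        back = h.load_library(p)
        assert set(back.records) == set(lib.records)
        for cid, rec in lib.records.items():
            other = back[cid]
            assert other.MW == rec.MW
            assert other.logP == rec.logP
            assert other.pKa_donor == rec.pKa_donor
            assert other.logHenry == rec.logHenry
            assert other.Clint == rec.Clint
            assert other.fup == rec.fup
            assert other.Rblood2plasma_measured == rec.Rblood2plasma_measured
            assert other.chem_class == rec.chem_class


class TestAddChemtable:
    def _lib_of(self, *recs):
        lib = h.ChemicalLibrary()
        for r in recs:
            lib.add(r)
        return lib

    def test_disjoint_union(self):
        a = self._lib_of(h.ChemicalRecord(dtxsid="A", MW=100))
        b = self._lib_of(h.ChemicalRecord(dtxsid="B", MW=200))
        assert len(h.add_chemtable(a, b, "overwrite")) == 2

    def test_field_union_same_id(self):
        a = self._lib_of(h.ChemicalRecord(dtxsid="A", MW=100, logP=2.0))
        b = self._lib_of(
            h.ChemicalRecord(dtxsid="A", MW=100, fup={"Human": h.UncertainValue(0.1)})
        )
        merged = h.add_chemtable(a, b, "overwrite")["A"]
        assert merged.logP == 2.0
        assert merged.fup["Human"].point == 0.1

    def test_overwrite_precedence_notes_replacement(self):
        a = self._lib_of(h.ChemicalRecord(dtxsid="A", MW=100, logP=2.0))
        b = self._lib_of(h.ChemicalRecord(dtxsid="A", MW=100, logP=3.0))
        merged = h.add_chemtable(a, b, "overwrite")["A"]
        assert merged.logP == 3.0
        assert "logP" in merged.references

    def test_keep_existing_mw_conflict_logged(self, caplog):
        a = self._lib_of(h.ChemicalRecord(dtxsid="A", MW=100))
        b = self._lib_of(h.ChemicalRecord(dtxsid="A", MW=150))
        import logging

        with caplog.at_level(logging.WARNING):
            merged = h.add_chemtable(a, b, "keep_existing")
        assert merged["A"].MW == 100
        assert any("MW" in r.message for r in caplog.records)


class TestGetCheminfo:
    def _mini_lib(self):
        lib = h.ChemicalLibrary()
        lib.add(h.ChemicalRecord(dtxsid="A", MW=100, logP=1.0, logHenry=-8,
                                 Clint={"Human": h.UncertainValue(5)},
                                 fup={"Human": h.UncertainValue(0.1)}))
        lib.add(h.ChemicalRecord(dtxsid="B", MW=100, logP=1.0, logHenry=-8,
                                 fup={"Human": h.UncertainValue(0.1)}))  # no Clint
        lib.add(h.ChemicalRecord(dtxsid="C", MW=100, logP=1.0, logHenry=-8,
                                 Clint={"Human": h.UncertainValue(5)},
                                 fup={"Human": h.UncertainValue(0.0)}))  # failed assay
        lib.add(h.ChemicalRecord(dtxsid="P", MW=100, logP=1.0, logHenry=-8,
                                 Clint={"Human": h.UncertainValue(5)},
                                 fup={"Human": h.UncertainValue(0.1)},
                                 chem_class=frozenset({"PFAS"})))
        lib.add(h.ChemicalRecord(dtxsid="V", MW=100, logP=1.0, logHenry=-2,
                                 Clint={"Human": h.UncertainValue(5)},
                                 fup={"Human": h.UncertainValue(0.1)}))  # volatile
        return lib

    def test_missing_clint_filtered(self):
        df = h.get_cheminfo(self._mini_lib(), model="pbtk")
        assert "B" not in set(df["dtxsid"])

    def test_fup_zero_retained_and_flagged(self):
        df = h.get_cheminfo(self._mini_lib(), model="pbtk")
        row = df[df["dtxsid"] == "C"]
        assert len(row) == 1
        assert bool(row["fup_default_flagged"].iloc[0])

    def test_volatile_excluded_by_henry_threshold(self):
        df = h.get_cheminfo(self._mini_lib(), model="pbtk")
        assert "V" not in set(df["dtxsid"])
        # the gas model declares no threshold: volatile chemical eligible
        df_gas = h.get_cheminfo(self._mini_lib(), model="gas_pbtk")
        assert "V" in set(df_gas["dtxsid"])

    def test_chem_class_filter_excludes_pfas(self):
        import dataclasses

        info = h.get_model("pbtk")
        reqs = dataclasses.replace(
            info.data_requirements, chem_class_filter=frozenset({"PFAS"})
        )
        patched = dataclasses.replace(info, data_requirements=reqs)
        from pyhttk.models import registry

        old = registry._clear_registry_for_tests()
        try:
            registry.register_model(patched)
            df = h.get_cheminfo(self._mini_lib(), model="pbtk")
            assert "P" not in set(df["dtxsid"])
            assert "A" in set(df["dtxsid"])
        finally:
            registry._restore_registry_for_tests(old)

    def test_subset_and_monotone_under_added_requirement(self, lib):
        df_3c = h.get_cheminfo(lib, model="3compartmentss")
        df_pbtk = h.get_cheminfo(lib, model="pbtk")
        all_ids = set(lib.records)
        assert set(df_3c["dtxsid"]) <= all_ids
        # pbtk adds a logP requirement to the same criteria: never enlarges
        assert set(df_pbtk["dtxsid"]) <= set(df_3c["dtxsid"])

    def test_unknown_model_and_info_field(self, lib):
        with pytest.raises(KeyError):
            h.get_cheminfo(lib, model="no-such-model")
        with pytest.raises(ValueError, match="nonsense"):
            h.get_cheminfo(lib, model="pbtk", info=["nonsense"])


class TestGetParam:
    def _lib(self):
        lib = h.ChemicalLibrary()
        lib.add(
            h.ChemicalRecord(
                dtxsid="A", MW=100,
                Clint={"Human": h.UncertainValue(7.0), "Rat": h.UncertainValue(3.0)},
            )
        )
        lib.add(h.ChemicalRecord(dtxsid="B", MW=100,
                                 Clint={"Human": h.UncertainValue(7.0)}))
        lib.add(h.ChemicalRecord(dtxsid="C", MW=100))
        return lib

    def test_species_value_preferred(self):
        val, prov = h.get_param(self._lib(), "A", "Clint", species="Rat")
        assert val.point == 3.0 and prov == "rat"

    def test_human_fallback_provenance(self):
        val, prov = h.get_param(self._lib(), "B", "Clint", species="Rat",
                                default_to_human=True)
        assert val.point == 7.0 and prov == "human-default"

    def test_missing_everywhere_raises(self):
        with pytest.raises(MissingDataError):
            h.get_param(self._lib(), "C", "Clint", species="Rat")

    def test_no_fallback_when_disabled(self):
        with pytest.raises(MissingDataError):
            h.get_param(self._lib(), "B", "Clint", species="Rat",
                        default_to_human=False)


class TestSyntheticLibrary:
    def test_deterministic_per_seed(self):
        a = h.generate_synthetic_library(10, seed=1)
        b = h.generate_synthetic_library(10, seed=1)
        assert list(a.records) == list(b.records)
        for ra, rb in zip(a.records.values(), b.records.values()):
            assert ra.MW == rb.MW and ra.logP == rb.logP
            assert ra.fup == rb.fup and ra.Clint == rb.Clint

    def test_volatile_fraction_binomial(self):
        lib = h.generate_synthetic_library(1000, seed=9, volatile_fraction=0.1)
        frac = np.mean([r.logHenry > -4.5 for r in lib.records.values()])
        # binomial(1000, 0.1): 3 sigma ~ 0.0285
        assert abs(frac - 0.1) < 0.03

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            h.generate_synthetic_library(0, seed=1)
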