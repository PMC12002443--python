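import numpy as np
import pytest

import pyhttk as h


@pytest.fixture(scope="session")
def lib():
    """Session-wide synthetic chemical library."""
    return h.generate_synthetic_library(60, seed=42)


def _first(lib, pred):
    for rec in lib.records.values():
        if pred(rec):
            return rec
    raise RuntimeError("no matching chemical in fixture library")


@pytest.fixture(scope="session")
def chem(lib):
    """A well-behaved chemical: positive fup and Clint, non-volatile."""
    return _first(
        lib,
        lambda r: r.fup["Human"].point > 0.01
        and r.Clint["Human"].point > 5
        and r.logHenry < -6,
    )


@pytest.fixture(scope="session")
def volatile_chem(lib):
    """A volatile chemical for the gas model."""
    return _first(
        lib,
        lambda r: r.logHenry > -4
        and r.fup["Human"].point > 0.01
        and r.Clint["Human"].point > 0,
    )


@pytest.fixture(scope="session")
def nonvolatile_chem(lib):
    """Essentially involatile chemical (gas exchange negligible)."""
    return _first(
        lib,
        lambda r: r.logHenry < -8
        and r.fup["Human"].point > 0.01
        and r.Clint["Human"].point > 0,
    )


@pytest.fixture(scope="session")
def pbtk_params(lib, chem):
    return h.parameterize_model("pbtk", chem, lib=lib)


@pytest.fixture()
def oral_regimen():
    return h.DoseRegimen(route="oral", initial_dose=1.0, input_units="mg/kg")
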