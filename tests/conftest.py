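"""Shared fixtures: built-in systems, study protocols with auto-spanned
volume grids (computed once per session), and noiseless curves."""

import numpy as np
import pytest

from equispec import (
    Electrode,
    TitrationProtocol,
    builtin_model,
    default_volumes,
    simulate_curve,
)

STUDY_CL = 3.2e-4
STUDY_ACID = 2e-3


@pytest.fixture(scope="session")
def lig_model():
    return builtin_model("kemppr_ligand_only")


@pytest.fixture(scope="session")
def gd_model():
    return builtin_model("kemppr_gd")


@pytest.fixture(scope="session")
def h3l2_model():
    return builtin_model("h3l2_gd")


@pytest.fixture(scope="session")
def ntp_model():
    return builtin_model("ntp_prhp3_gd")


@pytest.fixture(scope="session")
def electrode():
    return Electrode(E0=400.0, slope=-59.16)


@pytest.fixture(scope="session")
def lig_protocol(lig_model):
    base = TitrationProtocol(C_L0=STUDY_CL, C_acid0=STUDY_ACID)
    vols = default_volumes(lig_model, base, pH_end=11.0, n_points=80)
    return TitrationProtocol(C_L0=STUDY_CL, C_acid0=STUDY_ACID, volumes=vols)


@pytest.fixture(scope="session")
def gd_protocol(gd_model):
    base = TitrationProtocol(C_L0=STUDY_CL, C_M0=STUDY_CL, C_acid0=STUDY_ACID)
    vols = default_volumes(gd_model, base, pH_end=6.0, n_points=80)
    return TitrationProtocol(C_L0=STUDY_CL, C_M0=STUDY_CL, C_acid0=STUDY_ACID,
                             volumes=vols)


@pytest.fixture(scope="session")
def lig_curve_exact(lig_model, lig_protocol, electrode):
    return simulate_curve(lig_model, lig_protocol, electrode,
                          sigma_E=0.0, sigma_v=0.0, seed=0)


@pytest.fixture(scope="session")
def gd_curve_exact(gd_model, gd_protocol, electrode):
    return simulate_curve(gd_model, gd_protocol, electrode,
                          sigma_E=0.0, sigma_v=0.0, seed=0)


@pytest.fixture(scope="session")
def calib_protocol():
    return TitrationProtocol(C_acid0=STUDY_ACID,
                             volumes=tuple(np.linspace(0.0, 0.8, 81)[1:]))
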