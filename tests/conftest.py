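import numpy as np
import pandas as pd
import pytest

from olzpk import synthetic_data as syn
from olzpk.pk_model import DoseArm, DoseEvent, PKParameters


@pytest.fixture(scope="session")
def control_params() -> PKParameters:
    return syn.CONTROL_MEDIANS


@pytest.fixture(scope="session")
def one_compartment_params() -> PKParameters:
    """One-compartment parent kinetics: distribution and conversion off."""
    return PKParameters(
        ka=1.0, ka_dmo=1.0, V1=1.0, V2=1.0, Q=0.0, CL=1.0,
        V1_dmo=1.0, V2_dmo=1.0, Q_dmo=0.0, CL_dmo=1.0,
        k_pm=0.0, F_po_total=0.5, F_d=1.0,
    )


@pytest.fixture(scope="session")
def iv_parent_dose() -> DoseEvent:
    return DoseEvent(DoseArm.IV_PARENT, 0.5)


@pytest.fixture(scope="session")
def noise_free_study() -> pd.DataFrame:
    """The full two-group, three-arm design with all variability off."""
    v = syn.VariabilityModel(bsv_cv=0.0, residual_cv=0.0)
    return syn.simulate_study(syn.default_design(),
                              syn.default_group_medians(), v, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture()
def complete_profiles(rng) -> pd.DataFrame:
    """Every animal sampled at every time (single complete batch)."""
    times = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
    rows = []
    for a in range(8):
        conc = rng.uniform(1.0, 20.0, len(times))
        rows += [{"animal_id": f"m{a}", "time_h": t, "conc": c}
                 for t, c in zip(times, conc)]
    return pd.DataFrame(rows)
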