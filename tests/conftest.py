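import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from ventdp import PatientParams, VentilatorScenario, simulate_measurement


@pytest.fixture(scope="session")
def patient():
    """Reference patient: EL 18, Ecw 9 cmH2O/L, TV 400 ml at 6 ml/kg."""
    return PatientParams(
        patient_id="ref",
        sex="male",
        height_cm=170.0,
        ibw_kg=400.0 / 6.0,
        el_true=18.0,
        ecw_true=9.0,
        rrs=10.0,
        roi_base=(0.19, 0.37, 0.31, 0.13),
        roi_peep_slope=(0.0, 0.0, 0.0, 0.0),
        pleural_baseline=5.0,
    )


@pytest.fixture(scope="session")
def quiet_scenario():
    """Noise-free VCV at PEEP 10 (no sensor noise, no cardiac artifact)."""
    return VentilatorScenario(
        peep_set=10.0, noise_sd_paw=0.0, noise_sd_peso=0.0, cardiac_amp=0.0, seed=0
    )


@pytest.fixture(scope="session")
def noiseless_bundle(patient, quiet_scenario):
    return simulate_measurement(patient, quiet_scenario)


@pytest.fixture(scope="session")
def analyzed_noiseless(noiseless_bundle):
    from ventdp import analyze_bundle

    summary, breaths = analyze_bundle(noiseless_bundle, with_peso=True)
    return summary, breaths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
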