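import numpy as np
import pytest

from hfopipe.pipeline import RunConfig, run_patient
from hfopipe.synthetic import SimChannelSpec, SimPatientSpec, generate_patient


@pytest.fixture(scope="session")
def small_tn_patient():
    """A compact TN patient: 6 channels, 4 x 60 s NREM intervals.

    Channel A3-A4 carries 3 HFO pairs/min and is resected; the others are
    quiet. ILAE 1, so the pipeline should classify the patient TN.
    """
    chs = tuple(
        SimChannelSpec(
            f"A{i}-A{i + 1}",
            "A",
            region="MTL" if i <= 3 else "Neocortex",
            resected=(i == 3),
            hfo_rate=3.0 if i == 3 else 0.0,
            ripple_rate=0.3,
            fr_rate=0.2,
        )
        for i in range(1, 7)
    )
    spec = SimPatientSpec(
        "tn-small", chs, n_intervals=4, interval_len_s=60.0, ilae=1, seed=5
    )
    data, truth, meta = generate_patient(spec)
    return spec, data, truth, meta


@pytest.fixture(scope="session")
def small_tn_report(small_tn_patient):
    _, data, _, _ = small_tn_patient
    return run_patient(data, RunConfig(n_perm=500, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
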