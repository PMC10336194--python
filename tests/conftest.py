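import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import carodop as cd

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_geometry() -> cd.ProbeGeometry:
    """Reduced gate count / PRF keeps synthesis fast while preserving the
    physics (Nyquist still clears the fastest baseline systolic velocity)."""
    return cd.ProbeGeometry(n_gates=8, gate_depth_min_mm=16.0,
                            gate_depth_max_mm=28.0, prf=12000.0)


@pytest.fixture(scope="session")
def vco_pipeline(small_geometry):
    """One clean-ish 20 s VCO sequence run end to end (shared across tests)."""
    cfg = cd.ScenarioConfig(kind="vco", duration=20.0)
    rng = np.random.default_rng(42)
    traces = cd.gen_vco_sequence(cfg, rng)
    record = cd.synthesize_iq(traces, small_geometry, snr_db=25.0, rng=rng)
    result = cd.process_record(record, ecg_events=traces.ecg_events)
    return traces, record, result
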