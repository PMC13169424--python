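import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_table():
    """Nine TRV reads: 3 subjects x 3 readers with known values."""
    from echoagree.core_io import MeasurementTable

    records = []
    values = {"S1": (2.0, 2.1, 1.9), "S2": (3.0, 3.3, 2.8), "S3": (4.0, 4.2, 4.1)}
    for sid, (cl1, dl, cl2) in values.items():
        for reader, v in zip(("CL1", "DL", "CL2"), (cl1, dl, cl2)):
            records.append(
                {
                    "subject_id": sid,
                    "parameter": "TRV",
                    "reader": reader,
                    "value": v,
                    "quality_score": 4,
                    "group": "PAH",
                    "age_years": 50.0,
                    "sex": "F",
                }
            )
    return MeasurementTable.from_records(records)
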