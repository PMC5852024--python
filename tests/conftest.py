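import numpy as np
import pytest

import comorbnet as cn
from comorbnet.records import DiagnosisRecord


@pytest.fixture
def toy_records():
    """Two patients, three diseases; p1 has A (twice) and B, p2 has C."""
    return [
        DiagnosisRecord("p1", 2000, "401.1", "outpatient"),
        DiagnosisRecord("p1", 2000, "401.1", "inpatient"),
        DiagnosisRecord("p1", 2000, "250.2", "outpatient"),
        DiagnosisRecord("p2", 2000, "272.1", "outpatient"),
    ]


@pytest.fixture
def records_csv(tmp_path):
    """A small well-formed registry file on disk."""
    path = tmp_path / "records.csv"
    path.write_text(
        "patient_id,year,code,setting\n"
        "p1,2000,401.1,outpatient\n"
        "p2,2000,V70.0,inpatient\n"
        "p3,2001,250.2,outpatient\n"
    )
    return path


@pytest.fixture(scope="session")
def planted_registry():
    """Reference planted-module registry (seed 0), shared across tests."""
    return cn.generate(cn.reference_planted_spec(0))


@pytest.fixture(scope="session")
def planted_occurrence(planted_registry):
    return cn.build_yearly_occurrence(planted_registry.records, 2000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
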