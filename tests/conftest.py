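import pytest

from isatis import default_isatis_spec
from isatis.scoring import PatientRecord


@pytest.fixture(scope="session")
def spec():
    return default_isatis_spec()


@pytest.fixture
def make_record():
    """Factory for patient records; ``codes`` maps item ID -> raw code,
    or a single int to apply to every one of the 32 items."""

    def _make(codes=None, arm="internet", patient_id="p1", los=5, delay=7.0,
              **kwargs):
        spec = default_isatis_spec()
        if isinstance(codes, int):
            codes = {item: codes for item in spec.all_items}
        responses = dict(codes or {})
        return PatientRecord(
            patient_id=patient_id,
            arm=arm,
            los_days=los,
            delay_days=delay if responses else None,
            responses=responses,
            **kwargs,
        )

    return _make
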