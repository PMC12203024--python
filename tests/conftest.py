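from datetime import date
from fractions import Fraction

import pytest

from doseatc import DrugRecord, default_formulary, mock_completion_backend


@pytest.fixture(scope="session")
def formulary():
    return default_formulary()


@pytest.fixture(scope="session")
def mock_backend(formulary):
    return mock_completion_backend(formulary)


@pytest.fixture
def quetiapine_records():
    """Two same-day dispenses of pms-quetiapine: 1x200 mg + 2x25 mg each."""
    day = date(2024, 3, 1)
    records = []
    for _dispense in range(2):
        records.append(
            DrugRecord("patient-7", day, "pms-quetiapine", "200 mg", Fraction(1))
        )
        records.append(
            DrugRecord("patient-7", day, "pms-quetiapine", "25 mg", Fraction(2))
        )
    return records
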