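from pathlib import Path

import pytest

from eicare.worked_example import worked_example_patient

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def fig1_dir() -> Path:
    """Directory with the shipped one-patient worked-example cohort CSVs."""
    return DATA_DIR / "fig1"


@pytest.fixture
def fig1_patient():
    return worked_example_patient()


@pytest.fixture
def cohort_paths(fig1_dir):
    return {
        "visits": fig1_dir / "visits.csv",
        "labs": fig1_dir / "labs.csv",
        "therapy": fig1_dir / "therapy.csv",
        "demographics": fig1_dir / "demographics.csv",
    }
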