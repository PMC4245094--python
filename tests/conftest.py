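import numpy as np
import pytest

from hepafat.phantom import SyntheticSubject
from hepafat.spectral_model import (
    TissueState,
    default_fat_spectrum,
    multi_echo_protocol,
    triple_echo_protocol,
)


@pytest.fixture(scope="session")
def spectrum():
    return default_fat_spectrum()


@pytest.fixture(scope="session")
def triple():
    return triple_echo_protocol()


@pytest.fixture(scope="session")
def multi():
    return multi_echo_protocol()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_subject(pdff_pct, t2star_ms=20.0, water_t2_ms=25.0, fat_t2_ms=60.0,
                 linewidth_hz=45.0, subject_id="subj_test"):
    """Synthetic subject with a given true PDFF (percent); histology fields
    are filled in consistently with the grading bands."""
    if pdff_pct < 5:
        histo, grade = 0.0, "none"
    elif pdff_pct < 33:
        histo, grade = 20.0, "mild"
    elif pdff_pct <= 66:
        histo, grade = 50.0, "moderate"
    else:
        histo, grade = 80.0, "severe"
    spectrum = default_fat_spectrum()
    tissue = TissueState(
        water_density=100.0 - pdff_pct,
        fat_density=pdff_pct,
        t2star_ms=t2star_ms,
        water_t2_ms=water_t2_ms,
        per_peak_t2_ms={ppm: fat_t2_ms for ppm, _ in spectrum.peaks},
    )
    return SyntheticSubject(
        subject_id=subject_id,
        true_pdff_percent=pdff_pct,
        histology_steatosis_percent=histo,
        grade=grade,
        steatohepatitis=False,
        fibrosis_stage="F0",
        tissue=tissue,
        linewidth_hz=linewidth_hz,
    )
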