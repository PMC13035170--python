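import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oglyco import (
    HEXNAC,
    DiagnosticOutcome,
    Peptide,
    SimulationConfig,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def glycopeptide():
    """The worked example: PNSRHDNVSPSK with HexNAc at S9 and S11."""
    return Peptide("PNSRHDNVSPSK", ((9, HEXNAC), (11, HEXNAC)))


@pytest.fixture
def passing_diagnostics():
    return DiagnosticOutcome(
        oxonium_primary_found=True,
        oxonium_secondary_found=True,
        neutral_loss_precursor=True,
        neutral_loss_fragment_count=2,
        site_flanking_b=True,
        site_flanking_y=True,
        precursor_ppm=3.0,
        matched_fraction=0.9,
    )


@pytest.fixture
def clean_config():
    """Zero-noise, full-ladder simulation world."""
    return SimulationConfig(
        seed=11, n_peptides=60, mz_jitter_ppm=0.0, noise_peaks_per_spectrum=0.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
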