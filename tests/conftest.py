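import numpy as np
import pytest

from glycopotency import ms_mapping as mm
from glycopotency import synthetic_data as sd


@pytest.fixture(scope="session")
def site_peptides():
    """One chymotryptic sequon peptide per glycosite."""
    return {site: peps[0] for site, peps in mm.default_site_peptides().items()}


@pytest.fixture
def noiseless_ms_config():
    return sd.MSSimulationConfig(
        noise_sigma=0.0, mz_jitter_ppm=0.0, decoy_rate=0.0, seed=11
    )


@pytest.fixture
def simple_peaklist():
    """Two scans, a handful of peaks, scan range wide open."""
    scans = [
        mm.Scan(1.0, np.array([500.000, 500.001, 800.0]), np.array([100.0, 50.0, 10.0])),
        mm.Scan(2.0, np.array([500.000, 900.0]), np.array([25.0, 5.0])),
    ]
    return mm.PeakList(scans=scans, scan_range=(100.0, 2000.0))
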