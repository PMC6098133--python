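import numpy as np
import pytest

from ftirsurv import analyze_cohort, generate_cohort, paper_like_config
from ftirsurv.io import Spectrum


@pytest.fixture(scope="session")
def preset_cohort():
    """The 27-patient preset cohort (seed 1): records, spectra, truth."""
    return generate_cohort(paper_like_config(seed=1))


@pytest.fixture(scope="session")
def preset_report(preset_cohort):
    records, spectra, _ = preset_cohort
    return analyze_cohort(records, spectra)


@pytest.fixture()
def gaussian_spectrum():
    """Noise-free single Gaussian band at 1030 cm^-1 on the standard grid."""
    nu = 800.0 + 2.0 * np.arange(1351)
    y = np.exp(-((nu - 1030.0) ** 2) / (2 * 8.0**2))
    return Spectrum(wavenumbers=nu, absorbance=y, patient_id="G", tissue_type="t_b")
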