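import pytest

from lipidbridge import LipidSpecies, generate_spectrum
from lipidbridge.synthdata import DGDG_ISOMERS, SimConfig, dgdg_showcase

SHOWCASE_CONFIG = SimConfig(rt_range=(9.5, 10.5), noise_level=0.05, seed=0)


@pytest.fixture(scope="session")
def dgdg_library():
    """In-silico spectra of the three co-eluting DGDG 34:3 isomers."""
    return [generate_spectrum(LipidSpecies.parse(n)) for n in DGDG_ISOMERS]


@pytest.fixture(scope="session")
def showcase():
    """One seeded realization of the nine-sample DGDG co-elution scenario."""
    return dgdg_showcase(SHOWCASE_CONFIG)
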