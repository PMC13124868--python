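import numpy as np
import pytest

from ramanscreen.dataset import WavenumberAxis
from ramanscreen.simulate import (
    ComponentSpectrum,
    KineticParams,
    NoiseModel,
    RunConfig,
    StudyConfig,
    generate_study,
)


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    """A shrunken study: 3 runs / 13 samples on a 501-channel axis, with
    component peaks inside that range.  Fast enough for per-test screens."""
    axis = WavenumberAxis(np.arange(600.0, 1101.0, 1.0))
    comps = (
        ComponentSpectrum("Gluc", ((1060, 10, 1.0), (911, 9, 0.6)), 4.5),
        ComponentSpectrum("Lac", ((830, 10, 1.0), (1045, 9, 0.7)), 1300.0),
        ComponentSpectrum("Gln", ((1090, 11, 1.0), (700, 12, 0.5)), 28.0),
        ComponentSpectrum("Glu", ((860, 10, 1.0), (980, 10, 0.6)), 100.0),
        ComponentSpectrum("NH4", ((765, 14, 1.0),), 1500.0),
        ComponentSpectrum("Xv", ((1004, 8, 1.0), (745, 10, 0.5)), 0.55),
        ComponentSpectrum("debris", ((940, 15, 1.0),), 0.9),
    )
    runs = (
        RunConfig("runA", 4, "uninfected", xv0=5.0),
        RunConfig("runB", 4, "single-infection", xv0=7.4, toi_h=24.0),
        RunConfig("runC", 5, "coinfection", xv0=5.0, toi_h=24.0),
    )
    return StudyConfig(axis=axis, runs=runs, components=comps)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config, master_seed=7)


@pytest.fixture(scope="session")
def default_study():
    """The full-size study at its default design (5 runs, 65 samples,
    100-3425 cm^-1 axis)."""
    return generate_study(master_seed=11)
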