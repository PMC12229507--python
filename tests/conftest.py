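import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fgrs.spectra import SpectraSet, Spectrum, default_band_panel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def axis571() -> np.ndarray:
    """The default fingerprint axis: 571 uniform channels, 400-1800 cm^-1."""
    return np.linspace(400.0, 1800.0, 571)


@pytest.fixture(scope="session")
def panel():
    return default_band_panel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def two_class_set(axis571, rng) -> SpectraSet:
    """Small labelled set: 6 noisy spectra per class on the default axis."""
    spectra = []
    base = (
        0.2
        + np.exp(-0.5 * ((axis571 - 1450.0) / 8.0) ** 2)
        + 0.8 * np.exp(-0.5 * ((axis571 - 1657.0) / 8.0) ** 2)
    )
    for label, shift in (("high", 0.1), ("low", 0.0)):
        bump = shift * np.exp(-0.5 * ((axis571 - 1003.0) / 8.0) ** 2)
        for i in range(6):
            y = base + bump + rng.normal(0, 0.01, axis571.size)
            spectra.append(
                Spectrum(axis571, y, sample_id=f"{label}{i}", label=label)
            )
    return SpectraSet.from_spectra(spectra, label_set=("high", "low"))


def make_spectrum(y, axis=None, **kw) -> Spectrum:
    y = np.asarray(y, dtype=float)
    if axis is None:
        axis = np.arange(y.size, dtype=float)
    return Spectrum(axis, y, **kw)
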