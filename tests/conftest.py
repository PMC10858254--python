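import numpy as np
import pandas as pd
import pytest

from larvaconnect import CoastlineSpec, Domain, Fjord, build_domain
from larvaconnect.flow import AnalyticField
from larvaconnect.genotypes import GenotypeMatrix


@pytest.fixture
def open_water():
    """1 deg x 1 deg all-water domain around 56.5 N."""
    return build_domain((-6.0, -5.0, 56.0, 57.0), 0.05, None)


@pytest.fixture
def equator_box():
    """Small all-water box straddling the equator (negligible metric distortion)."""
    return build_domain((-1.0, 1.0, -1.0, 1.0), 0.05, None)


def still_field(domain):
    return AnalyticField(domain, lambda t, lon, lat: (np.zeros_like(lon), np.zeros_like(lon)))


def northward_field(domain, speed):
    return AnalyticField(
        domain, lambda t, lon, lat: (np.zeros_like(lon), np.full_like(lon, speed))
    )


@pytest.fixture
def make_genotypes():
    """Build a GenotypeMatrix from a plain dosage array and population sizes."""

    def _make(dosages, pop_sizes, stages=None):
        dosages = np.asarray(dosages, dtype=np.int8)
        labels = []
        for k, n in enumerate(pop_sizes):
            labels += [f"p{k}"] * n
        samples = pd.DataFrame(
            {"site": labels, "stage": stages or "adult"},
            index=[f"i{i:03d}" for i in range(dosages.shape[0])],
        )
        return GenotypeMatrix(dosages, samples)

    return _make
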