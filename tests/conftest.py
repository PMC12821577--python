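"""Shared fixtures: small synthetic cohorts and binned matrices.

Everything is generated programmatically with fixed seeds; the expensive
full-size recovery and calibration studies live in test_acceptance.py.
"""

import numpy as np
import pytest

from urinmr import preprocess, synth
from urinmr.datatypes import BinnedMatrix, Spectrum


@pytest.fixture(scope="session")
def small_design():
    """A small but otherwise default-shaped cohort design."""
    return synth.CohortDesign(
        n_workers=8, n_residents=10, axis=(0.2, 9.8, 2048), seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return synth.simulate_cohort(small_design)


@pytest.fixture(scope="session")
def binned_default():
    """Fast-path binned matrix of a default-size cohort (with noise)."""
    design = synth.CohortDesign(seed=5)
    return synth.cohort_to_binned(design, 0.04, noise_sd=0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_spectra():
    """Six spectra: two clean Lorentzian singlets on weak noise."""
    r = np.random.default_rng(7)
    ppm = np.linspace(10, 0, 1024)

    def lor(c, g, a):
        return a / np.pi * g / ((ppm - c) ** 2 + g**2)

    return [
        Spectrum(ppm, lor(3, 0.02, 5) + lor(7, 0.02, 5) + r.normal(0, 0.01, ppm.size), f"s{i}")
        for i in range(6)
    ]


@pytest.fixture()
def simple_matrix():
    """A 4-sample, 5-bin matrix with hand-set values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [2.0, 4.0, 6.0, 8.0, 10.0],
            [0.5, 1.0, 1.5, 2.0, 2.5],
            [1.5, 3.0, 4.5, 6.0, 7.5],
        ]
    )
    edges = np.array([[5.0, 4.0], [4.0, 3.0], [3.0, 2.0], [2.0, 1.0], [1.0, 0.0]])
    return BinnedMatrix(values, edges, ["a", "b", "c", "d"])
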