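"""Shared fixtures: small grids, templates and seeded synthetic datasets."""

import numpy as np
import pytest

import tristepir as t


@pytest.fixture(scope="session")
def templates():
    return t.default_templates()


@pytest.fixture(scope="session")
def fingerprint_grid():
    """A 1 cm^-1 grid covering the fingerprint region (keeps tests fast)."""
    return np.arange(900.0, 1900.0, 1.0)


@pytest.fixture()
def flower_spectrum(templates):
    return t.generate_spectrum(templates["flower"], seed=11)


@pytest.fixture(scope="session")
def small_dataset(templates, fingerprint_grid):
    """Three classes x 20 samples on the fingerprint grid (raw absorbance)."""
    return t.generate_dataset(
        templates, {"flower": 20, "leaf": 20, "seed": 20}, seed=101,
        grid=fingerprint_grid)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    return t.DataMatrix.from_collection(small_dataset)
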