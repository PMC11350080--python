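import warnings

import numpy as np
import pytest

from stemftir.emsc import build_model
from stemftir.io_spectra import SampleMeta, SpectrumTable, WavenumberAxis
from stemftir.synth import SynthConfig, make_cube, make_library


@pytest.fixture(scope="session")
def config():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def library(config):
    return make_library(config)


@pytest.fixture(scope="session")
def default_cube(config, library):
    """Default 96x96 seven-region stem cube with ground truth (seed 1)."""
    return make_cube(config, library)


@pytest.fixture(scope="session")
def oracle_model(library):
    """EMSC model with a full-rank design: the reference set is noisy, so
    m_bar is not collinear with the baseline+component span."""
    rng = np.random.default_rng(10)
    weights = rng.uniform(0.5, 1.5, (12, library.n_components))
    ref = weights @ library.spectra + rng.normal(0.0, 0.01, (12, len(library.axis)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_model(np.abs(ref), library, poly_order=2)


@pytest.fixture()
def small_table():
    axis = WavenumberAxis(np.array([1200.0, 1100.0, 1000.0, 900.0]))
    absorbance = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
    meta = [SampleMeta("s1", "G01", "easy"), SampleMeta("s2", "G02", "difficult")]
    return SpectrumTable(axis, absorbance, meta)
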