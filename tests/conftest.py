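"""Shared fixtures: the expensive default build runs once per session."""

import numpy as np
import pytest

from wulffgraft import fixtures
from wulffgraft.crystal import MillerFacet, carve, replicate, wulff_shape
from wulffgraft.pipeline import BuildConfig, run_pipeline


@pytest.fixture(scope="session")
def cell():
    return fixtures.magnetite_cell()


@pytest.fixture(scope="session")
def default_shape(cell):
    return wulff_shape(
        [MillerFacet((1, 0, 0), 1.0), MillerFacet((1, 1, 1), 1.15)],
        cell, 30.0)


@pytest.fixture(scope="session")
def default_core(cell, default_shape):
    bulk = replicate(cell, 4, 4, 4)
    return carve(bulk, default_shape, np.asarray(bulk.box) / 2.0)


@pytest.fixture(scope="session")
def default_build():
    """Full default build through chain grafting, with artifacts kept."""
    cfg = BuildConfig(out_dir="scratch/test_build")
    return run_pipeline(cfg, until="chains", write_files=False,
                        keep_artifacts=True)


@pytest.fixture(scope="session")
def default_chain(default_build):
    return default_build["artifacts"]["chain"]


@pytest.fixture(scope="session")
def mag_ara(default_build):
    return default_build["artifacts"]["mag_ara"]
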