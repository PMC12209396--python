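import numpy as np
import pytest

from glandfrac import (
    ProjectionGeometry,
    build_phantom,
    load_tables,
    simulate_projection,
    trace_paths,
)
from glandfrac.evaluate import study_spectrum


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def geom():
    return ProjectionGeometry()


@pytest.fixture(scope="session")
def wal():
    """The broad W/Al 28 kV study beam (14-28 keV, 2 keV bins)."""
    return study_spectrum("W/Al")


@pytest.fixture(scope="session")
def wag():
    """The narrower W/Ag 34 kV clinical-style beam."""
    return study_spectrum("W/Ag")


@pytest.fixture(scope="session")
def cell_4cm_20(geom, wal):
    """A 4 cm, 20% GF phantom with its traced paths and a noiseless image."""
    ph = build_phantom(4.0, 0.2)
    paths = trace_paths(ph, geom)
    img = simulate_projection(ph, geom, wal, 30000.0, poisson=False, paths=paths)
    return ph, paths, img
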