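import numpy as np
import pytest

from anchordepth import coords as C
from anchordepth import synth


def make_model(points, names=None, resids=None, chain="A", elements=None):
    """Small helper: a StructureModel from a coordinate array."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    names = names or ["CA"] * n
    resids = resids or list(range(1, n + 1))
    elements = elements or [nm[0] for nm in names]
    atoms = [
        C.Atom(i + 1, names[i], "ALA", chain, resids[i], elements[i], points[i])
        for i in range(n)
    ]
    return C.StructureModel(atoms)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cloud_model(rng):
    return make_model(rng.normal(scale=3.0, size=(6, 3)))


@pytest.fixture
def toy_cdomain():
    return synth.make_toy_cdomain()


@pytest.fixture
def small_membrane():
    spec = synth.MembraneSpec(lipids_per_leaflet=20, jitter=0.0, seed=7)
    return synth.make_membrane_frame(spec)


@pytest.fixture
def jittered_membrane():
    spec = synth.MembraneSpec(lipids_per_leaflet=100, jitter=0.8, seed=11)
    return synth.make_membrane_frame(spec)
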