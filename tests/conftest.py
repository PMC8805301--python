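import numpy as np
import pytest

import icering as ir
from icering.reflection_io import ValueKind


@pytest.fixture(scope="session")
def cubic_cell():
    return ir.UnitCell(10.0, 10.0, 10.0)


@pytest.fixture(scope="session")
def window_table():
    return ir.default_ranges()


@pytest.fixture(scope="session")
def clean_set():
    """Unmodified simulated intensity set covering all eight windows."""
    p = ir.SimulationParams(n_target=15000, seed=101)
    rset, labels = ir.simulate_reflections(p)
    assert all(v == "clean" for v in labels.values())
    return rset


@pytest.fixture(scope="session")
def contaminated_set():
    """Simulated set with one strong full-fraction spike in window E."""
    p = ir.SimulationParams(
        contaminated_ranges=(ir.Contamination("E", 6.0, 1.0),),
        n_target=15000,
        seed=202,
    )
    return ir.simulate_reflections(p)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small, strongly-contaminated corpus for fast training tests."""
    grids, labels, manifest = ir.make_corpus(
        30,
        fraction_contaminated=0.3,
        difficulty_mix={"strong": 1.0},
        seed=7,
        kind=ValueKind.AMPLITUDE,
    )
    assert labels.sum() >= 10 and (labels == 0).sum() >= 10
    return grids, labels, manifest


@pytest.fixture(scope="session")
def tiny_model(tiny_corpus):
    """A briefly trained classifier (enough to be non-degenerate)."""
    grids, labels, _ = tiny_corpus
    tc = ir.TrainingConfig(seed=5, epochs=3)
    model, history = ir.train(grids, labels, tc=tc, kind=ValueKind.AMPLITUDE)
    return model, history


def random_reflection_set(rng, n=200, kind=ValueKind.INTENSITY):
    """Small random set for property tests (cell large enough for windows)."""
    cell = ir.UnitCell(*rng.uniform(55, 85, size=3))
    hkl = rng.integers(-20, 21, size=(3 * n, 3))
    hkl = hkl[np.any(hkl != 0, axis=1)][:n]
    value = rng.exponential(100.0, size=hkl.shape[0])
    return ir.ReflectionSet(cell, kind, hkl, value, None)
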