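"""Shared fixtures: synthetic models/maps and derived objects.

Everything heavy (curve ensembles, classifier centroids, maps, traces) is
session-scoped so the suite builds each once.
"""

from __future__ import annotations

import numpy as np
import pytest

from rnatrace.conformers import SuiteClassifier, default_classifier
from rnatrace.density import find_peaks
from rnatrace.fixtures import SyntheticSpec, build_ideal_model, simulate_map
from rnatrace.likelihoods import default_curves
from rnatrace.tracing import auto_trace


@pytest.fixture(scope="session")
def curves():
    return default_curves()


@pytest.fixture(scope="session")
def classifier() -> SuiteClassifier:
    clf = default_classifier()
    clf.centroids()
    return clf


@pytest.fixture(scope="session")
def helix7():
    """Clean all-A-form 7-mer: (spec, model, map, peaks)."""
    spec = SyntheticSpec(sequence="GACGUAC")
    model = build_ideal_model(spec)
    grid = simulate_map(model, spec)
    return spec, model, grid, find_peaks(grid)


@pytest.fixture(scope="session")
def mixed7():
    """Clean mixed-conformer 7-mer: (spec, model, map, peaks)."""
    spec = SyntheticSpec(
        sequence="GGACUAG", conformers=("1a", "1e", "1a", "1z", "4a", "1a")
    )
    model = build_ideal_model(spec)
    grid = simulate_map(model, spec)
    return spec, model, grid, find_peaks(grid)


@pytest.fixture(scope="session")
def helix12():
    """Clean all-A-form 12-mer used by the recovery metrics."""
    spec = SyntheticSpec(sequence="ACGUACGUACGU")
    model = build_ideal_model(spec)
    grid = simulate_map(model, spec)
    return spec, model, grid, find_peaks(grid)


@pytest.fixture(scope="session")
def traced7(helix7, curves):
    """Auto-trace of the clean 7-mer (top candidate at every step)."""
    spec, model, grid, peaks = helix7
    trace, report = auto_trace(
        grid, peaks, start=model.atom(0, "P"), length=7, curves=curves,
        sequence=spec.sequence,
    )
    return trace, report


def true_phosphates(model) -> np.ndarray:
    return np.array([model.atom(i, "P") for i in range(len(model))])
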