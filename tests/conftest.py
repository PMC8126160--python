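"""Shared fixtures: toy annotations and synthetic libraries.

Everything is generated programmatically at test time from fixed seeds, so
the suite needs no data files.
"""

import pytest

from nascentqc import (
    EndIndex,
    LibraryParams,
    make_toy_annotation,
    simulate_library,
)


@pytest.fixture(scope="session")
def annotation50():
    """The standard 50-gene toy annotation used by the metric-level tests."""
    return make_toy_annotation(50, seed=1)


@pytest.fixture(scope="session")
def annotation5():
    """A small 5-gene annotation for cheap unit tests."""
    return make_toy_annotation(5, seed=7)


@pytest.fixture(scope="session")
def paused_library(annotation50):
    """An efficient run-on library: 70% paused 3' ends, 20k reads."""
    params = LibraryParams(n_reads=20_000, pause_strength=0.7, seed=1)
    return simulate_library(params, annotation50)


@pytest.fixture(scope="session")
def unpaused_library(annotation50):
    """A library with no pausing and no contamination: uniform gene-span
    signal, 20k reads."""
    params = LibraryParams(n_reads=20_000, pause_strength=0.0, seed=1)
    return simulate_library(params, annotation50)


@pytest.fixture(scope="session")
def paused_index(paused_library):
    return EndIndex(paused_library.truth_alignments)


@pytest.fixture(scope="session")
def unpaused_index(unpaused_library):
    return EndIndex(unpaused_library.truth_alignments)
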