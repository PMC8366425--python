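"""Shared fixtures: synthetic patterns and (expensive) indexing runs.

The worked-example patterns and their full indexing runs are session-scoped
so the unit, property and acceptance tests share one computation.
"""

import numpy as np
import pytest

from gixdindex import (
    NospecConfig,
    PeakList,
    index_with_specular,
    index_without_specular,
    simulate_pattern,
)
from gixdindex.simulate import fixture_suite


@pytest.fixture(scope="session")
def suite():
    return fixture_suite()


@pytest.fixture(scope="session")
def pq_pattern(suite):
    return simulate_pattern(suite["pq_clean"])


@pytest.fixture(scope="session")
def pq_noisy_pattern(suite):
    return simulate_pattern(suite["pq_noisy"])


@pytest.fixture(scope="session")
def ass_pattern(suite):
    return simulate_pattern(suite["ass_clean"])


@pytest.fixture(scope="session")
def mono_pattern(suite):
    return simulate_pattern(suite["mono_toy"])


TIMINGS: dict[str, float] = {}


@pytest.fixture(scope="session")
def timings():
    return TIMINGS


@pytest.fixture(scope="session")
def pq_solutions(pq_pattern):
    import time

    peaks, _ = pq_pattern
    t0 = time.perf_counter()
    solutions = index_with_specular(peaks)
    TIMINGS["pq_clean"] = time.perf_counter() - t0
    return solutions


@pytest.fixture(scope="session")
def pq_noisy_solutions(pq_noisy_pattern):
    peaks, _ = pq_noisy_pattern
    return index_with_specular(peaks)


@pytest.fixture(scope="session")
def ass_solutions(ass_pattern):
    peaks, _ = ass_pattern
    return index_with_specular(peaks)


@pytest.fixture(scope="session")
def mono_spec_solutions(mono_pattern):
    peaks, _ = mono_pattern
    return index_with_specular(peaks)


@pytest.fixture(scope="session")
def mono_nospec_solutions(mono_pattern):
    peaks, _ = mono_pattern
    gixd_only = PeakList(peaks.gixd, None)
    return index_without_specular(gixd_only, NospecConfig(cell_type="monoclinic"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20210730)
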