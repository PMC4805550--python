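import numpy as np
import pytest

import gcmap
from gcmap.mapping import ConnectivityMapper


@pytest.fixture(scope="session")
def archetype_population():
    """Default four-archetype population at the study scale (49 cells)."""
    return gcmap.make_population(49, seed=1)


@pytest.fixture(scope="session")
def archetype_analysis(archetype_population):
    """Patterns, positions and archetype ids for the session population."""
    patterns, positions, archetypes = [], [], {}
    for cell in archetype_population:
        m = ConnectivityMapper().fit(cell)
        patterns.append(m.pattern_)
        positions.append(cell.soma_position_um)
        archetypes[cell.cell_id] = cell.archetype_id
    return patterns, np.asarray(positions), archetypes


def make_trace(samples, dt_ms=0.1, stim_onset_ms=200.0):
    return gcmap.PhotostimTrace(
        samples=np.asarray(samples, dtype=float),
        dt_ms=dt_ms,
        stim_onset_ms=stim_onset_ms,
    )


@pytest.fixture
def flat_trace():
    return make_trace(np.zeros(10_000))
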