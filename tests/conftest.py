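"""Shared fixtures: reference structures, catalog candidates, clean patterns.

Everything is generated programmatically; simulated candidate patterns are
cached per session because pattern simulation is deterministic.
"""

from __future__ import annotations

import pytest

import micphase as mp
from micphase.fixtures import FIXTURE_IDS, make_reference_structures


@pytest.fixture(scope="session")
def reference_structures():
    return make_reference_structures()


@pytest.fixture(scope="session")
def candidates(reference_structures):
    """The four catalog entries that have fixture structures attached."""
    by_id = {c.materials_id: c for c in mp.load_candidate_catalog()}
    out = []
    for mid in FIXTURE_IDS:
        cand = by_id[mid]
        cand.structure = reference_structures[mid]
        out.append(cand)
    return out


@pytest.fixture(scope="session")
def clean_patterns(reference_structures):
    """Noise-free simulated pattern per fixture phase (default scan settings)."""
    return {mid: mp.simulate_pattern(s) for mid, s in reference_structures.items()}


@pytest.fixture(scope="session")
def pattern_cache(clean_patterns):
    """Simulated-candidate cache shared by ranking calls across tests."""
    return dict(clean_patterns)
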