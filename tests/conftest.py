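"""Shared fixtures: toy alignments and small simulated families."""

import pytest

from regen_evo import CladeMap, ProteinAlignment, SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def toy_clade_map() -> CladeMap:
    entries = {}
    for i in (1, 2):
        entries[f"m{i}"] = "metazoa"
        entries[f"f{i}"] = "fungi"
        entries[f"p{i}"] = "plant"
    return CladeMap(entries=entries)


@pytest.fixture(scope="session")
def toy_alignment() -> ProteinAlignment:
    """Metazoa and fungi identical (A), plants maximally different (W)."""
    rows = {}
    for i in (1, 2):
        rows[f"m{i}"] = "AAAA"
        rows[f"f{i}"] = "AAAA"
        rows[f"p{i}"] = "WWWW"
    return ProteinAlignment(rows)


@pytest.fixture(scope="session")
def small_tol_family():
    return simulate_family(
        SimulationConfig(n_per_clade=4, n_codons=150, seed=3), gene="tol_small"
    )


@pytest.fixture(scope="session")
def small_non_tol_family():
    return simulate_family(
        SimulationConfig(n_per_clade=4, n_codons=150, seed=3, metazoan_multiplier=3.0),
        gene="non_tol_small",
    )
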