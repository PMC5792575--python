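import pytest

from plastoscreen import (
    MultipleAlignment,
    SimulationConfig,
    generate_reference,
    simulate_population,
    worked_example_fixture,
)


@pytest.fixture(scope="session")
def fixture_pop():
    """Compact worked-example population with exact planted per-region counts."""
    return worked_example_fixture(seed=0)


@pytest.fixture(scope="session")
def fixture_regions(fixture_pop):
    return {r.label: r for r in fixture_pop.regions}


@pytest.fixture(scope="session")
def sim_pop():
    """Default full-scale simulated population (21 individuals, 19 taxa)."""
    config = SimulationConfig(seed=1)
    return simulate_population(generate_reference(config), config)


@pytest.fixture
def make_aln():
    """Factory for small hand-written alignments.

    ``make_aln(["ACGT", "AC-T"], taxa=["t1", "t2"])`` -> MultipleAlignment
    with ids s1, s2, ... and optional taxon labels.
    """

    def _make(rows, taxa=None, reference_id=None):
        ids = [f"s{i + 1}" for i in range(len(rows))]
        taxon_of = dict(zip(ids, taxa)) if taxa is not None else None
        return MultipleAlignment(ids, rows, taxon_of=taxon_of,
                                 reference_id=reference_id)

    return _make
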