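import pytest

from haplopop.diversity import population_stats
from haplopop.pipeline import call_and_combine, combined_sequences
from haplopop.synthetic_data import PopulationSpec, SimConfig, generate_world, preset_paper_world


@pytest.fixture(scope="session")
def preset_world():
    return preset_paper_world(seed=20210215)


def analyze_world(world):
    """Run the in-memory calling stage on a synthetic world."""
    individuals, coi_cat, coii_cat = call_and_combine(
        world.coi_reference,
        world.coii_reference,
        world.coi_samples,
        world.coii_samples,
        world.popmap,
    )
    return individuals, combined_sequences(individuals, coi_cat, coii_cat)


def world_region_stats(world):
    """Per-region diversity stats for a synthetic world, keyed by region."""
    individuals, seqs = analyze_world(world)
    members = {}
    for ind in individuals:
        if ind.combined_name is not None:
            members.setdefault(ind.region, []).append(ind.combined_name)
    return {s.population: s for s in population_stats(members, seqs, 1175)}


def single_pop_world(seed, name, country, spectrum, tree):
    """One-population world from an explicit haplotype tree and spectrum."""
    config = SimConfig(
        seed=seed,
        tree=tuple(tree),
        populations=(PopulationSpec(name, country, "invadedB", spectrum),),
        known=frozenset(child for _, child, _ in tree),
    )
    return generate_world(config)
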