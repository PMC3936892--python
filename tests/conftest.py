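import pytest

from stemloop.pipeline import DiscoveryConfig, run_discovery
from stemloop.simulate import SimConfig, build_genome_and_libraries


@pytest.fixture(scope="session")
def study():
    """Default synthetic study plus the full discovery run on it.

    Built once per session: 10 novel + 2 known + 2 conserved hairpins,
    one decoy per violable criterion, two libraries of ~2x10^5 reads.
    """
    bundle = build_genome_and_libraries(SimConfig(seed=1))
    config = DiscoveryConfig(adapter=bundle.config.adapter,
                             species=bundle.config.species)
    result = run_discovery(
        bundle.genome, bundle.libraries, bundle.known_species,
        bundle.plant_mirs, bundle.rfam, bundle.repbase, config,
    )
    return bundle, result


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast end-to-end checks."""
    cfg = SimConfig(
        seed=7,
        n_true_hairpins=2,
        n_known=1,
        n_conserved=1,
        decoy_kinds=("no_star", "bulge_size"),
        genome_length=5_000,
        library_depth=20_000,
        abundance_range=(600.0, 1_500.0),
        decoy_abundance_range=(200.0, 400.0),
        n_targets=2,
        n_decoy_transcripts=1,
        degradome_depth=400,
    )
    bundle = build_genome_and_libraries(cfg)
    config = DiscoveryConfig(adapter=cfg.adapter, species=cfg.species)
    result = run_discovery(
        bundle.genome, bundle.libraries, bundle.known_species,
        bundle.plant_mirs, bundle.rfam, bundle.repbase, config,
    )
    return bundle, result
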