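"""Shared fixtures: one small synthetic experiment reused across modules."""

from types import SimpleNamespace

import pytest

from mirpipe import annotate as ann
from mirpipe import readproc as rp
from mirpipe import simdata as sd


@pytest.fixture(scope="session")
def sim_config() -> sd.SimConfig:
    return sd.SimConfig(
        seed=11,
        library_depth=20_000,
        n_known_precursors=10,
        n_conserved_precursors=5,
        n_novel_loci=8,
        genome_length=30_000,
    )


@pytest.fixture(scope="session")
def sim(sim_config):
    bundle = sd.generate_references(sim_config)
    reads_a, reads_b, truth = sd.simulate_libraries(bundle, sim_config)
    return SimpleNamespace(
        config=sim_config, bundle=bundle, reads_a=reads_a, reads_b=reads_b, truth=truth
    )


@pytest.fixture(scope="session")
def processed(sim):
    params = rp.FilterParams(adapter=sim.config.adapter_sequence)
    tags, report = rp.process_pair(
        [r.sequence for r in sim.reads_a],
        [r.sequence for r in sim.reads_b],
        params,
        sim.bundle.contaminants,
    )
    return SimpleNamespace(tags=tags, report=report, params=params)


@pytest.fixture(scope="session")
def classified(sim, processed):
    return ann.classify_tags(processed.tags, sim.bundle)
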