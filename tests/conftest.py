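import numpy as np
import pytest

from crowdlens.composition import SpeciesSpec, lens_composition, to_reduced_units
from crowdlens.engine import core as engine


@pytest.fixture(scope="session")
def lens_set():
    return lens_composition()


@pytest.fixture(scope="session")
def mono_species():
    return to_reduced_units([SpeciesSpec("alpha", 18.6, 1.13e-18)])


@pytest.fixture(scope="session")
def mono_fluid(mono_species):
    """Small equilibrated monodisperse fluid at phi=0.30 with sampled frames."""
    cfg = engine.SimConfig(
        n_particles=600, species_set=mono_species, target_phi=0.30, seed=101,
        equilibration_collisions_per_particle=100,
    )
    state = engine.initial_state(cfg)
    engine.compress_to_phi(state, cfg)
    eq = engine.equilibrate(state, cfg)
    frames = engine.sample_frames(
        state, cfg, n_frames=40,
        collision_rate=eq.n_collisions / eq.elapsed,
    )
    return cfg, state, frames
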