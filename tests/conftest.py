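import numpy as np
import pytest

import gqfret as g


@pytest.fixture
def ntfree_isotherm():
    """Langmuir parameters of the nucleotide-free protein titration."""
    return g.IsothermParams(alpha=49.0, k_eq=305.0, units="nM")


@pytest.fixture
def ntfree_occupancy(ntfree_isotherm):
    return g.OccupancySpec(
        ntfree_isotherm, g.folded_states_potassium(), g.default_low_states()
    )


@pytest.fixture
def blm_condition():
    return g.Condition(protein=g.Protein.BLM, protein_conc=300.0)


@pytest.fixture
def small_config(ntfree_occupancy, blm_condition):
    """A light simulation config for fast unit tests."""
    return g.SimulationConfig(
        condition=blm_condition,
        occupancy=ntfree_occupancy,
        n_molecules=60,
        n_frames=30,
        contaminant_fraction=0.0,
        seed=7,
    )


def single_state_config(
    state: g.FretState,
    n_molecules: int = 100,
    n_frames: int = 30,
    seed: int = 5,
    **overrides,
):
    """Generator pinned to one spectroscopic state (occupancy all-folded at x=0)."""
    occ = g.OccupancySpec(
        g.IsothermParams(50.0, 100.0),
        folded_states=((state, 1.0),),
        low_states=g.default_low_states(),
    )
    kwargs = dict(
        condition=g.Condition(),
        occupancy=occ,
        n_molecules=n_molecules,
        n_frames=n_frames,
        contaminant_fraction=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return g.SimulationConfig(**kwargs)


def fret_traces_of(config, dataset_index=0, proc=None):
    ds = g.simulate_dataset(config, dataset_index)
    proc = proc or g.ProcessingOptions(
        background_d=config.background_d, background_a=config.background_a
    )
    fret, _ = g.process_dataset(ds, proc)
    return fret
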