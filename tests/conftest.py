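import pytest

from smkinetics.conditions import CONDITIONS, make_simulation_config
from smkinetics.simulate import FretState, MoleculeClass, SimulationConfig


@pytest.fixture(scope="session")
def core_config() -> SimulationConfig:
    """Wild-type core condition, 10-minute movies."""
    return make_simulation_config(CONDITIONS["core"], n_frames=6000)


@pytest.fixture(scope="session")
def stem1_config() -> SimulationConfig:
    return make_simulation_config(CONDITIONS["stem1"], n_frames=6000)


@pytest.fixture
def single_state_fret_config() -> SimulationConfig:
    """Single FRET state matching the isolated Stem-I:tRNA histogram."""
    return SimulationConfig(
        n_frames=60,
        fret_states=(FretState(0.28, 0.13, 1.0),),
        noise_sd=0.0,
        intensity_on=600.0,
        bleach_lifetime_cy5_s=1e9,
        bleach_lifetime_cy3_s=1e9,
    )


def make_single_class_config(koff: float, kon_c_per_s: float, **overrides) -> SimulationConfig:
    """Homogeneous-kinetics config with a given pseudo-first-order rate."""
    kwargs = dict(
        n_frames=6000,
        trna_conc_nM=10.0,
        kon_per_M_s=kon_c_per_s / 10e-9,
        molecule_classes=(MoleculeClass("only", koff, 1.0),),
        inactive_fraction=0.0,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
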