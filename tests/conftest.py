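import pytest

from casim.params import load_preset, load_release_kinetics
from casim.release import fit_release

FIBERS = ("I", "IIA", "IIX", "IIB")


@pytest.fixture(scope="session")
def presets():
    return {ft: load_preset(ft) for ft in FIBERS}


@pytest.fixture(scope="session")
def kinetics():
    return {ft: load_release_kinetics(ft) for ft in FIBERS}


@pytest.fixture(scope="session")
def waveforms(kinetics):
    """Fitted release waveforms, shared across the whole test session."""
    return {ft: fit_release(kinetics[ft]) for ft in FIBERS}


@pytest.fixture(scope="session")
def single_runs(presets, waveforms):
    """Single-twitch simulations of all four fiber types."""
    from casim.simulate import SINGLE_TWITCH, run
    return {ft: run(presets[ft], waveforms[ft], SINGLE_TWITCH)
            for ft in FIBERS}


@pytest.fixture(scope="session")
def grid():
    """Summary grid over the full fiber-type continuum, both protocols."""
    from casim.simulate import run_continuum
    return run_continuum()
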