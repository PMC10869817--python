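import numpy as np
import pytest

from eqtac.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic cohort shared by unit tests (60 individuals, 20 peaks)."""
    cfg = SimConfig(
        seed=11,
        n_individuals=60,
        n_genes=60,
        n_peaks=20,
        genome_length=60_000,
        n_intergenic_blocks=6,
        n_lowexpr_genes=5,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def cohort_dir(small_sim, tmp_path_factory):
    """The same cohort written to disk in pipeline formats."""
    out = tmp_path_factory.mktemp("cohort")
    small_sim.write(out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
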