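import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def double_well_potential():
    from fieldpmf.committor import double_well

    return double_well(barrier_height=5.0, half_separation=1.0)


@pytest.fixture(scope="session")
def double_well_windows(double_well_potential):
    """21 umbrella windows (k = 50, centers -1.25..1.25 A) sampled exactly
    from the biased Boltzmann densities of the 5 kcal/mol quartic double
    well at 343.15 K; the standard parameter-recovery fixture."""
    from fieldpmf.synthetic_data import GeneratorSpec, sample_umbrella_windows
    from fieldpmf.wham import BiasSpec

    biases = [BiasSpec(c, 50.0) for c in np.linspace(-1.25, 1.25, 21)]
    return sample_umbrella_windows(
        double_well_potential,
        biases,
        temperature=343.15,
        n_samples=10_000,
        spec=GeneratorSpec(seed=7),
        support=(-2.0, 2.0),
        stratified=True,
    )


@pytest.fixture(scope="session")
def wham_config():
    from fieldpmf.wham import WhamConfig

    # discard_fraction 0 because the exact sampler has no equilibration phase
    return WhamConfig(bin_width=0.02, n_bootstrap=30, seed=11, discard_fraction=0.0)


@pytest.fixture(scope="session")
def double_well_profile(double_well_windows, wham_config):
    from fieldpmf.wham import wham_solve

    return wham_solve(double_well_windows, wham_config)


@pytest.fixture(scope="session")
def toy_site():
    from fieldpmf.synthetic_data import GeneratorSpec, gen_toy_active_site

    return gen_toy_active_site(GeneratorSpec(seed=0))


@pytest.fixture()
def toy_frame(toy_site, tmp_path):
    from fieldpmf.structures_io import read_structure

    p = tmp_path / "toy.pdb"
    p.write_text(toy_site.pdb_text)
    return read_structure(p, toy_site.charge_table)
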