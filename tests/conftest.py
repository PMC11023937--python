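import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from musicpipe.layout import BarcodeTables, ReadLayout
from musicpipe.synthdata import SimConfig, make_reference, simulate_ground_truth
from musicpipe.synthdata.reference import default_config


@pytest.fixture(scope="session")
def reference():
    return make_reference(default_config(), seed=7)


@pytest.fixture(scope="session")
def tables():
    return BarcodeTables.generate(seed=0)


@pytest.fixture(scope="session")
def layout():
    return ReadLayout()


@pytest.fixture(scope="session")
def small_ground_truth(reference):
    cfg = SimConfig(n_cells=12, complexes_per_cell=12, rna_dna_frac=0.3, xist_rate=1.0)
    return simulate_ground_truth(reference, cfg, seed=21)
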