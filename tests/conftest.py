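import pytest

from lnceqtm.pipeline import SubtypeInputs, run_subtype
from lnceqtm.simulate import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_tumor=30, n_normal=30, n_genes=30,
                            n_intergenic_probes=10)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_config):
    """One generated subtype bundle on disk, shared across the session."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_study(small_config, out)


def inputs_from(paths, clinical=True):
    return SubtypeInputs(
        gtf=paths["gtf"], probes=paths["probes"],
        beta_tumor=paths["beta_tumor"], beta_normal=paths["beta_normal"],
        expr_tumor=paths["expr_tumor"], expr_normal=paths["expr_normal"],
        clinical=paths["clinical"] if clinical else None)


@pytest.fixture(scope="session")
def small_result(small_bundle):
    """Full pipeline run on the shared bundle."""
    return run_subtype(inputs_from(small_bundle), "test")
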