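from __future__ import annotations

import numpy as np
import pytest

from mirquest.pipeline import PipelineConfig
from mirquest.simulate import SimConfig, make_fixture

COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The default synthetic study: Poisson counts, errors, jitter."""
    out = tmp_path_factory.mktemp("fixture_default")
    return make_fixture(SimConfig(seed=1), out)


@pytest.fixture(scope="session")
def noiseless_fixture(tmp_path_factory):
    """Exact-count, error-free, jitter-free study for conservation tests."""
    out = tmp_path_factory.mktemp("fixture_noiseless")
    config = SimConfig(
        seed=3, error_rate=0.0, read_end_jitter=0, fixed_counts=True
    )
    return make_fixture(config, out)


def pipeline_config_for(fixture) -> PipelineConfig:
    return PipelineConfig(
        reads=str(fixture.paths["reads"]),
        genome=str(fixture.paths["genome"]),
        mature=str(fixture.paths["mature"]),
        families=str(fixture.paths["families"]),
        contaminants=str(fixture.paths["contaminants"]),
        ncrna_db=str(fixture.paths["ncrna_db"]),
        annotation=str(fixture.paths["annotation"]),
        seed=fixture.config.seed,
    )


@pytest.fixture(scope="session")
def default_run(default_fixture):
    """Both pipeline branches executed once on the default study."""
    from mirquest.pipeline import run_discover, run_quantify

    config = pipeline_config_for(default_fixture)
    qres = run_quantify(config)
    dres = run_discover(config, qres)
    return config, qres, dres


@pytest.fixture(scope="session")
def noiseless_run(noiseless_fixture):
    from mirquest.pipeline import run_discover, run_quantify

    config = pipeline_config_for(noiseless_fixture)
    qres = run_quantify(config)
    dres = run_discover(config, qres)
    return config, qres, dres
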