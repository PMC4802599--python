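import numpy as np
import pytest
from hypothesis import settings

import senmir

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def small_config(seed: int = 11, **overrides) -> senmir.SimConfig:
    """A scaled-down study: same design, smaller genome and depth."""
    params = dict(
        seed=seed,
        genome_length=30_000,
        n_known_mirnas=10,
        n_novel_mirnas=3,
        n_ncrna_loci=6,
        n_sa_mirnas=4,
        reads_per_library=3_000,
        degradome_depth=3_000,
    )
    params.update(overrides)
    return senmir.SimConfig(**params)


@pytest.fixture(scope="session")
def small_study():
    return senmir.generate_toy_genome(small_config())


@pytest.fixture(scope="session")
def small_report(tmp_path_factory):
    cfg = senmir.RunConfig(seed=11, outdir=str(tmp_path_factory.mktemp("run")))
    cfg.sim = small_config()
    return senmir.run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
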