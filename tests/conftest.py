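from __future__ import annotations

import numpy as np
import pytest

from telocus.pipeline import RunConfig, run_all
from telocus.synth import SynthConfig, build_genome


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_build():
    """A small genome shared by read-level tests."""
    cfg = SynthConfig(n_chroms=2, chrom_length=40_000, n_genes=6, n_te=40,
                      expressed_fraction=0.6, n_planted_de=0, n_coupled_pairs=0)
    return build_genome(cfg, seed=77)


@pytest.fixture(scope="session")
def toy_run(tmp_path_factory):
    """One full default-config pipeline run, shared across tests."""
    outdir = tmp_path_factory.mktemp("toyrun")
    cfg = RunConfig(outdir=str(outdir), seed=1)
    results = run_all(cfg)
    return cfg, results
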