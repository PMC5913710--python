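"""Shared fixtures: small synthetic datasets and short fitted runs.

Fits are session-scoped because a posterior run is the expensive resource
here; analysis, selection, and CLI tests reuse the same draws.
"""

from __future__ import annotations

import numpy as np
import pytest

import fvcbayes as fb


@pytest.fixture(scope="session")
def jm_spec() -> fb.ModelSpec:
    return fb.ModelSpec.from_code("CaCc_Jm")


@pytest.fixture(scope="session")
def small_dataset(jm_spec):
    """Two genotypes x 3 individuals x 12 setpoints, strong signal."""
    truth = fb.default_truth(
        jm_spec,
        genotypes=("g1", "g2"),
        n_individuals=3,
        process_sigma=0.5,
        seed=7,
    )
    curves, record = fb.generate_dataset(truth)
    return curves, record


@pytest.fixture(scope="session")
def quick_config():
    return fb.RunConfig(chains=2, iterations=800, burn_in=800, thin=4, seed=11)


@pytest.fixture(scope="session")
def fitted_run(small_dataset, jm_spec, quick_config):
    """One short posterior run (genotype g1)."""
    curves, _ = small_dataset
    g1 = [c for c in curves if c.genotype_id == "g1"]
    return fb.run_mcmc(g1, jm_spec, quick_config)


@pytest.fixture(scope="session")
def fitted_pair(small_dataset, jm_spec, quick_config):
    """Short posterior runs for both genotypes of the small dataset."""
    curves, _ = small_dataset
    runs = {}
    for geno in ("g1", "g2"):
        sub = [c for c in curves if c.genotype_id == geno]
        cfg = fb.RunConfig(chains=2, iterations=800, burn_in=800, thin=4,
                           seed=11 + (geno == "g2"))
        runs[geno] = fb.run_mcmc(sub, jm_spec, cfg)
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
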