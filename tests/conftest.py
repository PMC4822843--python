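"""Shared fixtures: toy profile models and one full pipeline run.

The full synthetic pipeline run is expensive (~1 minute) and several tests
read different statistics off it, so it is session-scoped and executed at
the package's default study conditions (300 proteins, 6 families in two
superfamilies, divergence 0.25, seed 1).
"""

from __future__ import annotations

import numpy as np
import pytest

from periscan import default_synthetic_config, run_pipeline
from periscan.constants import BACKGROUND
from periscan.profiles import ProfileModel

PIPELINE_SEED = 1


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Completed pipeline manifest + state on the default synthetic proteome."""
    outdir = tmp_path_factory.mktemp("pipeline")
    manifest = run_pipeline(default_synthetic_config(rng_seed=PIPELINE_SEED), outdir)
    return manifest


@pytest.fixture(scope="session")
def pipeline_state(pipeline_run):
    return pipeline_run.state


def random_toy_model(rng: np.random.Generator, length: int, model_id: str) -> ProfileModel:
    """A random valid profile model with <= a few match states."""
    em = rng.dirichlet(np.ones(20) * 0.5, size=length)
    tMM = np.ones(length)
    tMI = np.zeros(length)
    tMD = np.zeros(length)
    for k in range(length - 1):
        tMM[k], tMI[k], tMD[k] = rng.dirichlet([5.0, 1.0, 1.0])
    tIM = np.empty(length)
    tII = np.empty(length)
    for k in range(length):
        tIM[k], tII[k] = rng.dirichlet([3.0, 1.0])
    tDM = np.ones(length)
    tDD = np.zeros(length)
    for k in range(1, length - 1):
        tDM[k], tDD[k] = rng.dirichlet([3.0, 1.0])
    model = ProfileModel(
        model_id=model_id,
        match_emissions=em,
        insert_emissions=BACKGROUND.copy(),
        tMM=tMM, tMI=tMI, tMD=tMD, tIM=tIM, tII=tII, tDM=tDM, tDD=tDD,
        background=BACKGROUND.copy(),
        exit_prob=0.05,
    )
    model.validate()
    return model
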