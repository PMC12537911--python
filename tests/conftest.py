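import logging

import numpy as np
import pandas as pd
import pytest

from clonetrack import (
    PipelineConfig,
    SimConfig,
    gen_repertoire,
    run_human_pipeline,
    run_mouse_pipeline,
)

logging.getLogger("clonetrack").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic subject: repertoires plus ground truth (seed 202)."""
    config = SimConfig(seed=202)
    samples, truth = gen_repertoire(config, config.rng())
    return config, samples, truth


@pytest.fixture(scope="session")
def mouse_run():
    """One full mouse-mode pipeline run on the default cohort (seed 202)."""
    cfg = PipelineConfig(seed=202)
    return run_mouse_pipeline(cfg, SimConfig(seed=202))


@pytest.fixture(scope="session")
def human_run():
    """Mouse-derived signature applied to the synthetic human cohort (seed 404)."""
    cfg = PipelineConfig(seed=404)
    mouse = run_mouse_pipeline(cfg, SimConfig(seed=404))
    human = run_human_pipeline(cfg, mouse.signature, SimConfig(seed=404))
    return mouse, human


def truth_expansion_by_key(truth) -> dict:
    """Map full clone keys (V, D, J, CDR3) to latent expansion rates."""
    keys = truth.clone_keys
    return {
        (r.v_call, r.d_call, r.j_call, r.cdr3_nt): e
        for r, e in zip(keys.itertuples(), truth.expansion_rate)
    }
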