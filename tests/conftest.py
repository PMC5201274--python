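import numpy as np
import pytest

from panelmediate.simulate import (SimConfig, ItemBlock, generate_panel,
                                   study_default_config, three_construct_config)


@pytest.fixture(scope="session")
def xmy_config():
    """Small X/M/Y 4-wave cohort with known nonzero mediation."""
    return three_construct_config(n_subjects=1000, seed=101)


@pytest.fixture(scope="session")
def xmy_panel(xmy_config):
    return generate_panel(xmy_config)


@pytest.fixture(scope="session")
def study_panel():
    """Mid-sized cohort calibrated to the study's baseline marginals."""
    cfg = study_default_config(n_subjects=2500, seed=7)
    return cfg, generate_panel(cfg)


@pytest.fixture(scope="session")
def lat_items():
    return {c: [[f"lat_{c}_w{w}"] for w in range(1, 5)] for c in ("X", "M", "Y")}
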