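"""Shared fixtures: synthetic grids and feature tables built once per session."""

import numpy as np
import pytest

from pwvlab.features import feature_table
from pwvlab.pipeline_io import process_record
from pwvlab.synthgen import GeneratorParams, generate_dataset, make_config_grid


@pytest.fixture(scope="session")
def full_grid():
    return make_config_grid()


@pytest.fixture(scope="session")
def noisefree_params():
    return GeneratorParams(noise_sd=0.0, drift_amp=0.0, duration=30.0)


@pytest.fixture(scope="session")
def noisefree_records(full_grid, noisefree_params):
    records, labels = generate_dataset(full_grid, noisefree_params)
    return records, labels


@pytest.fixture(scope="session")
def noisy_features(full_grid):
    """Per-trial feature table from the 90-config grid at default noise."""
    records, _ = generate_dataset(full_grid, GeneratorParams(seed=7))
    fvs = []
    for rec in records:
        fv, _ = process_record(rec)
        assert fv is not None
        fvs.append(fv)
    return feature_table(fvs)
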