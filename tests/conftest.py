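"""Shared fixtures: one surrogate system and one descriptor fixture per session."""

import numpy as np
import pandas as pd
import pytest

from translocv import surrogate as sg
from translocv.contacts import filter_descriptors
from translocv.tables import DescriptorTable

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def system():
    return sg.build_surrogate(sg.SurrogateConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def specs():
    return sg.default_descriptor_specs(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def two_state_tables():
    """Small PRE/POST candidate-pool tables (fast; margins don't depend on n)."""
    pre, post, labels = sg.make_fixture(seed=FIXTURE_SEED, n_frames_per_state=1500)
    return pre, post, labels


@pytest.fixture(scope="session")
def retained_ids(two_state_tables):
    pre, post, _ = two_state_tables
    retained, _ = filter_descriptors(pre, post)
    return retained


@pytest.fixture(scope="session")
def labeled_two_state(two_state_tables, retained_ids):
    """Retained-descriptor table with PRE/POST labels, ready for CV training."""
    pre, post, labels = two_state_tables
    a, b = pre.select(retained_ids), post.select(retained_ids)
    df = pd.concat([a.data, b.data], ignore_index=True)
    return DescriptorTable(df, a.metadata, labels)


@pytest.fixture(scope="session")
def descriptor_map(specs, retained_ids):
    return sg.DescriptorMap(specs).subset(retained_ids)
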