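import numpy as np
import pytest

import panelnet as pn


@pytest.fixture(scope="session")
def study_spec():
    """One fixed study-like ground truth shared across tests."""
    return pn.study_like_spec(seed=1)


@pytest.fixture(scope="session")
def study_panel(study_spec):
    """A complete (no-missing) study-sized panel and its latent scores."""
    return pn.simulate_panel(study_spec, pn.STUDY_N, seed=2)


@pytest.fixture(scope="session")
def fast_ggm_config():
    """Short penalty path used where many networks are re-estimated."""
    return pn.GGMConfig(n_lambda=20, lambda_min_ratio=0.05)


@pytest.fixture()
def tiny_schema():
    """A 5-item two-subscale schema for hand-sized fixtures."""
    items = ("a1", "a2", "a3", "b1", "b2")
    sub = {"a1": "intrusion", "a2": "intrusion", "a3": "intrusion",
           "b1": "avoidance", "b2": "avoidance"}
    return pn.ItemSchema(item_ids=items, subscale_of=sub, response_range=(0, 4))


def make_dataset(responses, schema, mask=None):
    responses = np.asarray(responses, dtype=float)
    if mask is None:
        mask = np.isnan(responses)
    return pn.PanelDataset(
        ids=np.arange(responses.shape[0]),
        responses=responses,
        mask=mask,
        schema=schema,
    )
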