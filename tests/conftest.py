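import numpy as np
import pandas as pd
import pytest

import proxinet as px
from proxinet.records import EVENT_COLS


@pytest.fixture(scope="session")
def small_truth():
    return px.simulate_colony(px.ColonyParams(n_bats=15, n_nights=5, seed=3))


@pytest.fixture(scope="session")
def night_streams(small_truth):
    return px.simulate_foraging_nights(small_truth)


@pytest.fixture(scope="session")
def full_streams(small_truth, night_streams):
    ev_n, st_n, bouts = night_streams
    ev_d, st_d = px.simulate_roosting_days(small_truth)
    events = pd.concat([ev_d, ev_n[EVENT_COLS]], ignore_index=True)
    stations = pd.concat([st_d, st_n], ignore_index=True)
    return events, stations, bouts


@pytest.fixture(scope="session")
def true_foraging_table(night_streams):
    ev_n, _, bouts = night_streams
    fe = ev_n[ev_n["true_context"] == "foraging"]
    return px.hourly_coforaging(fe, bouts)


def make_truth(relationship, seed=0, **overrides):
    """Hand-built SyntheticTruth around a given relationship matrix."""
    n = relationship.shape[0]
    params = px.ColonyParams(n_bats=n, seed=seed,
                             type_assignment=["control"] * n, **overrides)
    ids = params.ids
    truth = px.simulate_colony(params)
    truth = px.SyntheticTruth(
        params=params, ids=ids, types={b: "control" for b in ids},
        relationship=px.DyadicMatrix(ids, relationship, role="rate"),
        kinship=px.DyadicMatrix.zeros(ids, role="kinship"),
        grooming=None, sharing=None,
        depart_intercepts=truth.depart_intercepts,
        bout_intercepts=truth.bout_intercepts, dropout_nights={})
    return truth
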