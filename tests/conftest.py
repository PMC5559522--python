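import numpy as np
import pandas as pd
import pytest

from fluxcordance.expression import ReactionData
from fluxcordance.synth import (
    branched_cycle_model,
    chain_model,
    parallel_routes_model,
    two_compartment_model,
)


def reaction_data_from_dict(model, d, sigma=None, w=None):
    """Hand-built ReactionData for fixtures: d maps reaction id -> target."""
    ids = model.reaction_ids
    table = pd.DataFrame(index=ids, dtype=float)
    table["d"] = pd.Series(d, dtype=float).reindex(ids)
    table["sigma"] = pd.Series(sigma or {}, dtype=float).reindex(ids).fillna(0.0)
    if w is None:
        w = {rid: 1.0 for rid in d}
    table["w"] = pd.Series(w, dtype=float).reindex(ids)
    table["mapped"] = table.index.isin(d)
    table.loc[~table["mapped"], ["d", "sigma", "w"]] = np.nan
    return ReactionData(table=table, scale=1.0)


@pytest.fixture
def chain():
    return chain_model()


@pytest.fixture
def branched_cycle():
    return branched_cycle_model()


@pytest.fixture
def two_compartment():
    return two_compartment_model()


@pytest.fixture
def parallel_routes():
    return parallel_routes_model()
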