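import numpy as np
import pandas as pd
import pytest

from idnet import (
    LagNetwork,
    RatingMatrix,
    estimate_network,
    prune_isolated_nodes,
    case_study_spec,
    simulate,
)
from idnet.detrend import detrend_all


def make_rating_matrix(values, observed=None, start="2020-01-01", items=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if observed is None:
        observed = np.isfinite(values)
    if items is None:
        items = [f"it{i}" for i in range(p)]
    days = pd.date_range(start, periods=n, freq="D")
    return RatingMatrix(days=days, items=items, values=values,
                        observed=np.asarray(observed, dtype=bool))


@pytest.fixture(scope="session")
def diary_like():
    """A diary shaped like the motivating case: 22 items, 122-day span,
    ~90 observed days, a few planted quadratic trends, sparse signed truth."""
    spec = case_study_spec(seed=11)
    return spec, simulate(spec)


@pytest.fixture(scope="session")
def diary_network(diary_like):
    """Estimated and pruned network from the diary-shaped fixture."""
    spec, rm = diary_like
    residuals, _ = detrend_all(rm)
    net = estimate_network(residuals)
    pruned, removed = prune_isolated_nodes(net)
    return {"spec": spec, "residuals": residuals, "net": net,
            "pruned": pruned, "removed": removed}


@pytest.fixture
def two_node_net():
    return LagNetwork(nodes=["a", "b"], W=np.array([[0.0, 0.5], [-0.3, 0.0]]))
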