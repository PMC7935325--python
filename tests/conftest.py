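import networkx as nx
import numpy as np
import pandas as pd
import pytest

from sepsisnet import ExpressionMatrix, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def small_matrix():
    """3 genes × 4 samples, 2 control / 2 case."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [2.0, 2.5, 6.0, 7.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    group = {"s1": "control", "s2": "control", "s3": "case", "s4": "case"}
    return ExpressionMatrix(values=values, group=group)


@pytest.fixture
def grouped_matrix():
    """20 genes × 12 samples of seeded noise, 6/6 split."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        8.0 + rng.standard_normal((20, 12)),
        index=[f"G{i}" for i in range(20)],
        columns=[f"s{i}" for i in range(12)],
    )
    group = {f"s{i}": ("control" if i < 6 else "case") for i in range(12)}
    return ExpressionMatrix(values=values, group=group)


@pytest.fixture
def two_triangles():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")])
    return g


@pytest.fixture
def path3():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g
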