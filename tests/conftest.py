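import numpy as np
import pytest
from hypothesis import settings

from stratnet import WeightedGraph, default_schema

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def schema():
    return default_schema()


def make_random_graph(
    rng: np.random.Generator,
    n: int | None = None,
    edge_prob: float = 0.4,
    signed: bool = True,
) -> WeightedGraph:
    """Seeded random weighted graph with at least one edge."""
    n = n if n is not None else int(rng.integers(4, 21))
    while True:
        edges = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < edge_prob:
                    w = rng.uniform(0.1, 1.0)
                    if signed and rng.random() < 0.5:
                        w = -w
                    edges[(i, j)] = (float(w), None)
        if edges:
            return WeightedGraph(tuple(f"v{i}" for i in range(n)), edges)


@pytest.fixture
def random_graph_factory():
    return make_random_graph


@pytest.fixture
def small_cohort_csv(tmp_path, schema):
    """Well-formed 10-row cohort CSV matching the default schema."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(10):
        row = {}
        for e in schema:
            if e.mtype == "binary":
                row[e.name] = int(rng.integers(0, 2))
            else:
                row[e.name] = round(float(rng.normal(50, 10)), 3)
        row["FA"] = i % 2
        rows.append(row)
    import pandas as pd

    path = tmp_path / "cohort.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
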