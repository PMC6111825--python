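import numpy as np
import pandas as pd
import pytest

from subpathsig.expression_io import GOOD, POOR, ClinicalTable, ZMatrix
from subpathsig.pathway_io import PathwayGraph


def zmatrix(values, genes=None, samples=None) -> ZMatrix:
    """Z-normalize a raw array row-wise and wrap it (ddof=1)."""
    vals = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(vals.shape[0])]
    samples = samples or [f"s{j}" for j in range(vals.shape[1])]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(
        axis=1, ddof=1, keepdims=True
    )
    return ZMatrix(pd.DataFrame(z, index=genes, columns=samples))


def labels(n_good, n_poor, samples=None) -> pd.Series:
    samples = samples or [f"s{j}" for j in range(n_good + n_poor)]
    return pd.Series([GOOD] * n_good + [POOR] * n_poor, index=samples)


def path_graph(pid, genes) -> PathwayGraph:
    """A simple path graph over the given gene symbols."""
    edges = list(zip(genes[:-1], genes[1:]))
    return PathwayGraph.from_edges(pid, edges)


def random_graph(pid, n_nodes, rng, edge_prob=0.4) -> PathwayGraph:
    genes = [f"g{i}" for i in range(n_nodes)]
    edges = [
        (genes[i], genes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < edge_prob
    ]
    return PathwayGraph(pid, frozenset(genes), frozenset(edges))


def make_clinical(times, events, labels_=None, samples=None,
                  **covariates) -> ClinicalTable:
    samples = samples or [f"s{j}" for j in range(len(times))]
    data = {"time_months": times, "event": events}
    if labels_ is not None:
        data["label"] = labels_
    data.update(covariates)
    return ClinicalTable(pd.DataFrame(data, index=pd.Index(samples, name="sample")))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
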