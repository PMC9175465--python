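import networkx as nx
import numpy as np
import pytest
from scipy import sparse

from comorbnet import CohortMatrix, DiseaseNetwork
from comorbnet.network import ALL_EDGES


def make_cohort(incidence, labels=None) -> CohortMatrix:
    """Wrap a dense 0/1 array as a CohortMatrix."""
    incidence = np.asarray(incidence, dtype=np.uint8)
    if labels is None:
        labels = [f"C{j:03d}" for j in range(incidence.shape[1])]
    mat = sparse.csr_matrix(incidence)
    return CohortMatrix(
        incidence=mat,
        condition_labels=list(labels),
        prevalence=np.asarray(mat.mean(axis=0)).ravel(),
    )


def wrap_graph(graph: nx.Graph, measure="phi", selection=ALL_EDGES) -> DiseaseNetwork:
    """Wrap a bare networkx graph as a DiseaseNetwork for unit tests."""
    for _, _, d in graph.edges(data=True):
        d.setdefault("weight", 1.0)
        d.setdefault("joint_prevalence", 0.0)
        d.setdefault("prevalence_difference", 0.0)
    return DiseaseNetwork(graph=graph, measure_name=measure, selection=selection)


@pytest.fixture(scope="session")
def mixed_runs():
    """Three replicate mixed-spectrum cohorts with their screened dyads."""
    import comorbnet as cn

    runs = []
    for seed in (0, 1, 2):
        cohort = cn.generate_cohort(cn.mixed_spectrum_config(seed))
        runs.append((cohort, cn.build_association_table(cohort)))
    return runs


@pytest.fixture
def random_cohort():
    """120 individuals x 8 moderately prevalent independent conditions."""
    rng = np.random.default_rng(2024)
    return make_cohort(rng.random((120, 8)) < 0.3)
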