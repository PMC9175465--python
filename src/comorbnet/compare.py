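"""Cross-measure comparison of disease networks.

Networks built from the same cohort but weighted by different
co-occurrence measures are compared on three axes:

* community structure — adjusted Rand index (ARI) between Louvain
  partitions, computed on the intersection of the two node sets (the
  restrictive strata produce different node sets per measure);
* edges — percent of edges in common;
* central nodes — percent agreement of the top-k degree-central nodes.

Across all measure pairs, similarity is rolled up as the median and
the 25th/75th percentiles over the 21 unordered off-diagonal pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .community import Partition
from .errors import InvalidConfigError, UndefinedARIError
from .network import DiseaseNetwork, density, top_central_nodes


def adjusted_rand_index(
    p1: Partition, p2: Partition, scope: Sequence[str] | set[str]
) -> float:
    """Chance-corrected pair-counting agreement of two partitions.

    Both partitions must assign every node in ``scope``; 1 means
    identical clusterings, values near 0 mean chance-level agreement.
    """
    nodes = sorted(scope)
    if len(nodes) < 2:
        raise UndefinedARIError("ARI needs at least two nodes in scope")
    try:
        l1 = [p1.assignment[n] for n in nodes]
        l2 = [p2.assignment[n] for n in nodes]
    except KeyError as exc:
        raise UndefinedARIError(f"node {exc} not assigned in both partitions")
    return float(adjusted_rand_score(l1, l2))


def edge_agreement(n1: DiseaseNetwork, n2: DiseaseNetwork) -> float:
    """Percent of edges in common between two networks.

    The denominator is the shared edge count when both networks have
    the same number of edges (always true for same-stratum networks),
    otherwise the smaller of the two.
    """
    e1, e2 = n1.edge_set(), n2.edge_set()
    if not e1 or not e2:
        return 0.0
    denom = len(e1) if len(e1) == len(e2) else min(len(e1), len(e2))
    return 100.0 * len(e1 & e2) / denom


def central_node_agreement(
    list1: Sequence[str], list2: Sequence[str], k: int = 20
) -> float:
    """Percent overlap of two top-k central-node lists, relative to k."""
    if k == 0:
        raise InvalidConfigError("k must be positive")
    return 100.0 * len(set(list1) & set(list2)) / k


def _quantile_summary(values: np.ndarray) -> tuple[float, float, float]:
    med, q1, q3 = np.percentile(values, [50, 25, 75])
    return float(med), float(q1), float(q3)


@dataclass
class ComparisonReport:
    """Pairwise similarity matrices and per-network summaries."""

    measures: list[str]
    ari_matrix: np.ndarray
    edge_agreement_matrix: np.ndarray
    centrality_agreement_matrix: np.ndarray
    summaries: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    per_network: dict[str, dict[str, float]] = field(default_factory=dict)

    def _offdiag(self, matrix: np.ndarray) -> np.ndarray:
        iu = np.triu_indices(len(self.measures), k=1)
        return matrix[iu]

    def to_dict(self) -> dict:
        return {
            "measures": self.measures,
            "ari_matrix": self.ari_matrix.tolist(),
            "edge_agreement_matrix": self.edge_agreement_matrix.tolist(),
            "centrality_agreement_matrix": self.centrality_agreement_matrix.tolist(),
            "summaries": {
                key: {"median": s[0], "q1": s[1], "q3": s[2]}
                for key, s in self.summaries.items()
            },
            "per_network": self.per_network,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_comparison_report(
    networks: Mapping[str, DiseaseNetwork],
    partitions: Mapping[str, Partition],
    k: int = 20,
) -> ComparisonReport:
    """Fill all three similarity matrices over every measure pair.

    All networks must share the same edge stratum.  ARI is computed on
    the intersection of each pair's node sets; if the intersection has
    fewer than two nodes the entry is NaN and excluded from summaries.
    """
    measures = list(networks)
    if set(partitions) != set(networks):
        raise InvalidConfigError("networks and partitions must cover the same measures")
    strata = {net.selection for net in networks.values()}
    if len(strata) > 1:
        raise InvalidConfigError(
            f"all networks must share one edge stratum, got {strata}"
        )

    p = len(measures)
    ari = np.eye(p)
    edges = np.full((p, p), 100.0)
    central = np.full((p, p), 100.0)
    tops = {m: top_central_nodes(networks[m], k) for m in measures}

    for i in range(p):
        for j in range(i + 1, p):
            mi, mj = measures[i], measures[j]
            scope = set(networks[mi].graph.nodes) & set(networks[mj].graph.nodes)
            try:
                a = adjusted_rand_index(partitions[mi], partitions[mj], scope)
            except UndefinedARIError:
                a = float("nan")
            ari[i, j] = ari[j, i] = a
            e = edge_agreement(networks[mi], networks[mj])
            edges[i, j] = edges[j, i] = e
            c = central_node_agreement(tops[mi], tops[mj], k)
            central[i, j] = central[j, i] = c

    report = ComparisonReport(
        measures=measures,
        ari_matrix=ari,
        edge_agreement_matrix=edges,
        centrality_agreement_matrix=central,
    )
    iu = np.triu_indices(p, k=1)
    report.summaries = {
        "ari": _quantile_summary(ari[iu][~np.isnan(ari[iu])]) if p > 1 else (1.0, 1.0, 1.0),
        "edge_agreement": _quantile_summary(edges[iu]) if p > 1 else (100.0,) * 3,
        "centrality_agreement": _quantile_summary(central[iu]) if p > 1 else (100.0,) * 3,
    }
    for m in measures:
        net = networks[m]
        report.per_network[m] = {
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "density": density(net) if net.n_nodes >= 2 else float("nan"),
            "n_communities": partitions[m].n_communities,
            "modularity": partitions[m].modularity,
        }
    return report
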