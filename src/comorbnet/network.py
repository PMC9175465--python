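"""Weighted disease networks and their structural description.

A disease network links condition pairs that survived the association
filters, weighted by one of the seven co-occurrence measures.  Networks
are built under three edge strata: all retained associations, the
strongest 50% (floor convention), and the strongest 200.  Nodes enter
the graph only through kept edges, so restrictive strata shrink the
node set differently under different measures — which is exactly the
phenomenon this package quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .association import MEASURES, AssociationTable
from .errors import (
    InvalidConfigError,
    InvalidNetworkError,
    UndefinedDensityError,
)

BAND_THRESHOLDS = (0.01, 0.07)
BAND_NAMES = ("low", "moderate", "high")
#: Unordered endpoint-band classes for edges.
BAND_PAIR_CLASSES = (
    "low-low",
    "moderate-low",
    "moderate-moderate",
    "high-low",
    "high-moderate",
    "high-high",
)


def prevalence_band(
    prevalence: float, thresholds: tuple[float, float] = BAND_THRESHOLDS
) -> str:
    """Classify a prevalence as low (<1%), moderate (1 to <7%) or high (>=7%)."""
    lo, hi = thresholds
    if prevalence < lo:
        return "low"
    if prevalence < hi:
        return "moderate"
    return "high"


@dataclass(frozen=True)
class Selection:
    """Edge stratum: all edges, the top fraction, or the top k."""

    kind: str  # "all" | "top_fraction" | "top_k"
    param: float | int | None = None

    def __post_init__(self) -> None:
        if self.kind == "all":
            if self.param is not None:
                raise InvalidConfigError("'all' selection takes no parameter")
        elif self.kind == "top_fraction":
            if not (self.param is not None and 0 < self.param <= 1):
                raise InvalidConfigError("top_fraction needs a fraction in (0, 1]")
        elif self.kind == "top_k":
            if not (self.param is not None and int(self.param) >= 1):
                raise InvalidConfigError("top_k needs a positive count")
        else:
            raise InvalidConfigError(f"unknown selection kind {self.kind!r}")

    def n_kept(self, m: int) -> int:
        if self.kind == "all":
            return m
        if self.kind == "top_fraction":
            return math.floor(self.param * m)
        return min(int(self.param), m)

    def label(self) -> str:
        if self.kind == "all":
            return "all"
        if self.kind == "top_fraction":
            return f"top{int(round(self.param * 100))}pct"
        return f"top{int(self.param)}"


ALL_EDGES = Selection("all")


def top_fraction(f: float) -> Selection:
    return Selection("top_fraction", f)


def top_k(k: int) -> Selection:
    return Selection("top_k", k)


@dataclass
class DiseaseNetwork:
    """Weighted undirected condition network for one measure and stratum."""

    graph: nx.Graph
    measure_name: str
    selection: Selection

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset((u, v)) for u, v in self.graph.edges())


def _ranked_records(assoc: AssociationTable, measure: str):
    # inf weights (perfect-confidence relative risk) rank above all finite
    # ones; ties broken by ascending pair label so cuts are deterministic
    return sorted(
        assoc.records,
        key=lambda r: (-r.measure(measure), r.pair),
    )


def build_network(
    assoc: AssociationTable,
    measure: str,
    selection: Selection,
    prevalence: Mapping[str, float],
    band_thresholds: tuple[float, float] = BAND_THRESHOLDS,
) -> DiseaseNetwork:
    """Assemble the weighted graph for one measure under one edge stratum.

    Records are ranked by the chosen measure (descending, label-ordered
    ties); the stratum keeps ``m`` (all), ``floor(f*m)`` (top fraction)
    or ``min(k, m)`` (top k) edges.  Node attributes carry prevalence
    and its band; edge attributes carry the weight, the pair's joint
    prevalence, and the absolute prevalence difference of its endpoints.
    """
    if measure not in MEASURES:
        raise InvalidConfigError(f"unknown measure {measure!r}")
    ranked = _ranked_records(assoc, measure)
    kept = ranked[: selection.n_kept(len(ranked))]

    g = nx.Graph()
    for r in kept:
        g.add_edge(
            r.condition_x,
            r.condition_y,
            weight=r.measure(measure),
            joint_prevalence=r.joint_prevalence,
            prevalence_difference=abs(
                prevalence[r.condition_x] - prevalence[r.condition_y]
            ),
        )
    for node in g.nodes:
        p = float(prevalence[node])
        g.nodes[node]["prevalence"] = p
        g.nodes[node]["prevalence_band"] = prevalence_band(p, band_thresholds)
    return DiseaseNetwork(graph=g, measure_name=measure, selection=selection)


def density(net: DiseaseNetwork) -> float:
    """Edges present over all possible node pairs, ``m / (v(v-1)/2)``."""
    v = net.n_nodes
    if v < 2:
        raise UndefinedDensityError("density needs at least two nodes")
    return net.n_edges / (v * (v - 1) / 2)


def degree_centrality(net: DiseaseNetwork) -> dict[str, int]:
    """Unweighted incident-edge count per node."""
    if net.n_nodes == 0:
        raise InvalidNetworkError("network is empty")
    return {node: int(deg) for node, deg in net.graph.degree()}


def top_central_nodes(net: DiseaseNetwork, k: int = 20) -> list[str]:
    """The ``min(k, v)`` nodes of highest degree; ties by label order."""
    if k < 1:
        raise InvalidConfigError("k must be >= 1")
    degrees = degree_centrality(net)
    ordered = sorted(degrees, key=lambda node: (-degrees[node], node))
    return ordered[: min(k, len(ordered))]


@dataclass
class EdgeProfile:
    """How a network's edges distribute over prevalence bands.

    Percentages of edges per unordered endpoint-band class, plus
    median/Q1/Q3 (linear-interpolation quantiles) of edge joint
    prevalence and endpoint prevalence difference, all in percent.
    """

    band_pair_percentages: dict[str, float]
    joint_prevalence_summary: tuple[float, float, float]
    prevalence_difference_summary: tuple[float, float, float]


def _summary_percent(values: np.ndarray) -> tuple[float, float, float]:
    med, q1, q3 = np.percentile(values, [50, 25, 75])
    return float(med), float(q1), float(q3)


def edge_profile(
    net: DiseaseNetwork, band_thresholds: tuple[float, float] = BAND_THRESHOLDS
) -> EdgeProfile:
    """Classify every edge by its endpoints' prevalence bands."""
    if net.n_edges == 0:
        raise InvalidNetworkError("cannot profile a network without edges")
    counts = dict.fromkeys(BAND_PAIR_CLASSES, 0)
    jp: list[float] = []
    pdiff: list[float] = []
    for u, v, attrs in net.graph.edges(data=True):
        for node in (u, v):
            if "prevalence" not in net.graph.nodes[node]:
                raise InvalidNetworkError(f"node {node!r} lacks prevalence")
        bu = prevalence_band(net.graph.nodes[u]["prevalence"], band_thresholds)
        bv = prevalence_band(net.graph.nodes[v]["prevalence"], band_thresholds)
        # unordered class name, higher band first
        hi, lo = sorted((bu, bv), key=BAND_NAMES.index, reverse=True)
        counts[f"{hi}-{lo}"] += 1
        jp.append(attrs["joint_prevalence"])
        pdiff.append(
            abs(
                net.graph.nodes[u]["prevalence"]
                - net.graph.nodes[v]["prevalence"]
            )
        )
    m = net.n_edges
    return EdgeProfile(
        band_pair_percentages={k: 100.0 * c / m for k, c in counts.items()},
        joint_prevalence_summary=_summary_percent(100.0 * np.array(jp)),
        prevalence_difference_summary=_summary_percent(100.0 * np.array(pdiff)),
    )


def _finite_weight_graph(graph: nx.Graph) -> nx.Graph:
    """Copy with inf edge weights replaced by 10x the max finite weight."""
    weights = [d.get("weight", 1.0) for _, _, d in graph.edges(data=True)]
    finite = [w for w in weights if math.isfinite(w)]
    if len(finite) == len(weights):
        return graph
    cap = (max(finite) if finite else 1.0) * 10.0
    g = graph.copy()
    for u, v, d in g.edges(data=True):
        if not math.isfinite(d.get("weight", 1.0)):
            d["weight"] = cap
    return g


def write_graphml(net: DiseaseNetwork, path: str | Path) -> None:
    nx.write_graphml(_finite_weight_graph(net.graph), str(path))


def write_gexf(net: DiseaseNetwork, path: str | Path) -> None:
    nx.write_gexf(_finite_weight_graph(net.graph), str(path))


def write_edgelist_csv(net: DiseaseNetwork, path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "source": u,
            "target": v,
            "weight": d["weight"],
            "joint_prevalence": d["joint_prevalence"],
            "prevalence_difference": d["prevalence_difference"],
        }
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    pd.DataFrame(
        rows,
        columns=[
            "source", "target", "weight", "joint_prevalence",
            "prevalence_difference",
        ],
    ).to_csv(path, index=False)
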