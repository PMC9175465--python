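"""Independent brute-force reference implementations used only by tests.

Everything here recomputes quantities from first principles (per-person
loops, pair counting, exhaustive enumeration) without touching the
package's vectorised code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def contingency_from_vectors(x, y):
    """(a, b, c, d) counted by an explicit per-person loop."""
    a = b = c = d = 0
    for xi, yi in zip(x, y):
        if xi and yi:
            a += 1
        elif xi:
            b += 1
        elif yi:
            c += 1
        else:
            d += 1
    return a, b, c, d


def measures_from_vectors(x, y):
    """All seven co-occurrence measures straight from indicator vectors."""
    a, b, c, d = contingency_from_vectors(x, y)
    n = a + b + c + d
    px, py = (a + b) / n, (a + c) / n
    pxy = a / n
    out = {
        "lift": pxy / (px * py),
        "phi": (a * d - b * c)
        / math.sqrt((a + b) * (a + c) * (b + d) * (c + d)),
        "jaccard": a / (a + b + c),
        "cosine": a / math.sqrt((a + b) * (a + c)),
        "kulczynski": (a / (a + b) + a / (a + c)) / 2,
        "joint_prevalence": pxy,
    }
    if b > 0 and c > 0:
        out["relative_risk"] = max(
            (a / (a + b)) / (c / (c + d)), (a / (a + c)) / (b / (b + d))
        )
    else:
        out["relative_risk"] = math.inf if a > 0 else 0.0
    return out


def pair_count_ari(labels1, labels2):
    """Adjusted Rand index by explicit pair enumeration."""
    n = len(labels1)
    same1 = same2 = both = 0
    for i, j in itertools.combinations(range(n), 2):
        s1 = labels1[i] == labels1[j]
        s2 = labels2[i] == labels2[j]
        same1 += s1
        same2 += s2
        both += s1 and s2
    total = n * (n - 1) // 2
    expected = same1 * same2 / total
    maximum = (same1 + same2) / 2
    if maximum == expected:
        return 1.0
    return (both - expected) / (maximum - expected)


def direct_modularity(graph, communities):
    """Weighted Newman-Girvan Q from the adjacency matrix definition."""
    nodes = list(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = w
    two_w = A.sum()
    k = A.sum(axis=1)
    label = {}
    for cid, comm in enumerate(communities):
        for v in comm:
            label[idx[v]] = cid
    q = 0.0
    for i in range(n):
        for j in range(n):
            if label[i] == label[j]:
                q += A[i, j] - k[i] * k[j] / two_w
    return q / two_w


def set_partitions(items):
    """All partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in set_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1 :]
        yield [[first]] + sub


def best_partition_exhaustive(graph):
    """Max-modularity partition by exhaustive search (small graphs only)."""
    best_q, best_p = -math.inf, None
    for parts in set_partitions(list(graph.nodes)):
        q = direct_modularity(graph, [set(p) for p in parts])
        if q > best_q:
            best_q, best_p = q, parts
    return best_q, [frozenset(p) for p in best_p]
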