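"""Pairwise condition association from 2x2 contingency tables.

Every dyad of chronic conditions is summarised by the classic two-way
table

    =============  ==========  ==========
                   y present   y absent
    =============  ==========  ==========
    x present      a           b
    x absent       c           d
    =============  ==========  ==========

with ``n = a + b + c + d`` individuals in total.  Seven co-occurrence
measures are computed from these cells: lift, relative risk (symmetrised
by taking the larger direction), the phi coefficient, Jaccard, cosine,
Kulczynski, and joint prevalence.  Jaccard, cosine and Kulczynski are
*null-invariant*: their value does not depend on the count ``d`` of
individuals with neither condition, which makes them attractive for
sparse disease-status data.

Dyads are screened before entering a network: a minimum joint frequency
(support) of ``a >= 15``, a significance test (Pearson chi-square when
all expected cell counts exceed five, Fisher's exact test otherwise) at
``alpha = 0.01``, and positivity (``phi > 0``) so that only conditions
that co-occur *more* than expected under independence are linked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError, InvalidPairError, UndefinedMeasureError
from .synthetic import CohortMatrix

MEASURE_NAMES: tuple[str, ...] = (
    "lift",
    "relative_risk",
    "phi",
    "jaccard",
    "cosine",
    "kulczynski",
    "joint_prevalence",
)

#: Measures whose value is unchanged by adding individuals with neither
#: condition (cell ``d``).
NULL_INVARIANT_MEASURES: frozenset[str] = frozenset(
    {"jaccard", "cosine", "kulczynski"}
)


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts of a 2x2 condition-pair contingency table."""

    a: int  #: both conditions
    b: int  #: x only
    c: int  #: y only
    d: int  #: neither

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            v = getattr(self, cell)
            if v < 0 or v != int(v):
                raise InvalidConfigError(f"cell {cell} must be a nonnegative count, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable":
        """The same table with the roles of x and y exchanged (b <-> c)."""
        return ContingencyTable(self.a, self.c, self.b, self.d)

    def inverted(self) -> "ContingencyTable":
        """The table after flipping presence/absence of both conditions."""
        return ContingencyTable(self.d, self.c, self.b, self.a)


def lift(t: ContingencyTable) -> float:
    """``n * a / ((a+b)(a+c))``; equals 1 under exact independence."""
    mx, my = t.a + t.b, t.a + t.c
    if mx == 0 or my == 0:
        raise UndefinedMeasureError("lift undefined: empty marginal")
    return t.n * t.a / (mx * my)


def relative_risk(t: ContingencyTable) -> float:
    """Max of the two directional relative risks.

    RR(x->y) = [a/(a+b)] / [c/(c+d)]; the measure is asymmetric, so the
    larger of the two directions is reported.  A zero denominator in one
    direction (b == 0 or c == 0 with a > 0) yields ``inf``.
    """
    mx, my = t.a + t.b, t.a + t.c
    if mx == 0 or my == 0:
        raise UndefinedMeasureError("relative risk undefined: empty marginal")
    if t.a == 0:
        return 0.0
    if t.b == 0 or t.c == 0:
        return math.inf
    rr_xy = t.a * (t.c + t.d) / (t.c * mx)
    rr_yx = t.a * (t.b + t.d) / (t.b * my)
    return max(rr_xy, rr_yx)


def phi(t: ContingencyTable) -> float:
    """Pearson phi coefficient ``(ad - bc)/sqrt((a+b)(a+c)(b+d)(c+d))``."""
    m1, m2, m3, m4 = t.a + t.b, t.a + t.c, t.b + t.d, t.c + t.d
    if min(m1, m2, m3, m4) == 0:
        raise UndefinedMeasureError("phi undefined: zero marginal")
    return (t.a * t.d - t.b * t.c) / math.sqrt(m1 * m2 * m3 * m4)


def jaccard(t: ContingencyTable) -> float:
    """``a / (a + b + c)`` — ignores cell d entirely."""
    denom = t.a + t.b + t.c
    if denom == 0:
        raise UndefinedMeasureError("jaccard undefined: a + b + c = 0")
    return t.a / denom


def cosine(t: ContingencyTable) -> float:
    """``a / sqrt((a+b)(a+c))`` — geometric mean of the two confidences."""
    mx, my = t.a + t.b, t.a + t.c
    if mx == 0 or my == 0:
        raise UndefinedMeasureError("cosine undefined: empty marginal")
    return t.a / math.sqrt(mx * my)


def kulczynski(t: ContingencyTable) -> float:
    """``(a/(a+b) + a/(a+c)) / 2`` — arithmetic mean of the two confidences."""
    mx, my = t.a + t.b, t.a + t.c
    if mx == 0 or my == 0:
        raise UndefinedMeasureError("kulczynski undefined: empty marginal")
    return 0.5 * (t.a / mx + t.a / my)


def joint_prevalence(t: ContingencyTable) -> float:
    """``a / n`` — fraction of the cohort with both conditions."""
    if t.n == 0:
        raise UndefinedMeasureError("joint prevalence undefined: n = 0")
    return t.a / t.n


MEASURES = {
    "lift": lift,
    "relative_risk": relative_risk,
    "phi": phi,
    "jaccard": jaccard,
    "cosine": cosine,
    "kulczynski": kulczynski,
    "joint_prevalence": joint_prevalence,
}


def significance_test(
    t: ContingencyTable, *, continuity_correction: bool = False
) -> tuple[float, Literal["chi_square", "fisher_exact"]]:
    """P-value for association in a 2x2 table, with the test that produced it.

    Pearson's chi-square (1 df) is used when all four expected cell
    counts strictly exceed five; otherwise Fisher's exact two-sided test.
    A degenerate table (an empty row or column) returns ``(1.0,
    "fisher_exact")``.  The continuity (Yates) correction is off by
    default but can be switched on.
    """
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=np.int64)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if t.n == 0 or row.min() == 0 or col.min() == 0:
        return 1.0, "fisher_exact"
    expected = np.outer(row, col) / t.n
    if np.all(expected > 5):
        _, p, _, _ = stats.chi2_contingency(obs, correction=continuity_correction)
        return float(p), "chi_square"
    _, p = stats.fisher_exact(obs, alternative="two-sided")
    return float(p), "fisher_exact"


def count_contingency(
    cohort: CohortMatrix, condition_x: str, condition_y: str
) -> ContingencyTable:
    """Contingency table for one condition pair, counted over all individuals."""
    if condition_x == condition_y:
        raise InvalidPairError(f"conditions must differ, got {condition_x!r} twice")
    ix = cohort.column_index(condition_x)
    iy = cohort.column_index(condition_y)
    x = cohort.column(ix)
    y = cohort.column(iy)
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = cohort.n_individuals - a - b - c
    return ContingencyTable(a, b, c, d)


@dataclass(frozen=True)
class AssociationRecord:
    """One retained dyad with its table, test result, and all seven measures."""

    condition_x: str
    condition_y: str
    table: ContingencyTable
    p_value: float
    test_used: str
    lift: float
    relative_risk: float
    phi: float
    jaccard: float
    cosine: float
    kulczynski: float
    joint_prevalence: float

    def measure(self, name: str) -> float:
        if name not in MEASURES:
            raise InvalidConfigError(f"unknown measure {name!r}")
        return getattr(self, name)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.condition_x, self.condition_y)


@dataclass
class AssociationTable:
    """All dyads surviving the support/significance/positivity filters."""

    records: list[AssociationRecord]
    n_candidates: int
    n_excluded: int
    min_support: int
    alpha: float

    def __post_init__(self) -> None:
        if len(self.records) != self.n_candidates - self.n_excluded:
            raise InvalidConfigError(
                "record count must equal n_candidates - n_excluded"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AssociationRecord]:
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "pair_x": r.condition_x,
                "pair_y": r.condition_y,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "n": r.table.n,
                "test_used": r.test_used,
                "p_value": r.p_value,
                **{m: getattr(r, m) for m in MEASURE_NAMES},
            }
            for r in self.records
        ]
        columns = [
            "pair_x", "pair_y", "a", "b", "c", "d", "n", "test_used", "p_value",
            *MEASURE_NAMES,
        ]
        return pd.DataFrame(rows, columns=columns)


def _record_from_table(
    x: str, y: str, t: ContingencyTable, p: float, test: str
) -> AssociationRecord:
    return AssociationRecord(
        condition_x=x,
        condition_y=y,
        table=t,
        p_value=p,
        test_used=test,
        lift=lift(t),
        relative_risk=relative_risk(t),
        phi=phi(t),
        jaccard=jaccard(t),
        cosine=cosine(t),
        kulczynski=kulczynski(t),
        joint_prevalence=joint_prevalence(t),
    )


def build_association_table(
    cohort: CohortMatrix,
    min_support: int = 15,
    alpha: float = 0.01,
    *,
    continuity_correction: bool = False,
) -> AssociationTable:
    """Screen every condition dyad and compute the seven measures.

    Candidates are unordered pairs with joint frequency ``a >=
    min_support``; a candidate is retained iff its significance test
    gives ``p < alpha`` *and* ``phi > 0``.  Records come back sorted by
    (condition_x, condition_y) label, with x < y within each pair.
    """
    if min_support < 1:
        raise InvalidConfigError(f"min_support must be >= 1, got {min_support}")
    if not (0.0 < alpha < 1.0):
        raise InvalidConfigError(f"alpha must lie in (0, 1), got {alpha}")
    if cohort.n_individuals == 0:
        raise InvalidConfigError("cohort has no individuals")

    X = cohort.incidence.tocsc().astype(np.int64)
    joint = (X.T @ X).toarray()  # joint[i, j] = a for pair (i, j)
    margin = np.asarray(X.sum(axis=0)).ravel()
    n = cohort.n_individuals
    labels = cohort.condition_labels

    # lexicographic output order over label pairs
    order = sorted(range(len(labels)), key=lambda i: labels[i])

    records: list[AssociationRecord] = []
    n_candidates = 0
    for pos, i in enumerate(order):
        for j in order[pos + 1 :]:
            a = int(joint[i, j])
            if a < min_support:
                continue
            n_candidates += 1
            b = int(margin[i]) - a
            c = int(margin[j]) - a
            t = ContingencyTable(a, b, c, n - a - b - c)
            p, test = significance_test(
                t, continuity_correction=continuity_correction
            )
            if not (p < alpha):
                continue
            try:
                if phi(t) <= 0:
                    continue
            except UndefinedMeasureError:
                continue
            records.append(_record_from_table(labels[i], labels[j], t, p, test))

    return AssociationTable(
        records=records,
        n_candidates=n_candidates,
        n_excluded=n_candidates - len(records),
        min_support=min_support,
        alpha=alpha,
    )
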