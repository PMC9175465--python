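"""Contingency counting, the seven measures, and the screening filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import comorbnet as cn
from comorbnet.errors import (
    InvalidConfigError,
    InvalidPairError,
    UndefinedMeasureError,
)

from _oracles import contingency_from_vectors, measures_from_vectors
from conftest import make_cohort

T = cn.ContingencyTable

# strictly positive cells so every measure is defined
tables = st.builds(
    T,
    a=st.integers(1, 400),
    b=st.integers(1, 400),
    c=st.integers(1, 400),
    d=st.integers(1, 400),
)


class TestContingency:
    def test_direct_count(self):
        cohort = make_cohort([[1, 1], [1, 0], [0, 0]], labels=["x", "y"])
        t = cn.count_contingency(cohort, "x", "y")
        assert (t.a, t.b, t.c, t.d, t.n) == (1, 1, 0, 1, 3)

    def test_matches_per_person_loop_on_all_pairs(self):
        rng = np.random.default_rng(7)
        mat = (rng.random((500, 8)) < 0.25).astype(int)
        cohort = make_cohort(mat)
        for i in range(8):
            for j in range(i + 1, 8):
                t = cn.count_contingency(
                    cohort, cohort.condition_labels[i], cohort.condition_labels[j]
                )
                assert (t.a, t.b, t.c, t.d) == contingency_from_vectors(
                    mat[:, i], mat[:, j]
                )

    def test_same_condition_rejected(self):
        cohort = make_cohort([[1, 1], [0, 1]], labels=["x", "y"])
        with pytest.raises(InvalidPairError):
            cn.count_contingency(cohort, "x", "x")

    def test_unknown_label_rejected(self):
        cohort = make_cohort([[1, 1]], labels=["x", "y"])
        with pytest.raises(KeyError):
            cn.count_contingency(cohort, "x", "z")

    @given(tables)
    def test_cells_partition_cohort(self, t):
        assert t.a + t.b + t.c + t.d == t.n


@pytest.mark.parametrize(
    "measure, table, expected",
    [
        # exact independence point
        (cn.lift, T(10, 10, 40, 40), 1.0),
        (cn.relative_risk, T(10, 10, 40, 40), 1.0),
        (cn.phi, T(10, 10, 40, 40), 0.0),
        # perfect association
        (cn.lift, T(20, 0, 0, 80), 5.0),
        (cn.phi, T(20, 0, 0, 80), 1.0),
        (cn.jaccard, T(20, 0, 0, 80), 1.0),
        (cn.cosine, T(20, 0, 0, 80), 1.0),
        (cn.kulczynski, T(20, 0, 0, 80), 1.0),
        # hand-computed worked example
        (cn.lift, T(15, 5, 10, 70), 3.0),
        (cn.relative_risk, T(15, 5, 10, 70), 9.0),
        (cn.phi, T(15, 5, 10, 70), 1000 / math.sqrt(3_000_000)),
        (cn.jaccard, T(15, 5, 10, 70), 0.5),
        (cn.cosine, T(15, 5, 10, 70), 15 / math.sqrt(500)),
        (cn.kulczynski, T(15, 5, 10, 70), 0.675),
        (cn.joint_prevalence, T(15, 5, 10, 70), 0.15),
        # null-invariance: only d differs from the worked example
        (cn.jaccard, T(15, 5, 10, 700), 0.5),
        (cn.kulczynski, T(15, 5, 10, 9999), 0.675),
        (cn.joint_prevalence, T(0, 5, 5, 90), 0.0),
        (cn.joint_prevalence, T(42, 0, 0, 0), 1.0),
    ],
)
def test_measure_worked_examples(measure, table, expected):
    assert measure(table) == pytest.approx(expected, rel=1e-12)


def test_relative_risk_infinite_when_one_direction_has_zero_denominator():
    assert cn.relative_risk(T(20, 0, 0, 80)) == math.inf
    assert cn.relative_risk(T(15, 0, 10, 75)) == math.inf


def test_measures_undefined_on_empty_marginals():
    empty_x = T(0, 0, 10, 90)
    for measure in (cn.lift, cn.relative_risk, cn.phi, cn.cosine, cn.kulczynski):
        with pytest.raises(UndefinedMeasureError):
            measure(empty_x)
    with pytest.raises(UndefinedMeasureError):
        cn.jaccard(T(0, 0, 0, 10))


class TestMeasureProperties:
    """Algebraic identities that hold on every valid table."""

    @given(tables)
    def test_null_invariance_taxonomy(self, t):
        shifted = T(t.a, t.b, t.c, t.d + 57)
        for name in ("jaccard", "cosine", "kulczynski"):
            assert getattr(cn, name)(t) == getattr(cn, name)(shifted)
        # the remaining four are all sensitive to d (bc > 0 here)
        assert cn.lift(t) != pytest.approx(cn.lift(shifted), rel=1e-12)
        assert cn.phi(t) != pytest.approx(cn.phi(shifted), rel=1e-12)
        assert cn.joint_prevalence(t) != pytest.approx(
            cn.joint_prevalence(shifted), rel=1e-12
        )

    @given(tables)
    def test_phi_inversion_invariant_jaccard_not(self, t):
        assert cn.phi(t) == pytest.approx(cn.phi(t.inverted()), abs=1e-15)
        if t.a != t.d:
            assert cn.jaccard(t) != pytest.approx(cn.jaccard(t.inverted()), rel=1e-9)

    @given(tables)
    def test_symmetry_in_x_and_y(self, t):
        for name in cn.MEASURE_NAMES:
            assert getattr(cn, name)(t) == pytest.approx(
                getattr(cn, name)(t.swapped()), rel=1e-12
            )

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50))
    def test_independence_point(self, i, j, k):
        # a/b = c/d ensures ad = bc
        t = T(i * j, i * k, j * 7, k * 7)
        assert cn.lift(t) == pytest.approx(1.0, rel=1e-12)
        assert cn.relative_risk(t) == pytest.approx(1.0, rel=1e-12)
        assert cn.phi(t) == pytest.approx(0.0, abs=1e-12)

    @given(tables)
    def test_confidence_mean_ordering(self, t):
        assert cn.kulczynski(t) >= cn.cosine(t) - 1e-12
        assert cn.cosine(t) >= cn.jaccard(t) - 1e-12

    @given(tables)
    def test_cosine_squared_identity(self, t):
        assert cn.cosine(t) ** 2 == pytest.approx(
            cn.lift(t) * cn.joint_prevalence(t), rel=1e-12
        )

    @given(tables)
    def test_chi_square_equals_n_phi_squared(self, t):
        from scipy.stats import chi2_contingency

        stat, _, _, _ = chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=False
        )
        assert stat == pytest.approx(t.n * cn.phi(t) ** 2, rel=1e-9)

    @settings(max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_from_indicator_vectors(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(300) < 0.4
        y = (rng.random(300) < 0.5) | x & (rng.random(300) < 0.3)
        if not 0 < x.sum() < 300 or not 0 < y.sum() < 300:
            return
        a, b, c, d = contingency_from_vectors(x, y)
        t = T(a, b, c, d)
        expected = measures_from_vectors(x, y)
        for name in cn.MEASURE_NAMES:
            got = getattr(cn, name)(t)
            if math.isinf(expected[name]):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(expected[name], rel=1e-12)


class TestSignificance:
    def test_chi_square_branch_statistic(self):
        # all expected counts are 25 > 5; statistic = n*phi^2 = 4.0
        t = T(30, 20, 20, 30)
        p, test = cn.significance_test(t)
        assert test == "chi_square"
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(4.0, df=1), rel=1e-12)

    @pytest.mark.parametrize(
        "table",
        [T(3, 2, 2, 93), T(15, 5, 10, 70)],  # E[a]=0.25 and E[a]=5 exactly
    )
    def test_fisher_branch_when_expected_not_above_five(self, table):
        _, test = cn.significance_test(table)
        assert test == "fisher_exact"

    def test_degenerate_table_gives_p_one(self):
        assert cn.significance_test(T(0, 0, 10, 90)) == (1.0, "fisher_exact")


class TestAssociationTable:
    def test_identical_columns_retained_with_jaccard_one(self):
        rng = np.random.default_rng(3)
        col = (rng.random(200) < 0.2).astype(int)
        other = (rng.random(200) < 0.3).astype(int)
        cohort = make_cohort(
            np.column_stack([col, col, other]), labels=["dup1", "dup2", "other"]
        )
        table = cn.build_association_table(cohort, min_support=15, alpha=0.01)
        by_pair = {r.pair: r for r in table}
        assert ("dup1", "dup2") in by_pair
        assert by_pair[("dup1", "dup2")].jaccard == 1.0

    def test_accounting_identity_and_ordering(self, random_cohort):
        table = cn.build_association_table(random_cohort, min_support=5, alpha=0.5)
        assert len(table) == table.n_candidates - table.n_excluded
        pairs = [r.pair for r in table]
        assert pairs == sorted(pairs)
        assert all(r.condition_x < r.condition_y for r in table)
        assert all(r.table.a >= 5 and r.p_value < 0.5 and r.phi > 0 for r in table)

    def test_invalid_filter_params_rejected(self, random_cohort):
        with pytest.raises(InvalidConfigError):
            cn.build_association_table(random_cohort, min_support=0)
        with pytest.raises(InvalidConfigError):
            cn.build_association_table(random_cohort, alpha=1.1)

    def test_type_one_error_controlled_on_independent_cohort(self):
        # no planted structure: few dyads should survive the p < 0.01
        # + positivity screen (tested across 3 seeds downstream too)
        cfg = cn.SyntheticConfig.from_targets(
            [0.05] * 20,
            n_individuals=20000,
            n_blocks=1,
            block_effect=0.0,
            block_activation_prob=0.0,
            seed=5,
            restrict_multimorbid=False,
        )
        cohort = cn.generate_cohort(cfg)
        table = cn.build_association_table(cohort)
        assert table.n_candidates > 0
        assert len(table) / table.n_candidates <= 0.02
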