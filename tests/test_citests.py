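"""Independence tests against independent hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from engagenet import (MISSING, anova_oneway, contingency, g2_test, spearman,
                       x2_test)
from engagenet.citests import (ContingencyTable, TestError, g2_statistic,
                               x2_statistic)
from engagenet.metadata import VariableMeta


def ct(counts, z=()):
    counts = np.asarray(counts)
    if counts.ndim == 2:
        counts = counts[None]
    kx, ky = counts.shape[1], counts.shape[2]
    return ContingencyTable(
        counts=counts, x="x", y="y", z=tuple(z),
        x_levels=tuple(f"x{i}" for i in range(kx)),
        y_levels=tuple(f"y{i}" for i in range(ky)),
    )


def g2_oracle(counts):
    """2 Σ O ln(O/E) with E = row·col/N, summed per stratum."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 2:
        counts = counts[None]
    total = 0.0
    for stratum in counts:
        n = stratum.sum()
        for i in range(stratum.shape[0]):
            for j in range(stratum.shape[1]):
                o = stratum[i, j]
                if o > 0:
                    e = stratum[i].sum() * stratum[:, j].sum() / n
                    total += 2 * o * np.log(o / e)
    return total


def entropy_mi_oracle(counts):
    """Conditional MI via H(X|Z)+H(Y|Z)-H(X,Y|Z), in nats."""

    def entropy(p):
        p = p[p > 0]
        return -(p * np.log(p)).sum()

    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    mi = 0.0
    for stratum in counts:
        nz = stratum.sum()
        if nz == 0:
            continue
        p = stratum / nz
        mi += (nz / n) * (
            entropy(p.sum(axis=1)) + entropy(p.sum(axis=0)) - entropy(p.ravel())
        )
    return mi


class TestG2:
    def test_two_by_two_frozen_value(self):
        res = g2_test(ct([[10, 20], [30, 40]]))
        assert res.statistic == pytest.approx(0.80435, abs=1e-4)
        assert res.df == 1
        assert res.statistic == pytest.approx(g2_oracle([[10, 20], [30, 40]]))

    def test_proportional_table_is_exactly_zero(self):
        assert g2_test(ct([[10, 20], [20, 40]])).statistic == 0.0

    def test_matches_hand_oracle_on_random_tables(self, rng=None):
        rng = np.random.default_rng(42)
        from .conftest import random_counts

        for _ in range(20):
            counts = random_counts(rng, rng.integers(2, 4), rng.integers(2, 4),
                                   rng.integers(1, 4))
            assert g2_statistic(counts) == pytest.approx(
                g2_oracle(counts), abs=1e-10)

    def test_equals_2n_times_mutual_information(self):
        rng = np.random.default_rng(7)
        from .conftest import random_counts

        for _ in range(20):
            counts = random_counts(rng, 3, 2, rng.integers(1, 4), n=600)
            n = counts.sum()
            assert g2_statistic(counts) == pytest.approx(
                2 * n * entropy_mi_oracle(counts), abs=1e-10)

    def test_rejects_all_zero_and_degenerate(self):
        with pytest.raises(TestError):
            g2_test(ct(np.zeros((2, 2), dtype=int)))
        with pytest.raises(TestError):
            g2_test(ct(np.ones((1, 3), dtype=int)))


class TestX2:
    def test_two_by_two_frozen_value(self):
        res = x2_test(ct([[10, 20], [30, 40]]))
        assert res.statistic == pytest.approx(0.7937, abs=1e-4)
        assert res.df == 1

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(3)
        from .conftest import random_counts

        for _ in range(10):
            counts = random_counts(rng, 3, 3, 1, n=900)[0]
            expected = sps.chi2_contingency(counts, correction=False)
            res = x2_test(ct(counts))
            assert res.statistic == pytest.approx(expected.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(expected.pvalue, abs=1e-12)

    def test_exact_independence_gives_zero(self):
        assert x2_test(ct([[10, 20], [20, 40]])).statistic == 0.0


class TestStatisticProperties:
    def test_invariant_to_label_permutation(self):
        rng = np.random.default_rng(11)
        from .conftest import random_counts

        counts = random_counts(rng, 3, 4, 2, n=800)
        perm_x = rng.permutation(3)
        perm_y = rng.permutation(4)
        shuffled = counts[:, perm_x][:, :, perm_y]
        assert g2_statistic(shuffled) == pytest.approx(g2_statistic(counts))
        assert x2_statistic(shuffled) == pytest.approx(x2_statistic(counts))

    def test_additive_over_strata(self):
        rng = np.random.default_rng(13)
        from .conftest import random_counts

        counts = random_counts(rng, 2, 3, 4, n=900)
        for stat in (g2_statistic, x2_statistic):
            total = stat(counts)
            parts = sum(stat(counts[z][None]) for z in range(4))
            assert total == pytest.approx(parts, abs=1e-10)


class TestContingency:
    def test_unit_table(self):
        table = pd.DataFrame({
            "x": ["Yes", "Yes", "No", "No"],
            "y": ["Yes", "No", "Yes", "No"],
        })
        out = contingency(table, "x", "y")
        assert out.counts.shape == (1, 2, 2)
        assert (out.counts == 1).all()

    def test_sentinel_rows_deleted(self):
        table = pd.DataFrame({
            "x": ["Yes", MISSING, "No"],
            "y": ["Yes", "Yes", "No"],
        })
        out = contingency(table, "x", "y")
        assert out.n_used == 2

    def test_conditioning_shape_with_explicit_zeros(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame({
            "x": rng.choice(["a", "b"], 50),
            "y": rng.choice(["a", "b"], 50),
            "z1": rng.choice(["a", "b"], 50),
            "z2": rng.choice(["a", "b"], 50),
        })
        out = contingency(table, "x", "y", ["z1", "z2"])
        assert out.counts.shape == (4, 2, 2)
        assert out.counts.sum() == 50


class TestSpearman:
    @pytest.fixture
    def meta(self):
        return [
            VariableMeta(name="x", levels=("a", "b", "c", "d"), ordinal=True),
            VariableMeta(name="y", levels=("p", "q", "r", "s"), ordinal=True),
        ]

    def test_monotone_perfect_correlation(self, meta):
        table = pd.DataFrame({"x": list("abcd"), "y": list("pqrs")})
        assert spearman(table, "x", "y", meta).statistic == pytest.approx(1.0)
        rev = pd.DataFrame({"x": list("abcd"), "y": list("srqp")})
        assert spearman(rev, "x", "y", meta).statistic == pytest.approx(-1.0)

    def test_matches_midrank_oracle_with_ties(self, meta):
        rng = np.random.default_rng(17)
        for _ in range(10):
            xs = rng.integers(0, 4, 20)
            ys = rng.integers(0, 4, 20)
            if len(set(xs)) < 2 or len(set(ys)) < 2:
                continue
            table = pd.DataFrame({
                "x": np.array(list("abcd"))[xs], "y": np.array(list("pqrs"))[ys],
            })
            res = spearman(table, "x", "y", meta)
            rx = sps.rankdata(xs)
            ry = sps.rankdata(ys)
            rho = np.corrcoef(rx, ry)[0, 1]
            assert res.statistic == pytest.approx(rho, abs=1e-12)

    def test_zero_variance_rejected(self, meta):
        table = pd.DataFrame({"x": ["a"] * 5, "y": list("pqrsp")})
        with pytest.raises(TestError):
            spearman(table, "x", "y", meta)


class TestAnova:
    def test_equal_means_give_small_f(self):
        rng = np.random.default_rng(23)
        values = rng.normal(size=300)
        groups = np.repeat(["a", "b", "c"], 100)
        res = anova_oneway(values, groups)
        assert res.p_value > 0.001

    def test_two_groups_equal_squared_t(self):
        values = np.array([1.0, 2, 3, 4, 5, 2, 4, 6, 8, 10])
        groups = np.array(["a"] * 5 + ["b"] * 5)
        res = anova_oneway(values, groups)
        t, p = sps.ttest_ind(values[:5], values[5:])
        assert res.statistic == pytest.approx(t ** 2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_power_under_planted_shift(self):
        rng = np.random.default_rng(29)
        hits = 0
        for _ in range(200):
            a = rng.normal(0, 1, 100)
            b = rng.normal(1, 1, 100)
            c = rng.normal(0, 1, 100)
            values = np.concatenate([a, b, c])
            groups = np.repeat(["a", "b", "c"], 100)
            hits += anova_oneway(values, groups).p_value < 0.05
        assert hits >= 198

    def test_zero_within_variance_reports_infinite_f(self):
        values = np.array([1.0, 1, 2, 2])
        groups = np.array(["a", "a", "b", "b"])
        res = anova_oneway(values, groups)
        assert np.isinf(res.statistic)
        assert res.p_value == 0.0
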