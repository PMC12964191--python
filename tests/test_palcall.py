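import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palnn.palcall import (
    MASMatrix,
    aggregate,
    block_clump_distance,
    clump_cross_model,
    percentile_threshold,
)

from .conftest import make_genotypes


def random_mas_matrix(rng, m, L):
    raw = rng.random((m, L)) + 1e-6
    return MASMatrix(A=raw / raw.sum(axis=1, keepdims=True))


def brute_force_report(A, q):
    """Independent enumeration of mu/theta/w/AMAS/PAL straight from the definitions."""
    m, L = A.shape
    mu = np.array([sum(A[a][j] for a in range(m)) / m for j in range(L)])
    k_above = math.floor(L * (1 - q / 100.0))
    theta = sorted(mu, reverse=True)[k_above]
    w = np.array([sum(1 for a in range(m) if A[a][j] > theta) / m for j in range(L)])
    amas = {j: w[j] * mu[j] for j in range(L) if mu[j] > theta}
    pal_amas = {j for j, v in amas.items() if v > theta}
    pal_common = {j for j in range(L) if all(A[a][j] > theta for a in range(m))}
    return mu, theta, w, amas, pal_amas, pal_common


class TestPercentileThreshold:
    def test_290522_strict_leaves_29(self):
        values = np.random.default_rng(0).permutation(np.arange(290_522) + 0.5)
        theta = percentile_threshold(values, 99.99)
        assert int((values > theta).sum()) == 29

    def test_290522_relaxed_leaves_145(self):
        values = np.random.default_rng(1).permutation(np.arange(290_522) + 0.5)
        theta = percentile_threshold(values, 99.95)
        assert int((values > theta).sum()) == 145

    def test_n100_q99_leaves_1(self):
        values = np.arange(100.0)
        theta = percentile_threshold(values, 99.0)
        assert int((values > theta).sum()) == 1

    @pytest.mark.parametrize("q", [0.0, 100.0, -3.0, 101.0])
    def test_invalid_percentile(self, q):
        with pytest.raises(ValueError):
            percentile_threshold(np.arange(10.0), q)

    @given(
        n=st.integers(2, 500),
        q=st.floats(50.0, 99.99),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_count_above(self, n, q, seed):
        values = np.random.default_rng(seed).permutation(np.arange(n) + 0.0)
        theta = percentile_threshold(values, q)
        assert int((values > theta).sum()) == math.floor(n * (1 - q / 100.0))


class TestAggregate:
    def test_weight_is_exceedance_fraction(self):
        rng = np.random.default_rng(3)
        A = random_mas_matrix(rng, 10, 50)
        report = aggregate(A, q=98.0)
        exceed = A.A > report.theta
        assert np.allclose(report.weights, exceed.sum(axis=0) / 10)

    def test_full_weight_gives_amas_equal_mu(self):
        # position 0 dominates every row -> w = 1 and AMAS = mu there
        base = np.full((3, 10), 0.05)
        base[:, 0] = 0.55
        report = aggregate(MASMatrix(A=base), q=85.0)
        assert report.weights[0] == 1.0
        assert report.amas[0] == pytest.approx(report.mu[0])

    def test_toy_matrix_matches_brute_force(self):
        rng = np.random.default_rng(7)
        A = random_mas_matrix(rng, 3, 5)
        q = 75.0
        report = aggregate(A, q)
        mu, theta, w, amas, pal_amas, pal_common = brute_force_report(A.A, q)
        assert np.allclose(report.mu, mu)
        assert report.theta == pytest.approx(theta)
        assert np.allclose(report.weights, w)
        assert report.pal_amas == pal_amas
        assert report.pal_common == pal_common

    @given(
        m=st.integers(1, 8),
        L=st.integers(3, 40),
        seed=st.integers(0, 10_000),
        q=st.floats(60.0, 99.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_subset_law_and_amas_bound(self, m, L, seed, q):
        A = random_mas_matrix(np.random.default_rng(seed), m, L)
        report = aggregate(A, q)
        assert report.pal_common <= report.pal_amas
        amas_full = report.weights * report.mu
        assert np.all(amas_full <= report.mu + 1e-15)
        eq = np.isclose(amas_full, report.mu) & (report.mu > 0)
        assert np.all(report.weights[eq] == 1.0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        A = random_mas_matrix(rng, 4, 20)
        r1 = aggregate(A, q=90.0)
        r2 = aggregate(MASMatrix(A=A.A[::-1]), q=90.0)
        assert np.allclose(r1.mu, r2.mu)
        assert r1.pal_amas == r2.pal_amas

    def test_position_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        A = random_mas_matrix(rng, 4, 20)
        perm = rng.permutation(20)
        r1 = aggregate(A, q=90.0)
        r2 = aggregate(MASMatrix(A=A.A[:, perm]), q=90.0)
        assert {int(perm[j]) for j in r2.pal_amas} == set() or (
            r1.pal_amas == {int(np.flatnonzero(perm == j)[0]) for j in r2.pal_amas}
        )
        assert np.allclose(np.sort(r1.mu), np.sort(r2.mu))

    def test_m1_collapses_sets(self):
        rng = np.random.default_rng(8)
        A = random_mas_matrix(rng, 1, 30)
        report = aggregate(A, q=90.0)
        expected = set(np.flatnonzero(A.A[0] > report.theta).tolist())
        assert report.pal_amas == report.pal_common == expected

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            MASMatrix(A=np.array([[0.5, 0.6]]))


class TestClumpCrossModel:
    def _correlated_genotypes(self):
        rng = np.random.default_rng(2)
        a = rng.choice([-1, 0, 1], size=500)
        b = a.copy()
        b[:140] = rng.choice([-1, 0, 1], size=140)  # |r| ~ 0.7 with a
        c = a.copy()
        c[:350] = rng.choice([-1, 0, 1], size=350)  # |r| ~ 0.3 with a
        d = rng.choice([-1, 0, 1], size=500)
        return make_genotypes(np.stack([a, b, c, d], axis=1))

    def test_high_ld_merges(self):
        g = self._correlated_genotypes()
        signals = clump_cross_model([{0}, {1}], g, r_threshold=0.5)
        assert len(signals) == 1
        assert signals[0]["members"] == [0, 1]

    def test_low_ld_stays_separate(self):
        g = self._correlated_genotypes()
        signals = clump_cross_model([{0}, {3}], g, r_threshold=0.5)
        assert len(signals) == 2

    def test_transitive_closure(self):
        rng = np.random.default_rng(4)
        a = rng.choice([-1, 0, 1], size=2000)
        b = a.copy()
        b[:800] = rng.choice([-1, 0, 1], size=800)   # r(a,b) ~ 0.6
        c = b.copy()
        c[1200:] = rng.choice([-1, 0, 1], size=800)  # r(b,c) ~ 0.6, r(a,c) ~ 0.35
        g = make_genotypes(np.stack([a, b, c], axis=1))
        from palnn.genotypes import compute_ld

        assert abs(compute_ld(g, 0, 1)) > 0.5
        assert abs(compute_ld(g, 1, 2)) > 0.5
        assert abs(compute_ld(g, 0, 2)) < 0.5
        signals = clump_cross_model([{0}, {1}, {2}], g, r_threshold=0.5)
        assert len(signals) == 1 and signals[0]["members"] == [0, 1, 2]

    def test_representative_is_highest_amas(self):
        g = self._correlated_genotypes()
        signals = clump_cross_model([{0, 1}], g, amas={0: 0.1, 1: 0.9})
        assert signals[0]["representative"] == 1


class TestBlockClump:
    def _variants(self, bps, chroms=None):
        n = len(bps)
        return pd.DataFrame(
            {
                "chrom": chroms or ["1"] * n,
                "bp": bps,
                "id": [f"v{i}" for i in range(n)],
            }
        )

    def test_within_gap_one_block(self):
        v = self._variants([1_000_000, 1_050_000])
        assert block_clump_distance([0, 1], v) == [[0, 1]]

    def test_beyond_gap_two_blocks(self):
        v = self._variants([1_000_000, 1_150_001])
        assert block_clump_distance([0, 1], v) == [[0], [1]]

    def test_chromosome_change_splits(self):
        v = self._variants([1_000_000, 1_000_500], chroms=["1", "2"])
        assert block_clump_distance([0, 1], v) == [[0], [1]]

    def test_empty(self):
        assert block_clump_distance([], self._variants([100])) == []


def test_plot_manhattan_writes_image(tmp_path):
    pytest.importorskip("matplotlib")
    from palnn.palcall import plot_manhattan

    rng = np.random.default_rng(9)
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * 30 + ["2"] * 30,
            "bp": list(range(1, 31)) + list(range(1, 31)),
            "id": [f"v{i}" for i in range(60)],
        }
    )
    out = tmp_path / "manhattan.png"
    plot_manhattan(rng.random(60), variants, out,
                   thresholds={"strict": 0.9}, highlight={5, 40})
    assert out.stat().st_size > 0
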