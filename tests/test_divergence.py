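"""Divergence statistics and Wilcoxon signed-rank tests."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps

from barcodeval.divergence import (
    STATISTIC_ROWS,
    divergence_summary,
    paired_distances,
    rank_markers,
    wilcoxon_signed_rank,
)
from barcodeval.site_stats import UndefinedValueError

from .conftest import make_dm


def brute_force_summary(values, species):
    """Naive double-loop recomputation of all six statistics."""
    n = len(species)
    inter, intra = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (inter, intra)[species[i] == species[j]].append(values[i][j])
    per_sp = {}
    for sp in sorted(set(species)):
        mine = [i for i in range(n) if species[i] == sp]
        others = [i for i in range(n) if species[i] != sp]
        hetero = [values[i][j] for i in mine for j in others]
        within = [values[i][j] for i, j in itertools.combinations(mine, 2)]
        per_sp[sp] = (hetero, within)
    tp = [np.mean(h) for h, _ in per_sp.values() if h]
    mi = [np.min(h) for h, _ in per_sp.values() if h]
    th = [np.mean(w) for _, w in per_sp.values() if w]
    cd = [np.max(w) for _, w in per_sp.values() if w]
    mean = lambda xs: float(np.mean(xs)) if len(xs) else math.nan
    return {
        "all_interspecific_distance": mean(inter),
        "theta_prime": mean(tp),
        "minimum_interspecific_distance": mean(mi),
        "all_intraspecific_distance": mean(intra),
        "theta": mean(th),
        "coalescent_depth": mean(cd),
    }


def random_labelled_matrix(rng, n, n_species):
    v = rng.random((n, n)) * 0.2
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    species = [f"sp{rng.integers(n_species)}" for _ in range(n)]
    return make_dm(v, species)


class TestDivergenceSummary:
    def test_two_species_forced_values(self):
        # 2 species x 2 samples: all intra 0.01, all inter 0.05
        v = np.full((4, 4), 0.05)
        v[0, 1] = v[1, 0] = v[2, 3] = v[3, 2] = 0.01
        np.fill_diagonal(v, 0)
        s = divergence_summary(make_dm(v, ["a", "a", "b", "b"]))
        assert s.all_interspecific_distance.mean == pytest.approx(0.05)
        assert s.theta_prime.mean == pytest.approx(0.05)
        assert s.minimum_interspecific_distance.mean == pytest.approx(0.05)
        assert s.all_intraspecific_distance.mean == pytest.approx(0.01)
        assert s.theta.mean == pytest.approx(0.01)
        assert s.coalescent_depth.mean == pytest.approx(0.01)

    def test_single_species_interspecific_undefined(self):
        v = np.array([[0, 0.01, 0.02], [0.01, 0, 0.03], [0.02, 0.03, 0]])
        s = divergence_summary(make_dm(v, ["a", "a", "a"]))
        assert s.theta.mean == pytest.approx(0.02)
        assert s.coalescent_depth.mean == pytest.approx(0.03)
        assert math.isnan(s.all_interspecific_distance.mean)
        assert math.isnan(s.theta_prime.mean)

    def test_matches_loop_recomputation(self, rng):
        for _ in range(200):
            dm = random_labelled_matrix(rng, int(rng.integers(4, 10)), 3)
            got = divergence_summary(dm)
            exp = brute_force_summary(dm.values.tolist(), dm.species)
            for row in STATISTIC_ROWS:
                g, e = got.as_dict()[row], exp[row]
                if math.isnan(e):
                    assert math.isnan(g)
                else:
                    assert g == pytest.approx(e, abs=1e-12)

    def test_theta_prime_per_species_pair_convention(self):
        # species a (2 samples), b (1): cross distances 0.02, 0.04; c (1):
        # a-c 0.10, 0.12, b-c 0.30
        v = np.array([
            [0.00, 0.01, 0.02, 0.10],
            [0.01, 0.00, 0.04, 0.12],
            [0.02, 0.04, 0.00, 0.30],
            [0.10, 0.12, 0.30, 0.00],
        ])
        dm = make_dm(v, ["a", "a", "b", "c"])
        per_pair = divergence_summary(dm, theta_prime="per_species_pair")
        # pair means: a-b = 0.03, a-c = 0.11, b-c = 0.30
        assert per_pair.theta_prime.mean == pytest.approx(
            (0.03 + 0.11 + 0.30) / 3
        )
        per_species = divergence_summary(dm)
        # a: mean(0.02,0.04,0.10,0.12); b: mean(0.02,0.04,0.30); c: mean(...)
        assert per_species.theta_prime.mean == pytest.approx(
            np.mean([np.mean([0.02, 0.04, 0.10, 0.12]),
                     np.mean([0.02, 0.04, 0.30]),
                     np.mean([0.10, 0.12, 0.30])])
        )
        with pytest.raises(ValueError):
            divergence_summary(dm, theta_prime="nope")

    def test_scaling_property(self, rng):
        dm = random_labelled_matrix(rng, 8, 3)
        scaled = make_dm(dm.values * 3.5, dm.species)
        a, b = divergence_summary(dm), divergence_summary(scaled)
        for row in STATISTIC_ROWS:
            x, y = a.as_dict()[row], b.as_dict()[row]
            if not math.isnan(x):
                assert y == pytest.approx(3.5 * x)

    def test_theta_never_exceeds_coalescent_depth(self, rng):
        for _ in range(50):
            dm = random_labelled_matrix(rng, 8, 2)
            s = divergence_summary(dm)
            if not math.isnan(s.theta.mean):
                assert s.theta.mean <= s.coalescent_depth.mean + 1e-12


class TestWilcoxon:
    def test_all_positive_three(self):
        r = wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert r.W == 6
        assert r.p_value == pytest.approx(0.25)
        assert r.method == "exact"

    def test_symmetric_diffs_give_p_one(self):
        r = wilcoxon_signed_rank([1.0, -1.0], [0.0, 0.0])
        assert r.p_value == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        r = wilcoxon_signed_rank([1.0, 2.0, 5.0, 5.0], [1.0, 2.0, 0.0, 1.0])
        assert r.n_pairs == 2

    def test_all_zero_raises(self):
        with pytest.raises(UndefinedValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_exact_matches_full_enumeration(self, rng):
        """DP tail equals literal enumeration of all 2^n sign assignments."""
        for _ in range(100):
            n = int(rng.integers(3, 13))
            diffs = np.round(rng.normal(size=n), 2)
            diffs = diffs[diffs != 0]
            if diffs.size == 0:
                continue
            r = wilcoxon_signed_rank(diffs, np.zeros_like(diffs))
            ranks = sps.rankdata(np.abs(diffs))
            total = ranks.sum()
            dev = abs(r.W - total / 2)
            count = 0
            for signs in itertools.product([0, 1], repeat=diffs.size):
                w = sum(rk for s, rk in zip(signs, ranks) if s)
                if abs(w - total / 2) >= dev - 1e-9:
                    count += 1
            assert r.p_value == pytest.approx(count / 2 ** diffs.size,
                                              abs=1e-12)

    def test_matches_scipy_without_ties(self, rng):
        diffs = rng.normal(size=15)
        r = wilcoxon_signed_rank(diffs, np.zeros_like(diffs))
        ref = sps.wilcoxon(diffs, alternative="two-sided", method="exact")
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_near_exact_at_boundary(self, rng):
        # n = 25 is served exactly; compare the approximation on the same data
        from barcodeval import divergence as dv

        diffs = rng.normal(size=25)
        exact = wilcoxon_signed_rank(diffs, np.zeros_like(diffs))
        assert exact.method == "exact"
        old = dv.EXACT_N_MAX
        try:
            dv.EXACT_N_MAX = 24
            approx = wilcoxon_signed_rank(diffs, np.zeros_like(diffs))
        finally:
            dv.EXACT_N_MAX = old
        assert approx.method == "normal_approximation"
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.01)

    def test_scale_invariance_of_p(self, rng):
        x = rng.random(12)
        y = rng.random(12)
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(7.0 * x, 7.0 * y)
        assert a.p_value == b.p_value
        assert a.W == b.W


class TestPairingAndRanking:
    def test_paired_distances_intersection(self):
        import pandas as pd

        a = pd.DataFrame({
            "sample_i": ["s1", "s1"], "sample_j": ["s2", "s3"],
            "species_i": ["x", "x"], "species_j": ["x", "y"],
            "n": [10, 10], "d": [0.1, 0.2],
        })
        b = pd.DataFrame({
            "sample_i": ["s3", "s2"], "sample_j": ["s1", "s1"],
            "species_i": ["y", "x"], "species_j": ["x", "x"],
            "n": [10, 10], "d": [0.25, np.nan],
        })
        xa, xb = paired_distances(a, b)
        assert list(xa) == [0.2]
        assert list(xb) == [0.25]

    def test_rank_markers_by_interspecific_mean(self):
        from barcodeval.divergence import Dispersed, DivergenceSummary

        def summary(name, inter):
            d = Dispersed(inter, 0.0, 0.0)
            return DivergenceSummary(name, d, d, d, d, d, d, 2, 4)

        high = summary("hi", 0.027)
        low = summary("lo", 0.001)
        ranking = rank_markers([low, high])
        assert [e["marker"] for e in ranking] == ["hi", "lo"]

    def test_tied_markers_keep_input_order(self):
        from barcodeval.divergence import Dispersed, DivergenceSummary

        d = Dispersed(0.01, 0.0, 0.0)
        a = DivergenceSummary("a", d, d, d, d, d, d, 2, 4)
        b = DivergenceSummary("b", d, d, d, d, d, d, 2, 4)
        ranking = rank_markers([a, b])
        assert [e["marker"] for e in ranking] == ["a", "b"]
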