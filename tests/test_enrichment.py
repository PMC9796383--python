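"""Over-representation analysis: exact tail, BH, GMT I/O, permutation null."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import hypergeom

from seizekit.enrichment import (
    GeneSetCollection,
    enrich_collection,
    hypergeom_overrep,
    permutation_baseline,
    read_gmt,
    write_gmt,
)


def hypergeom_tail_oracle(k, K, n, N):
    """Exact enumeration with integer binomial coefficients:
    P(X >= k) = sum_{j=k}^{min(K,n)} C(K,j) C(N-K, n-j) / C(N, n)."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
    return float(total)


class TestHypergeomOverrep:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_overrep(0, 5, 5, 20) == 1.0
        assert hypergeom_overrep(0, 1, 19, 20) == 1.0

    def test_enumerated_example(self):
        # C(5,3)C(15,2) + C(5,4)C(15,1) + C(5,5) = 1050+75+1 = 1126; C(20,5) = 15504
        expected = 1126 / 15504
        assert hypergeom_overrep(3, 5, 5, 20) == pytest.approx(expected, rel=1e-12)
        assert hypergeom_tail_oracle(3, 5, 5, 20) == pytest.approx(expected, rel=1e-15)

    def test_degenerate_certainty(self):
        assert hypergeom_overrep(7, 7, 7, 7) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hypergeom_overrep(3, 2, 5, 20)  # k > K
        with pytest.raises(ValueError):
            hypergeom_overrep(1, 25, 5, 20)  # K > N
        with pytest.raises(ValueError):
            hypergeom_overrep(-1, 2, 2, 4)

    def test_matches_enumeration_oracle_on_sampled_grid(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            N = int(rng.integers(2, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_overrep(k, K, n, N) == pytest.approx(
                hypergeom_tail_oracle(k, K, n, N), rel=1e-10, abs=1e-300
            )

    def test_tail_nonincreasing_in_k(self):
        K, n, N = 8, 10, 25
        tails = [hypergeom_overrep(k, K, n, N) for k in range(min(K, n) + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))


class TestGeneSetCollection:
    def test_default_universe_is_union(self):
        c = GeneSetCollection({"P1": ["A", "B"], "P2": ["B", "C"]})
        assert c.universe == {"A", "B", "C"}

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            GeneSetCollection({"P1": ["A", "Z"]}, universe=["A", "B"])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSetCollection({"P1": []}, universe=["A"])

    def test_gmt_round_trip(self, tmp_path):
        c = GeneSetCollection({"P1": ["A", "B"], "P2": ["C", "D", "E"]},
                              universe=[f"{ch}" for ch in "ABCDEFG"])
        path = tmp_path / "sets.gmt"
        write_gmt(c, path)
        again = read_gmt(path, universe=c.universe)
        assert again.sets == c.sets
        assert again.universe == c.universe

    def test_malformed_gmt_line(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("P1\tdesc\n")
        with pytest.raises(ValueError, match="GMT line"):
            read_gmt(path)


class TestEnrichCollection:
    def test_perfect_overlap_ranks_first(self):
        universe = [f"G{i}" for i in range(40)]
        c = GeneSetCollection({"HIT": universe[:8], "MISS": universe[20:28]}, universe=universe)
        report = enrich_collection(universe[:8], c)
        assert report.results[0].pathway == "HIT"
        assert report.results[0].k_overlap == 8
        assert report.results[0].p_value < report.results[1].p_value

    def test_disjoint_query_nothing_significant(self):
        universe = [f"G{i}" for i in range(30)]
        c = GeneSetCollection({"P1": universe[:5], "P2": universe[5:10]}, universe=universe)
        report = enrich_collection(universe[10:20], c)
        assert report.n_significant == 0
        assert all(r.p_value == 1.0 for r in report.results)

    def test_query_outside_universe_dropped_and_counted(self):
        universe = [f"G{i}" for i in range(20)]
        c = GeneSetCollection({"P1": universe[:5]}, universe=universe)
        report = enrich_collection(universe[:3] + ["NOTHERE"], c)
        assert report.n_query_used == 3
        assert report.n_query_dropped == 1

    def test_significant_count_invariant_to_pathway_order(self):
        rng = np.random.default_rng(9)
        universe = [f"G{i}" for i in range(200)]
        sets = {f"P{i}": list(rng.choice(universe, 15, replace=False)) for i in range(20)}
        query = list(rng.choice(universe, 60, replace=False))
        fwd = enrich_collection(query, GeneSetCollection(sets, universe=universe))
        rev = enrich_collection(query, GeneSetCollection(dict(reversed(sets.items())), universe=universe))
        assert fwd.n_significant == rev.n_significant
        assert {(r.pathway, r.p_value, r.fdr) for r in fwd.results} == {
            (r.pathway, r.p_value, r.fdr) for r in rev.results}

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enrich_collection(["A"], GeneSetCollection({}, universe=[]))


def _random_collection(rng, n_genes=300, n_sets=40, size=(10, 40)):
    universe = [f"G{i}" for i in range(n_genes)]
    sets = {
        f"P{i}": list(rng.choice(universe, int(rng.integers(*size)), replace=False))
        for i in range(n_sets)
    }
    return GeneSetCollection(sets, universe=universe)


def test_null_query_p_values_calibrated():
    """Uniform random queries: the fraction of pathways with p < alpha matches
    the exact attainable level of the discrete hypergeometric test (within
    3 SE). The exact level, not alpha itself, is the correct reference: the
    test is discrete, so P(p < alpha) sits strictly below alpha."""
    alpha, n_query = 0.05, 80
    rng = np.random.default_rng(21)
    collection = _random_collection(rng)
    universe = sorted(collection.universe)
    N = len(universe)
    # exact P(p < alpha) per pathway under the hypergeometric null
    exact = []
    for name in collection.names():
        K = len(collection.sets[name])
        ks = np.arange(0, min(K, n_query) + 1)
        tails = hypergeom.sf(ks - 1, N, K, n_query)
        hits = ks[tails < alpha]
        exact.append(float(hypergeom.sf(hits[0] - 1, N, K, n_query)) if hits.size else 0.0)
    expected = float(np.mean(exact))

    fractions = []
    for _ in range(200):
        query = rng.choice(universe, n_query, replace=False)
        report = enrich_collection(query, collection)
        fractions.append(np.mean([r.p_value < alpha for r in report.results]))
    fractions = np.asarray(fractions)
    se = fractions.std(ddof=1) / np.sqrt(len(fractions))
    assert abs(fractions.mean() - expected) <= 3 * se
    assert expected < alpha  # discreteness makes the exact level conservative


class TestPermutationBaseline:
    def test_add_one_formula_floor(self):
        rng = np.random.default_rng(2)
        collection = _random_collection(rng, n_genes=100, n_sets=10, size=(5, 15))
        # an observed count larger than any attainable null count
        summary = permutation_baseline(30, collection, observed_count=11, B=99, seed=1)
        assert summary.empirical_p == pytest.approx(1 / 100)
        assert max(summary.null_counts) <= 10

    def test_observed_zero_gives_p_one(self):
        rng = np.random.default_rng(2)
        collection = _random_collection(rng, n_genes=100, n_sets=10, size=(5, 15))
        summary = permutation_baseline(30, collection, observed_count=0, B=49, seed=1)
        assert summary.empirical_p == 1.0

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        collection = _random_collection(rng, n_genes=120, n_sets=12, size=(5, 20))
        a = permutation_baseline(40, collection, observed_count=2, B=50, seed=7)
        b = permutation_baseline(40, collection, observed_count=2, B=50, seed=7)
        assert a.null_counts == b.null_counts
        c = permutation_baseline(40, collection, observed_count=2, B=50, seed=8)
        assert c.null_counts != a.null_counts

    def test_query_larger_than_universe_rejected(self):
        rng = np.random.default_rng(4)
        collection = _random_collection(rng, n_genes=50, n_sets=5, size=(5, 10))
        with pytest.raises(ValueError, match="universe"):
            permutation_baseline(51, collection, observed_count=1, B=10, seed=0)

    def test_null_counts_match_per_permutation_enrich(self):
        """The vectorized permutation scorer agrees with scoring each random
        query through enrich_collection one at a time."""
        rng = np.random.default_rng(6)
        collection = _random_collection(rng, n_genes=150, n_sets=15, size=(8, 25))
        universe = sorted(collection.universe)
        B, n_query = 20, 45
        summary = permutation_baseline(
            n_query, collection, observed_count=3, B=B, seed=13, fdr_threshold=0.3)
        for b in range(B):
            rng_b = np.random.default_rng(np.random.SeedSequence(entropy=13, spawn_key=(b,)))
            query = [universe[i] for i in rng_b.choice(len(universe), n_query, replace=False)]
            report = enrich_collection(query, collection, fdr_threshold=0.3)
            assert report.n_significant == summary.null_counts[b]
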