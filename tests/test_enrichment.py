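"""Overrepresentation permutation test and classic-scheme GSEA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from _oracles import es_oracle
from craniodev.enrichment import (
    gsea_es,
    gsea_preranked,
    hypergeometric_tail,
    make_ranked,
    permutation_overlap_test,
    rank_by_mean_logfc,
)


class TestHypergeometricTail:
    def test_zero_threshold_is_certain(self):
        assert hypergeometric_tail(0, 5, 10, 100) == 1.0

    def test_forced_draw_is_certain(self):
        assert hypergeometric_tail(3, 3, 3, 3) == 1.0

    def test_combinatorial_example(self):
        # (C(4,2)C(6,1) + C(4,3)C(6,0)) / C(10,3) = 40/120
        assert hypergeometric_tail(2, 4, 3, 10) == pytest.approx(1 / 3)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(5, 4, 3, 10)


class TestPermutationOverlap:
    UNIVERSE = [f"g{i}" for i in range(200)]

    def test_curated_equals_universe_saturates(self):
        res = permutation_overlap_test(
            self.UNIVERSE[:30], self.UNIVERSE, self.UNIVERSE, n_perm=100,
            seed=0,
        )
        assert res.observed == 30
        assert res.p_empirical == 1.0

    def test_query_disjoint_from_curated_observes_zero(self):
        res = permutation_overlap_test(
            self.UNIVERSE[:30], self.UNIVERSE[100:], self.UNIVERSE,
            n_perm=100, seed=0,
        )
        assert res.observed == 0

    def test_empirical_p_close_to_hypergeometric(self):
        """The permutation null IS hypergeometric; at n_perm = 1e4 the
        empirical tail must sit within 3 Monte-Carlo SEs of the closed
        form (|universe| = 1000, |curated| = 100, |query| = 50)."""
        rng = np.random.default_rng(31)
        universe = [f"g{i}" for i in range(1000)]
        curated = universe[:100]
        query = list(rng.choice(universe, 50, replace=False))
        res = permutation_overlap_test(
            query, curated, universe, n_perm=10_000, seed=1
        )
        p_exact = res.p_hypergeom
        p_raw = np.mean(res.null_counts >= res.observed)
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(p_raw - p_exact) <= 3 * se

    def test_oversized_query_rejected(self):
        with pytest.raises(ValueError):
            permutation_overlap_test(
                self.UNIVERSE + ["x"], [], self.UNIVERSE, seed=0
            )


class TestGseaEs:
    def test_top_gene_set_scores_plus_one(self):
        ranked = make_ranked(pd.Series([4.0, 3, 2, 1], index=list("abcd")))
        assert gsea_es(ranked, ["a"])[0] == 1.0

    def test_bottom_gene_set_scores_minus_one(self):
        ranked = make_ranked(pd.Series([4.0, 3, 2, 1], index=list("abcd")))
        assert gsea_es(ranked, ["d"])[0] == -1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_quadratic_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        genes = [f"g{i}" for i in range(n)]
        ranked = make_ranked(pd.Series(rng.normal(size=n), index=genes))
        gs = list(rng.choice(genes, int(rng.integers(2, n // 2)),
                             replace=False))
        es, running = gsea_es(ranked, gs)
        assert es == es_oracle(ranked, gs)
        assert abs(running[-1]) < 1e-9  # increments balance exactly

    @pytest.mark.parametrize("seed", range(5))
    def test_reversing_list_negates_es(self, seed):
        rng = np.random.default_rng(100 + seed)
        genes = [f"g{i}" for i in range(30)]
        scores = pd.Series(rng.normal(size=30), index=genes)
        gs = list(rng.choice(genes, 7, replace=False))
        fwd, _ = gsea_es(make_ranked(scores), gs)
        rev = make_ranked(scores).iloc[::-1].reset_index(drop=True)
        bwd, _ = gsea_es(rev, gs)
        assert fwd == pytest.approx(-bwd, abs=1e-12)
        assert -1.0 <= fwd <= 1.0

    def test_no_member_present_errors(self):
        ranked = make_ranked(pd.Series([1.0, 2.0], index=["a", "b"]))
        with pytest.raises(ValueError, match="no member"):
            gsea_es(ranked, ["zzz"])


class TestGseaPreranked:
    def test_whole_list_set_is_skipped(self):
        ranked = make_ranked(pd.Series([3.0, 2, 1], index=list("abc")))
        with pytest.raises(ValueError, match="no usable"):
            with pytest.warns(UserWarning, match="degenerate"):
                gsea_preranked(ranked, {"all": list("abc")}, n_perm=10,
                               seed=0)

    def test_same_seed_reproduces_table(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(60)]
        ranked = make_ranked(pd.Series(rng.normal(size=60), index=genes))
        coll = {f"s{k}": list(rng.choice(genes, 10, replace=False))
                for k in range(4)}
        a = gsea_preranked(ranked, coll, n_perm=200, seed=5)
        b = gsea_preranked(ranked, coll, n_perm=200, seed=5)
        assert a.equals(b)

    def test_exhaustive_nominal_p_matches_enumeration(self):
        """N = 12, G = 3: the null can be enumerated (220 subsets); the
        nominal p must equal the same-sign tail fraction exactly."""
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(12)]
        ranked = make_ranked(pd.Series(rng.normal(size=12), index=genes))
        gs = [genes[0], genes[3], genes[7]]
        table = gsea_preranked(ranked, {"s": gs}, exhaustive=True, seed=0)
        es_obs = table["ES"].iloc[0]
        null = [
            es_oracle(ranked, list(combo))
            for combo in itertools.combinations(genes, 3)
        ]
        null = np.array(null)
        same = null >= 0 if es_obs >= 0 else null < 0
        expected_p = np.sum(np.abs(null[same]) >= abs(es_obs)) / same.sum()
        assert table["p"].iloc[0] == pytest.approx(expected_p, abs=1e-12)
        expected_nes = es_obs / np.mean(np.abs(null[same]))
        assert table["NES"].iloc[0] == pytest.approx(expected_nes, rel=1e-9)

    def test_nominal_p_uniform_under_random_ranking(self):
        """Null sets on a random ranking: nominal p ~ U(0,1)."""
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(100)]
        ranked = make_ranked(pd.Series(rng.normal(size=100), index=genes))
        coll = {
            f"s{k}": list(rng.choice(genes, 10, replace=False))
            for k in range(500)
        }
        table = gsea_preranked(ranked, coll, n_perm=500, seed=3)
        stat = kstest(table["p"], "uniform")
        assert stat.pvalue > 0.01
        assert np.all((table["q"] >= 0) & (table["q"] <= 1))
        assert np.all(np.sign(table["NES"]) == np.sign(table["ES"]))


class TestRankByMeanLogfc:
    def _tables(self, lfcs):
        genes = [f"g{i}" for i in range(len(lfcs[0]))]
        return [
            pd.DataFrame({"gene_id": genes, "logFC": v}) for v in lfcs
        ]

    def test_mean_of_three(self):
        t = self._tables([[1.0, 0.0], [1.0, 0.5], [1.0, 0.1]])
        ranked = rank_by_mean_logfc(t)
        assert ranked.loc[0, "gene_id"] == "g0"
        assert ranked.loc[0, "score"] == pytest.approx(1.0)

    def test_negation_reverses_ranking(self):
        rng = np.random.default_rng(17)
        lfcs = [rng.normal(size=40) for _ in range(3)]
        fwd = rank_by_mean_logfc(self._tables(lfcs))
        bwd = rank_by_mean_logfc(self._tables([-v for v in lfcs]))
        assert list(fwd["gene_id"]) == list(bwd["gene_id"])[::-1]

    def test_order_matches_sort_oracle(self):
        rng = np.random.default_rng(19)
        lfcs = [rng.normal(size=50) for _ in range(3)]
        ranked = rank_by_mean_logfc(self._tables(lfcs))
        mean = np.mean(lfcs, axis=0)
        oracle = sorted(
            (f"g{i}" for i in range(50)),
            key=lambda g: (-mean[int(g[1:])], g),
        )
        assert list(ranked["gene_id"]) == oracle


def test_gsea_es_agrees_with_gseapy():
    """Independent cross-check of the classic (unweighted) score against
    the gseapy implementation on one instance."""
    gseapy = pytest.importorskip("gseapy")
    rng = np.random.default_rng(23)
    genes = [f"G{i}" for i in range(100)]
    scores = pd.Series(np.sort(rng.normal(size=100))[::-1], index=genes)
    gs = list(rng.choice(genes, 12, replace=False))
    ranked = make_ranked(scores)
    ours, _ = gsea_es(ranked, gs)
    rnk = ranked.set_index("gene_id")["score"]
    res = gseapy.prerank(
        rnk=rnk, gene_sets={"s": gs}, permutation_num=4, weight=0,
        min_size=2, max_size=500, seed=1, threads=1, outdir=None,
        no_plot=True,
    )
    theirs = res.res2d["ES"].iloc[0]
    assert ours == pytest.approx(float(theirs), abs=1e-6)
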