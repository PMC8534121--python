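import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metintegrate import synthdata
from metintegrate.containers import CLASS_METASTASIS, CLASS_PRIMARY, GeneSetCollection
from metintegrate.differential import rank_table, top_n
from metintegrate.enrichment import bh_fdr, gsea_es, gsea_perm_p, ora
from metintegrate.errors import InvalidInputError, InvalidParameterError

from oracles import bh_quadratic, binomial_upper_tail, running_sum_es


def _collection(named_sets):
    coll = GeneSetCollection()
    for sid, members in named_sets.items():
        coll.add(sid, "", members)
    return coll


class TestOra:
    def test_textbook_binomial_tail(self):
        # 10 submitted out of a 100-gene universe, set of size 10, 3 found:
        # P(Bin(10, 0.1) >= 3) ~ 0.0702
        universe = [f"g{i}" for i in range(100)]
        coll = _collection({"S": universe[:10]})
        query = universe[:3] + universe[90:97]
        res = ora(query, coll, universe, min_size=1)
        assert res.loc[0, "found"] == 3
        assert res.loc[0, "total"] == 10
        assert res.loc[0, "p_value"] == pytest.approx(0.07019083, abs=1e-7)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        coll = _collection({"S": universe[:10]})
        res = ora(universe[40:45], coll, universe, min_size=1)
        assert res.loc[0, "found"] == 0
        assert res.loc[0, "p_value"] == 1.0

    def test_query_saturating_universe(self):
        universe = [f"g{i}" for i in range(30)]
        coll = _collection({"S": universe[:8]})
        res = ora(universe, coll, universe, min_size=1)
        f, t = res.loc[0, "found"], res.loc[0, "total"]
        assert f == t == 8
        expected = float(stats.binom.sf(t - 1, 30, t / 30))
        assert res.loc[0, "p_value"] == pytest.approx(expected)

    def test_ids_outside_universe_are_dropped(self):
        universe = [f"g{i}" for i in range(20)]
        coll = _collection({"S": universe[:5]})
        res = ora(universe[:3] + ["alien1", "alien2"], coll, universe, min_size=1)
        # n excludes the aliens: P(Bin(3, 0.25) >= 3)
        assert res.loc[0, "p_value"] == pytest.approx(0.25**3)

    def test_matches_exact_summation_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            u = int(rng.integers(20, 2000))
            n = int(rng.integers(1, min(u, 1000) + 1))
            t = int(rng.integers(1, u + 1))
            universe = [f"g{i}" for i in range(u)]
            members = universe[:t]
            query = [universe[i] for i in rng.choice(u, size=n, replace=False)]
            f = len(set(query) & set(members))
            got = ora(query, _collection({"S": members}), universe,
                      min_size=1, max_size=u)
            assert abs(got.loc[0, "p_value"] - binomial_upper_tail(f, n, t, u)) < 1e-12

    def test_set_size_filter_limits_fdr_family(self):
        universe = [f"g{i}" for i in range(100)]
        coll = _collection({"BIG": universe[:50], "TINY": universe[:2]})
        res = ora(universe[:10], coll, universe, min_size=5, max_size=2000)
        assert res["set_id"].tolist() == ["BIG"]

    def test_empty_universe_rejected(self):
        with pytest.raises(InvalidInputError):
            ora(["a"], _collection({"S": ["a"]}), [])

    def test_planted_set_beats_decoys(self, small_tissue):
        em, truth = small_tissue
        table = rank_table(em, CLASS_METASTASIS, CLASS_PRIMARY, n_perm=9, seed=0)
        coll, planted = synthdata.generate_gene_sets(
            em.gene_ids, n_sets=21, set_size_range=(15, 40), n_planted=1,
            seed=5, planted_pool=truth.de_gene_ids)
        query = top_n(table, 100)["gene"].tolist()
        res = ora(query, coll, em.gene_ids)
        assert res.loc[0, "set_id"] == planted[0]


class TestBhFdr:
    def test_hand_worked_step_up(self):
        got = bh_fdr([0.01, 0.02, 0.03])
        assert got == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_all_ones_stay_one(self):
        assert bh_fdr([0.37]) == pytest.approx([0.37])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_quadratic_reference(self, p):
        assert bh_fdr(p) == pytest.approx(bh_quadratic(p), abs=1e-12)


class TestGseaEs:
    def test_top_concentrated_set_scores_near_one(self):
        genes = [f"g{i}" for i in range(40)]
        scores = np.linspace(5, -5, 40)
        res = gsea_es(genes, scores, genes[:5])
        assert res.es > 0.8
        assert res.leading_edge == genes[:5]

    def test_whole_list_as_set_is_degenerate(self):
        genes = ["a", "b", "c", "d", "e", "f"]
        with pytest.raises(InvalidInputError):
            gsea_es(genes, np.arange(6.0), genes)

    def test_no_overlap_rejected(self):
        with pytest.raises(InvalidInputError):
            gsea_es(["a", "b", "c", "d"], [3.0, 2.0, 1.0, 0.5], ["zz"])

    def test_spec_list_matches_brute_force(self):
        genes = [f"g{i}" for i in range(10)]
        scores = [5.0, 4.0, 3.0, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        members = genes[:3]
        res = gsea_es(genes, scores, members, weight=1.0)
        es, peak, le = running_sum_es(genes, scores, members, weight=1.0)
        assert res.es == pytest.approx(es)
        assert res.peak_rank == peak + 1
        assert res.leading_edge == le

    def test_matches_brute_force_on_random_small_lists(self):
        rng = np.random.default_rng(9)
        for n in range(3, 13):
            for _ in range(25):
                genes = [f"g{i}" for i in range(n)]
                scores = rng.normal(size=n)
                k = int(rng.integers(1, n))
                members = [genes[i] for i in rng.choice(n, size=k, replace=False)]
                for w in (0.0, 1.0, 2.0):
                    res = gsea_es(genes, scores, members, weight=w)
                    es, peak, le = running_sum_es(genes, scores, members, weight=w)
                    assert res.es == pytest.approx(es, abs=1e-12)
                    assert res.peak_rank == peak + 1
                    assert res.leading_edge == le
                    assert -1.0 - 1e-12 <= res.es <= 1.0 + 1e-12

    def test_weight_zero_reduces_to_ks_statistic(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(50)]
        scores = rng.normal(size=50)
        members = [genes[i] for i in rng.choice(50, size=12, replace=False)]
        res = gsea_es(genes, scores, members, weight=0.0)
        order = np.argsort(-scores, kind="stable")
        ranks = np.arange(1, 51)
        in_set = np.isin(order, [genes.index(m) for m in members])
        ks = stats.ks_2samp(ranks[in_set], ranks[~in_set]).statistic
        assert abs(res.es) == pytest.approx(ks, abs=1e-12)

    def test_complement_set_negates_es_under_weight_zero(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(12)]
        scores = rng.normal(size=12)
        members = genes[2:6]
        complement = [g for g in genes if g not in members]
        res = gsea_es(genes, scores, members, weight=0.0)
        res_c = gsea_es(genes, scores, complement, weight=0.0)
        assert res_c.es == pytest.approx(-res.es, abs=1e-12)
        assert res_c.peak_rank == res.peak_rank

    def test_tie_handling_is_stable_and_deterministic(self):
        genes = ["gA", "gB", "gC", "gD", "gE"]
        scores = [1.0, 1.0, 1.0, 0.0, 0.0]
        r1 = gsea_es(genes, scores, ["gB", "gD"])
        r2 = gsea_es(genes, scores, ["gB", "gD"])
        assert r1 == r2


class TestGseaPermP:
    def test_planted_coherent_set_hits_floor(self, small_tissue):
        em, truth = small_tissue
        members = truth.de_gene_ids[:30]
        _res, p = gsea_perm_p(em, CLASS_METASTASIS, CLASS_PRIMARY, members,
                              n_perm=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_zero_permutations_rejected(self, tiny_matrix):
        with pytest.raises(InvalidParameterError):
            gsea_perm_p(tiny_matrix, "metastasis", "primary", ["GA"], n_perm=0)
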