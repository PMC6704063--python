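import numpy as np
import pandas as pd
import pytest

from scmetab import (
    GeneSetCollection,
    enrichment_score,
    preranked_gsea,
    two_class_gsea,
)
from scmetab.enrichment import _es_from_positions

from conftest import make_annotation, make_matrix


def brute_force_es(ranked_genes, ranked_scores, gene_set, exponent=1.0):
    """Independent running-sum walk, one explicit step per gene."""
    members = set(gene_set)
    hits = [g in members for g in ranked_genes]
    n, nh = len(ranked_genes), sum(hits)
    total_w = sum(abs(s) ** exponent for g, s, h in
                  zip(ranked_genes, ranked_scores, hits) if h)
    running, cur, best = [], 0.0, 0.0
    for g, s, h in zip(ranked_genes, ranked_scores, hits):
        if h:
            cur += (abs(s) ** exponent) / total_w if total_w > 0 else 1.0 / nh
        else:
            cur -= 1.0 / (n - nh)
        running.append(cur)
        if abs(cur) > abs(best):
            best = cur
    return best, running


def random_instance(rng, n=50, m=6):
    genes = [f"g{i:03d}" for i in range(n)]
    scores = rng.normal(0, 2, n)
    order = np.argsort(-scores)
    ranked_genes = [genes[i] for i in order]
    ranked_scores = scores[order]
    gene_set = list(rng.choice(genes, m, replace=False))
    return ranked_genes, ranked_scores, gene_set


class TestEnrichmentScore:
    def test_single_top_gene_exponent_zero(self):
        genes = [f"g{i}" for i in range(10)]
        scores = np.arange(10, 0, -1, dtype=float)
        es, running = enrichment_score(genes, scores, ["g0"], weight_exponent=0)
        assert es == pytest.approx(1.0)
        # after the initial hit the walk decays by 1/9 per miss
        assert running[1] == pytest.approx(1.0 - 1.0 / 9.0)

    def test_single_bottom_gene_matches_bruteforce(self):
        genes = [f"g{i}" for i in range(10)]
        scores = np.arange(10, 0, -1, dtype=float)
        es, _ = enrichment_score(genes, scores, ["g9"], weight_exponent=0)
        expected, _ = brute_force_es(genes, scores, ["g9"], exponent=0)
        assert es == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("exponent", [0.0, 1.0])
    def test_oracle_equivalence_random_instances(self, rng, exponent):
        for _ in range(100):
            g, s, gs = random_instance(rng)
            es, _ = enrichment_score(g, s, gs, weight_exponent=exponent)
            expected, _ = brute_force_es(g, s, gs, exponent=exponent)
            assert es == pytest.approx(expected, abs=1e-12)
            assert abs(es) <= 1.0 + 1e-12

    def test_fast_position_form_matches_full_walk(self, rng):
        for _ in range(100):
            g, s, gs = random_instance(rng)
            es, _ = enrichment_score(g, s, gs, weight_exponent=1.0)
            pos = np.sort([g.index(x) for x in gs])
            w = np.abs(np.asarray(s)[pos])
            assert _es_from_positions(pos, w, len(g)) == pytest.approx(es, abs=1e-12)

    def test_monotone_transform_invariance_exponent_zero(self, rng):
        g, s, gs = random_instance(rng)
        es1, _ = enrichment_score(g, s, gs, weight_exponent=0)
        es2, _ = enrichment_score(g, np.exp(s / 3.0), gs, weight_exponent=0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_reversed_ranking_negates_es_exponent_zero(self, rng):
        g, s, gs = random_instance(rng, n=51)  # odd length avoids midpoint ties
        es1, _ = enrichment_score(g, s, gs, weight_exponent=0)
        es2, _ = enrichment_score(g[::-1], s[::-1], gs, weight_exponent=0)
        assert es2 == pytest.approx(-es1, abs=1e-12)

    def test_empty_overlap_errors(self):
        with pytest.raises(ValueError, match="no overlap"):
            enrichment_score(["a", "b"], [2.0, 1.0], ["z"])


class TestPrerankedGsea:
    def test_planted_top_set_significant(self, rng):
        genes = [f"g{i:03d}" for i in range(100)]
        scores = rng.normal(0, 1, 100)
        scores[:10] += 5.0  # the first ten genes carry the signal
        ranking = pd.Series(scores, index=genes)
        sets = {"TOP": genes[:10]}
        sets.update({f"BG{i}": list(rng.choice(genes, 10, replace=False))
                     for i in range(5)})
        res = preranked_gsea(ranking, GeneSetCollection(sets), n_perm=500, seed=4)
        top = next(r for r in res if r.set_name == "TOP")
        assert top.p_value < 0.05 and top.nes > 1.0
        assert res[0].set_name == "TOP"

    def test_null_false_positive_rate(self, rng):
        # shuffled ranking, 50 sets: about 5% significant at 0.05
        genes = [f"g{i:03d}" for i in range(200)]
        hits = 0
        n_sets = 50
        for seed in range(4):
            ranking = pd.Series(rng.normal(0, 1, 200), index=genes)
            sets = {f"S{i}": list(rng.choice(genes, 15, replace=False))
                    for i in range(n_sets)}
            res = preranked_gsea(ranking, GeneSetCollection(sets),
                                 n_perm=200, seed=seed)
            hits += sum(r.p_value < 0.05 for r in res)
        rate = hits / (4 * n_sets)
        assert rate < 0.12

    def test_same_seed_bit_identical(self, rng):
        genes = [f"g{i:03d}" for i in range(60)]
        ranking = pd.Series(rng.normal(0, 1, 60), index=genes)
        sets = GeneSetCollection({"A": genes[:8], "B": genes[10:20]})
        r1 = preranked_gsea(ranking, sets, n_perm=200, seed=7)
        r2 = preranked_gsea(ranking, sets, n_perm=200, seed=7)
        assert [(a.set_name, a.es, a.nes, a.p_value) for a in r1] == \
               [(b.set_name, b.es, b.nes, b.p_value) for b in r2]

    def test_size_bounds_filter_sets(self, rng):
        genes = [f"g{i:03d}" for i in range(60)]
        ranking = pd.Series(rng.normal(0, 1, 60), index=genes)
        sets = GeneSetCollection({"small": genes[:2], "ok": genes[:10]})
        res = preranked_gsea(ranking, sets, n_perm=100, set_min=5, seed=0)
        assert [r.set_name for r in res] == ["ok"]

    def test_no_usable_set_warns_and_returns_empty(self, rng):
        genes = [f"g{i}" for i in range(20)]
        ranking = pd.Series(rng.normal(0, 1, 20), index=genes)
        sets = GeneSetCollection({"alien": ["x1", "x2", "x3", "x4", "x5"]})
        with pytest.warns(UserWarning, match="no gene set"):
            assert preranked_gsea(ranking, sets, n_perm=100, seed=0) == []

    def test_leading_edge_members_subset_of_set(self, rng):
        genes = [f"g{i:03d}" for i in range(80)]
        ranking = pd.Series(rng.normal(0, 1, 80), index=genes)
        sets = GeneSetCollection({"S": list(rng.choice(genes, 12, replace=False))})
        res = preranked_gsea(ranking, sets, n_perm=100, seed=0)
        assert set(res[0].leading_edge) <= set(sets.sets["S"])
        assert 1 <= len(res[0].leading_edge) <= 12


class TestTwoClassGsea:
    def make_two_class(self, rng, shift=0.0):
        genes = [f"g{i:03d}" for i in range(100)]
        cells = [f"c{i}" for i in range(40)]
        vals = rng.normal(2, 1, (100, 100))[:, :40]
        vals = np.abs(vals)
        vals[:10, :20] += shift  # set genes up in class "A" (first 20 cells)
        m = make_matrix(vals, genes=genes, cells=cells)
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=cells)
        sets = {"SIG": genes[:10]}
        sets.update({f"BG{i}": list(rng.choice(genes[10:], 10, replace=False))
                     for i in range(5)})
        return m, labels, GeneSetCollection(sets)

    def test_upshifted_set_detected(self, rng):
        m, labels, sets = self.make_two_class(rng, shift=1.0)
        res = two_class_gsea(m, labels, sets, n_perm=500, seed=3)
        assert res[0].set_name == "SIG" and res[0].p_value < 0.05

    def test_label_swap_negates_es(self, rng):
        m, labels, sets = self.make_two_class(rng, shift=0.5)
        r1 = two_class_gsea(m, labels, sets, n_perm=100, seed=0,
                            class_order=["A", "B"])
        r2 = two_class_gsea(m, labels, sets, n_perm=100, seed=0,
                            class_order=["B", "A"])
        es1 = {r.set_name: r.es for r in r1}
        es2 = {r.set_name: r.es for r in r2}
        for name in es1:
            assert es2[name] == pytest.approx(-es1[name], abs=1e-9)

    def test_small_class_errors(self, rng):
        m, labels, sets = self.make_two_class(rng)
        labels.iloc[2:] = "B"
        with pytest.raises(ValueError, match="at least 3"):
            two_class_gsea(m, labels, sets, n_perm=100, seed=0)
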