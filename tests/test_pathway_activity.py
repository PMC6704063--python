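import numpy as np
import pandas as pd
import pytest

from scmetab import (
    GeneSetCollection,
    bulk_group_activity,
    celltype_means,
    gene_weights,
    pathway_scores,
    permutation_test,
    relative_expression,
)
from scmetab.pathway_activity import CellTypeMeans

from conftest import make_annotation, make_matrix


def rel_from_E(E):
    """Wrap a plain gene x group mean table as RelativeExpression input."""
    means = CellTypeMeans(E, pd.Series(1, index=E.columns))
    return relative_expression(means)


class TestCellTypeMeans:
    def test_simple_mean(self):
        m = make_matrix([[1.0, 3.0]])
        ann = make_annotation(list(m.cell_ids), ["A", "A"])
        assert celltype_means(m, ann).E.loc["G0", "A"] == 2.0

    def test_one_cell_per_type(self, small_matrix):
        ann = make_annotation(list(small_matrix.cell_ids), ["A", "B", "C", "D"])
        E = celltype_means(small_matrix, ann).E
        assert np.array_equal(E.to_numpy(), small_matrix.values)

    def test_matches_bruteforce_group_mean(self, rng):
        vals = rng.random((15, 30))
        m = make_matrix(vals)
        labels = rng.choice(["A", "B", "C"], 30).tolist()
        ann = make_annotation(list(m.cell_ids), labels)
        E = celltype_means(m, ann).E
        for j, t in enumerate(["A", "B", "C"]):
            cols = [i for i, l in enumerate(labels) if l == t]
            assert np.allclose(E[t].to_numpy(), vals[:, cols].mean(axis=1))


class TestRelativeExpression:
    @pytest.mark.parametrize("row, expected", [
        ([2.0, 2.0, 2.0], [1.0, 1.0, 1.0]),
        ([1.0, 3.0], [0.5, 1.5]),
    ])
    def test_arithmetic(self, row, expected):
        E = pd.DataFrame([row], index=["G0"],
                         columns=[f"T{i}" for i in range(len(row))])
        r = rel_from_E(E).r
        assert np.allclose(r.loc["G0"].to_numpy(), expected)

    def test_row_mean_identity_on_random_inputs(self, rng):
        for _ in range(20):
            E = pd.DataFrame(rng.random((30, 4)) * 10, columns=list("ABCD"))
            rel = rel_from_E(E)
            means = rel.r.loc[rel.valid_mask].mean(axis=1)
            assert np.allclose(means, 1.0, atol=1e-12)

    def test_zero_mean_gene_flagged_invalid(self):
        E = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["G0", "G1"],
                         columns=["A", "B"])
        rel = rel_from_E(E)
        assert not rel.valid_mask.loc["G0"] and rel.valid_mask.loc["G1"]


class TestGeneWeights:
    def test_reciprocal_membership(self, two_sets):
        w = gene_weights(two_sets)
        assert w["G0"] == 1.0 and w["G1"] == 0.5 and w["G2"] == 1.0


class TestPathwayScores:
    def test_all_ones_gives_unit_scores(self, two_sets):
        E = pd.DataFrame(np.ones((3, 3)), index=["G0", "G1", "G2"],
                         columns=list("XYZ"))
        table = pathway_scores(rel_from_E(E), two_sets)
        assert np.allclose(table.scores.to_numpy(), 1.0)

    def test_hand_computed_weighted_average(self):
        # gene a in 1 set (w=1) with r=[2,0]; gene b in 2 sets (w=0.5) with
        # r=[0,2]: scores are [4/3, 2/3]
        sets = GeneSetCollection({"P": ["a", "b"], "Q": ["b", "z"]})
        E = pd.DataFrame([[2.0, 0.0], [0.0, 2.0]], index=["a", "b"],
                         columns=["T1", "T2"])
        table = pathway_scores(rel_from_E(E * 5), sets)  # scale-free in r
        assert table.scores.loc["P", "T1"] == pytest.approx(4.0 / 3.0, abs=1e-12)
        assert table.scores.loc["P", "T2"] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_outlier_gene_excluded_and_score_recomputed(self, rng):
        genes = [f"g{i}" for i in range(6)]
        E = pd.DataFrame(rng.random((6, 3)) + 0.5, index=genes, columns=list("XYZ"))
        # one gene concentrated in a single type: its near-zero relative
        # expression elsewhere trips the low-side outlier rule
        E.iloc[0] = [1000.0, 1e-3, 1e-3]
        sets = GeneSetCollection({"P": genes})
        rel = rel_from_E(E)
        table = pathway_scores(rel, sets)
        assert table.excluded_outlier_genes["P"] == ["g0"]
        # brute-force: recompute percentiles, drop flagged genes, re-average
        r = rel.r.to_numpy()
        q25, q75 = np.percentile(r, [25, 75])
        keep = ~((r > 3 * q75).any(axis=1) | (r < q25 / 3).any(axis=1))
        w = np.ones(keep.sum())
        expected = w @ r[keep] / w.sum()
        assert np.allclose(table.scores.loc["P"].to_numpy(), expected)

    def test_no_surviving_genes_is_flagged_not_zero(self):
        sets = GeneSetCollection({"P": ["missing1", "missing2"]})
        E = pd.DataFrame([[1.0, 2.0]], index=["G0"], columns=["A", "B"])
        table = pathway_scores(rel_from_E(E), sets)
        assert table.scores.loc["P"].isna().all()
        assert "P" in table.undefined

    def test_score_within_member_r_range(self, rng):
        genes = [f"g{i}" for i in range(8)]
        E = pd.DataFrame(rng.random((8, 4)) + 0.2, index=genes, columns=list("WXYZ"))
        sets = GeneSetCollection({"P": genes[:5], "Q": genes[3:]})
        rel = rel_from_E(E)
        table = pathway_scores(rel, sets)
        for name, members in sets:
            surviving = [g for g in members
                         if g not in table.excluded_outlier_genes.get(name, [])]
            sub = rel.r.loc[surviving]
            assert (table.scores.loc[name] >= sub.min(axis=0) - 1e-12).all()
            assert (table.scores.loc[name] <= sub.max(axis=0) + 1e-12).all()


class TestPermutationTest:
    def test_same_seed_bit_identical(self, rng, two_sets):
        m = make_matrix(rng.random((3, 40)) * 4,
                        genes=["G0", "G1", "G2"])
        ann = make_annotation(list(m.cell_ids),
                              (["A"] * 20 + ["B"] * 20))
        t1 = permutation_test(m, ann, two_sets, n_perm=100, seed=9)
        t2 = permutation_test(m, ann, two_sets, n_perm=100, seed=9)
        assert t1.p_values.equals(t2.p_values)
        assert t1.scores.equals(t2.scores)

    def test_planted_upregulation_detected(self):
        import scmetab
        spec = scmetab.SimulationSpec(
            n_genes=200, gene_set_sizes={"UP": 15, "BG1": 15, "BG2": 15},
            cell_types={"A": 60, "B": 60, "C": 60}, tumors={},
            planted_effects=[scmetab.PlantedEffect("UP", "A", 1.0)], seed=21)
        m, ann, gs, _ = scmetab.generate(spec)
        table = permutation_test(m, ann, gs, n_perm=500, seed=22)
        assert table.scores.loc["UP", "A"] > 1.0
        assert table.p_values.loc["UP", "A"] < 0.01

    def test_duplicating_every_cell_preserves_scores(self, rng, two_sets):
        vals = rng.random((3, 20)) * 3
        m1 = make_matrix(vals, genes=["G0", "G1", "G2"])
        ann1 = make_annotation(list(m1.cell_ids), ["A"] * 10 + ["B"] * 10)
        m2 = make_matrix(np.hstack([vals, vals]), genes=["G0", "G1", "G2"],
                         cells=[f"x{i}" for i in range(40)])
        ann2 = make_annotation(list(m2.cell_ids), (["A"] * 10 + ["B"] * 10) * 2)
        t1 = permutation_test(m1, ann1, two_sets, n_perm=100, seed=1)
        t2 = permutation_test(m2, ann2, two_sets, n_perm=100, seed=1)
        assert np.allclose(t1.scores.to_numpy(), t2.scores.to_numpy())

    def test_raw_tail_flag_recovers_unsmoothed_fraction(self, rng, two_sets):
        m = make_matrix(rng.random((3, 30)) * 4, genes=["G0", "G1", "G2"])
        ann = make_annotation(list(m.cell_ids), ["A"] * 15 + ["B"] * 15)
        t = permutation_test(m, ann, two_sets, n_perm=100, seed=3,
                             tail="observed", smoothing=False)
        p = t.p_values.to_numpy()
        # raw fractions lie on the k/100 grid
        assert np.allclose(np.round(p * 100), p * 100)

    def test_single_group_errors(self, rng, two_sets):
        m = make_matrix(rng.random((3, 10)), genes=["G0", "G1", "G2"])
        ann = make_annotation(list(m.cell_ids), ["A"] * 10)
        with pytest.raises(ValueError, match="two groups"):
            permutation_test(m, ann, two_sets, n_perm=100, seed=0)


class TestBulkGroupActivity:
    def test_equal_groups_score_one(self, two_sets, rng):
        profile = rng.random(3) + 0.5
        vals = np.tile(profile, (8, 1)).T
        m = make_matrix(vals, genes=["G0", "G1", "G2"],
                        cells=[f"s{i}" for i in range(8)])
        labels = pd.Series(["tumor"] * 4 + ["normal"] * 4, index=m.cell_ids)
        t = bulk_group_activity(m, labels, two_sets, n_perm=100, seed=0)
        assert np.allclose(t.scores.to_numpy(), 1.0)

    def test_doubled_pathway_matches_hand_computation(self, rng):
        # log2 values: tumor has gene g0 doubled in linear r terms
        sets = GeneSetCollection({"P": ["g0"]})
        vals = np.array([[4.0, 4.0, 2.0, 2.0]])
        m = make_matrix(vals, genes=["g0"], cells=[f"s{i}" for i in range(4)])
        labels = pd.Series(["tumor", "tumor", "normal", "normal"], index=m.cell_ids)
        t = bulk_group_activity(m, labels, sets, n_perm=100, seed=0)
        # E = [2, 4]; mean 3 -> r = [2/3, 4/3]
        assert t.scores.loc["P", "normal"] == pytest.approx(2.0 / 3.0)
        assert t.scores.loc["P", "tumor"] == pytest.approx(4.0 / 3.0)

    def test_seed_determinism(self, two_sets, rng):
        m = make_matrix(rng.random((3, 12)) * 3, genes=["G0", "G1", "G2"])
        labels = pd.Series(["t"] * 6 + ["n"] * 6, index=m.cell_ids)
        a = bulk_group_activity(m, labels, two_sets, n_perm=100, seed=5)
        b = bulk_group_activity(m, labels, two_sets, n_perm=100, seed=5)
        assert a.p_values.equals(b.p_values)
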