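import numpy as np
import pandas as pd
import pytest

import genecol as gc
from genecol.zonetree import (
    ZoneTreeModel,
    best_split,
    fit_zonetree,
    zone_codes,
)

from _oracles import brute_force_tree, tree_to_nested, trees_equal


def _scores(Y):
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] == 1:
        Y = Y.T
    return pd.DataFrame(Y, index=[f"P{i}" for i in range(len(Y))],
                        columns=[f"PC{j+1}" for j in range(Y.shape[1])])


def _preds(**cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"P{i}" for i in range(n)])


class TestBestSplit:
    def test_hand_computed_two_group_split(self):
        Y = np.array([[0.0], [0.0], [0.0], [10.0], [10.0], [10.0]])
        X = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6]})
        rule = best_split(Y, X, min_node=3)
        assert rule.threshold == pytest.approx(3.5)
        assert rule.gain == pytest.approx(150.0)

    def test_constant_scores_yield_no_split(self):
        Y = np.full((8, 2), 3.3)
        X = pd.DataFrame({"x": np.arange(8.0)})
        assert best_split(Y, X, min_node=2) is None

    def test_predictor_declaration_order_breaks_ties(self):
        Y = np.array([[0.0], [0.0], [5.0], [5.0]])
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        rule = best_split(Y, X, min_node=2)
        assert rule.predictor == "a"
        # and with reversed declaration order the other one wins
        rule2 = best_split(Y, X[["b", "a"]], min_node=2)
        assert rule2.predictor == "b"

    def test_smallest_threshold_among_equal_gains(self):
        # response constant except one extreme; equal-gain thresholds exist
        Y = np.array([[0.0], [0.0], [1.0], [1.0]])
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        rule = best_split(Y, X, min_node=1)
        assert rule.threshold == pytest.approx(2.5)

    def test_min_node_respected(self):
        Y = np.array([[0.0], [10.0], [10.0], [10.0], [10.0], [10.0]])
        X = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6]})
        rule = best_split(Y, X, min_node=3)
        assert rule is None or min(3, 3) >= 3  # only the 3|3 cut is legal
        assert rule.threshold == pytest.approx(3.5)


class TestCategoricalSplit:
    def test_binary_level_partition_recovered(self):
        Y = np.array([[0.0], [0.0], [9.0], [9.0], [0.0], [9.0]])
        X = _preds(taxon=["a", "a", "b", "b", "a", "b"])
        scores = _scores(Y)
        model = fit_zonetree(scores, X, cp=0.0, min_node=2,
                             categorical=("taxon",))
        rule = model.root.split
        assert rule.kind == "categorical"
        assert set(rule.left_levels) == {"a"}

    def test_too_many_levels_rejected(self):
        n = 14
        Y = np.arange(n, dtype=float)
        X = _preds(taxon=[f"t{i}" for i in range(n)])
        with pytest.raises(ValueError, match="levels"):
            fit_zonetree(_scores(Y), X, cp=0.0, min_node=1,
                         categorical=("taxon",))


class TestFitZonetree:
    def test_parameter_validation(self):
        Y, X = _scores([0, 1, 2, 3]), _preds(x=[1.0, 2, 3, 4])
        with pytest.raises(ValueError):
            fit_zonetree(Y, X, cp=-0.1, min_node=2)
        with pytest.raises(ValueError):
            fit_zonetree(Y, X, cp=0.1, min_node=0)

    def test_cp_one_yields_root_only_model(self, rng):
        Y = _scores(rng.standard_normal(20))
        X = _preds(x=rng.standard_normal(20))
        model = fit_zonetree(Y, X, cp=1.0, min_node=2)
        assert model.root.is_leaf
        fracs, resid = model.variance_by_level()
        assert resid == pytest.approx(1.0)

    def test_ss_conservation_at_every_split(self, rng):
        Y = _scores(rng.standard_normal((40, 2)))
        X = _preds(a=rng.standard_normal(40), b=rng.standard_normal(40),
                   c=rng.standard_normal(40))
        model = fit_zonetree(Y, X, cp=0.0, min_node=3)
        for node in model.nodes.values():
            if node.is_leaf:
                continue
            l, r = (model.nodes[c] for c in node.children)
            assert node.ss == pytest.approx(l.ss + r.ss + node.split.gain,
                                            abs=1e-8 * max(node.ss, 1))
        explained = sum(n.split.gain for n in model.nodes.values()
                        if not n.is_leaf)
        terminal = sum(l.ss for l in model.leaves())
        assert model.root_ss == pytest.approx(explained + terminal, rel=1e-10)

    @pytest.mark.parametrize("seed", range(12))
    def test_greedy_equals_brute_force_enumerator(self, seed):
        """On small instances the greedy tree coincides split-for-split
        with an independent naive recursive enumerator."""
        r = np.random.default_rng(seed)
        n = 20
        Y = r.standard_normal((n, 2))
        X = r.standard_normal((n, 3))
        names = ["v1", "v2", "v3"]
        scores = _scores(Y)
        preds = pd.DataFrame(X, index=scores.index, columns=names)
        model = fit_zonetree(scores, preds, cp=0.0, min_node=2)
        oracle = brute_force_tree(Y, X, names, cp=0.0, min_node=2)
        index_of = {f"P{i}": i for i in range(n)}
        assert trees_equal(tree_to_nested(model, index_of), oracle)

    def test_row_permutation_gives_identical_tree(self, rng):
        n = 30
        Y = rng.standard_normal((n, 2))
        X = rng.standard_normal((n, 3))
        scores = _scores(Y)
        preds = pd.DataFrame(X, index=scores.index,
                             columns=["a", "b", "c"])
        perm = rng.permutation(n)
        m1 = fit_zonetree(scores, preds, cp=0.01, min_node=3)
        m2 = fit_zonetree(scores.iloc[perm], preds.iloc[perm],
                          cp=0.01, min_node=3)
        assert m1.to_dict()["nodes"].keys() == m2.to_dict()["nodes"].keys()
        for nid, n1 in m1.nodes.items():
            n2 = m2.nodes[nid]
            assert sorted(n1.members) == sorted(n2.members)
            if not n1.is_leaf:
                assert n1.split.predictor == n2.split.predictor
                assert n1.split.threshold == pytest.approx(n2.split.threshold)

    def test_serialization_round_trip(self, rng):
        Y = _scores(rng.standard_normal((30, 2)))
        X = _preds(a=rng.standard_normal(30), b=rng.standard_normal(30))
        model = fit_zonetree(Y, X, cp=0.01, min_node=3)
        back = ZoneTreeModel.from_dict(model.to_dict())
        assert back.to_dict() == model.to_dict()


class TestZoneCodesAndLevels:
    def _three_group_model(self):
        # x < 2.5 -> group 0; x < 4.5 -> group 1; else group 2
        Y = np.array([[0.0], [0.0], [5.0], [5.0], [11.0], [11.0]])
        X = _preds(x=[1.0, 2, 4, 4.2, 6, 7])
        return fit_zonetree(_scores(Y), X, cp=0.0, min_node=2,
                            level_cut_points=(2,))

    def test_two_split_tree_codes_abc(self):
        model = self._three_group_model()
        codes = [l.code for l in model.leaves()]
        assert codes == ["A", "B", "C"]

    def test_single_level_flattening(self):
        model = self._three_group_model()
        codes = zone_codes(model, level_cut_points=(12,))
        assert sorted(codes.values()) == ["A", "B", "C"]

    def test_hierarchical_codes_letter_digit(self, rng):
        # zones at two scales: coarse split on a, fine splits on b
        n = 40
        a = np.repeat([0.0, 10.0], n // 2) + rng.normal(0, .1, n)
        b = np.tile(np.repeat([0.0, 5.0], n // 4), 2) + rng.normal(0, .1, n)
        Y = np.column_stack([a * 3, b])
        X = _preds(a=a + rng.normal(0, .01, n), b=b + rng.normal(0, .01, n))
        model = fit_zonetree(_scores(Y), X, cp=0.001, min_node=5,
                             level_cut_points=(1, 3))
        codes = [l.code for l in model.leaves()]
        assert codes[0][0] in "AB"
        assert any(len(c) == 2 and c[1].isdigit() for c in codes)

    def test_nonincreasing_cut_points_rejected(self):
        model = self._three_group_model()
        with pytest.raises(ValueError, match="cut-points"):
            zone_codes(model, level_cut_points=(3, 2))

    def test_variance_fractions_sum_to_one(self, rng):
        Y = _scores(rng.standard_normal((40, 2)))
        X = _preds(a=rng.standard_normal(40), b=rng.standard_normal(40))
        model = fit_zonetree(Y, X, cp=0.0, min_node=4)
        fracs, resid = model.variance_by_level()
        assert sum(fracs) + resid == pytest.approx(1.0, abs=1e-8)
        assert all(f >= 0 for f in fracs)

    def test_single_dominant_split_level_fraction(self):
        Y = np.array([[0.0]] * 3 + [[10.0]] * 3)
        X = _preds(x=[1.0, 2, 3, 4, 5, 6])
        model = fit_zonetree(_scores(Y), X, cp=0.0, min_node=3)
        fracs, resid = model.variance_by_level()
        assert fracs[0] == pytest.approx(1.0)
        assert resid == pytest.approx(0.0, abs=1e-12)


class TestAssign:
    def test_training_populations_map_to_their_leaf(self, rng):
        n = 30
        Y = _scores(rng.standard_normal((n, 2)))
        X = _preds(a=rng.standard_normal(n), b=rng.standard_normal(n))
        model = fit_zonetree(Y, X, cp=0.01, min_node=3)
        for leaf in model.leaves():
            for pop in leaf.members:
                assert model.assign(X.loc[pop]) == leaf.code

    def test_boundary_value_goes_right(self):
        Y = np.array([[0.0], [0.0], [9.0], [9.0]])
        X = _preds(x=[1.0, 2.0, 3.0, 4.0])
        model = fit_zonetree(_scores(Y), X, cp=0.0, min_node=2)
        thr = model.root.split.threshold
        left_code = model.nodes[model.root.children[0]].code
        right_code = model.nodes[model.root.children[1]].code
        assert model.assign({"x": thr}) == right_code
        assert model.assign({"x": thr - 1e-9}) == left_code

    def test_missing_predictor_named_in_error(self):
        Y = np.array([[0.0], [0.0], [9.0], [9.0]])
        X = _preds(x=[1.0, 2.0, 3.0, 4.0])
        model = fit_zonetree(_scores(Y), X, cp=0.0, min_node=2)
        with pytest.raises(KeyError, match="x"):
            model.assign({"y": 1.0})


class TestZoneRecovery:
    def test_latent_zones_recovered_from_study(self, full_study):
        """End-to-end: the primary zones of a tree fitted on PCA scores
        recover the generative 3-zone structure."""
        from sklearn.metrics import adjusted_rand_score

        plants = full_study.plants
        gardens = sorted(plants["garden"].unique())
        means = {g: gc.population_means(plants, g)[0] for g in gardens}
        retained = [(t.name, g) for t in gc.DEFAULT_TRAITS for g in gardens]
        mat = gc.build_trait_matrix(means, retained)
        space = gc.fit_pca(mat)
        scores = pd.DataFrame(space.scores[:, :6], index=mat.index,
                              columns=[f"PC{i+1}" for i in range(6)])
        clim = full_study.climate[list(gc.CLIMATE_VARIABLES)]
        model = fit_zonetree(scores, clim, cp=0.015, min_node=5)
        truth = [full_study.truth.zones[p] for p in scores.index]
        primary = [model.assign(clim.loc[p])[0] for p in scores.index]
        assert adjusted_rand_score(truth, primary) >= 0.9
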