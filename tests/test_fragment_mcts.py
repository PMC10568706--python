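"""Outer fragment-wise search: UCB1, squashing, tree bookkeeping, outputs."""

import math

import numpy as np
import pytest

from fragopt.chem_graph import parse_smiles
from fragopt.fragment_mcts import (
    OptimizeConfig,
    RewardTransform,
    SearchNode,
    optimize,
    rank_and_report,
    ucb1,
)
from fragopt.scoring import FAILED_CONSTRAINT, get_score_function

QED = get_score_function("qed")


class TestUcb1:
    def test_unvisited_node_scores_infinity(self):
        assert ucb1(0.0, 0, 5) == math.inf

    def test_log_one_gives_pure_exploitation(self):
        assert ucb1(0.0, 1, 1, c=math.sqrt(2)) == 0.0

    def test_arithmetic_oracle(self):
        # 0.5 + 1 * sqrt(2 ln 2 / 1)
        expected = 0.5 + math.sqrt(2.0 * math.log(2.0))
        assert ucb1(0.5, 1, 2, c=1.0) == pytest.approx(expected, abs=1e-10)
        assert ucb1(0.5, 1, 2, c=1.0) == pytest.approx(1.6774, abs=1e-4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ucb1(0.0, -1, 3)

    def test_exploration_grows_with_parent_visits(self):
        assert ucb1(0.0, 2, 100) > ucb1(0.0, 2, 10)


class TestRewardTransform:
    def test_linear_unit_endpoints(self):
        t = RewardTransform("linear", 0.0, 1.0)
        assert t(0.0) == -1.0 and t(1.0) == 1.0 and t(0.5) == 0.0

    def test_tanh_is_odd_and_bounded(self):
        t = RewardTransform("tanh", scale=10.0)
        assert t(0.0) == 0.0
        assert -1 <= t(-1e6) < t(-3) < t(3) < t(1e6) <= 1

    def test_monotone_on_samples(self):
        for t in (RewardTransform("linear", -5, 5), RewardTransform("tanh")):
            xs = np.linspace(-20, 20, 101)
            ys = [t(x) for x in xs]
            assert all(a <= b for a, b in zip(ys, ys[1:]))
            assert all(-1 <= y <= 1 for y in ys)

    def test_failed_constraint_maps_to_minus_one(self):
        assert RewardTransform("linear")(FAILED_CONSTRAINT) == -1.0
        assert RewardTransform("tanh")(FAILED_CONSTRAINT) == -1.0

    def test_chosen_by_declared_range(self):
        assert RewardTransform.for_score(QED).kind == "linear"
        plogp = get_score_function("plogp")
        assert RewardTransform.for_score(plogp).kind == "tanh"

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            RewardTransform()(float("nan"))


class TestOptimize:
    def test_ring_only_seed_expands_by_addition_only(self, quick_model):
        results = optimize("c1ccccc1", QED, quick_model,
                           fragment_steps=1, atom_steps=20, rng=0)
        benzene = parse_smiles("c1ccccc1")
        # every output must be strictly larger: nothing can be removed
        for smiles, _ in results:
            assert parse_smiles(smiles).n_atoms > benzene.n_atoms

    def test_all_outputs_parse_and_satisfy_valence(self, quick_model):
        results = optimize("CC(=O)Nc1ccc(O)cc1", QED, quick_model,
                           fragment_steps=5, atom_steps=30, rng=1)
        assert results
        for smiles, _ in results:
            g = parse_smiles(smiles)
            assert g.is_connected() and g.is_valence_valid()

    def test_outputs_ranked_and_deduplicated(self, quick_model):
        results = optimize("CC(=O)Nc1ccc(O)cc1", QED, quick_model,
                           fragment_steps=5, atom_steps=30, rng=2)
        scores = [v for _, v in results]
        assert scores == sorted(scores, reverse=True)
        keys = [s for s, _ in results]
        assert len(keys) == len(set(keys))

    def test_saturated_seed_raises(self, quick_model):
        # dinitrogen: no single bond to cut, no free valence to grow on
        with pytest.raises(ValueError, match="expandable"):
            optimize("N#N", QED, quick_model,
                     fragment_steps=1, atom_steps=5, rng=0)

    def test_tree_bookkeeping_root_visits_and_means(self, quick_model,
                                                    monkeypatch):
        import fragopt.fragment_mcts as mod
        nodes = []
        orig = mod.SearchNode

        class Spy(orig):
            def __init__(self, *a, **kw):
                super().__init__(*a, **kw)
                nodes.append(self)

        monkeypatch.setattr(mod, "SearchNode", Spy)
        cycles = 8
        optimize("CC(=O)Nc1ccc(O)cc1", QED, quick_model,
                 fragment_steps=cycles, atom_steps=20, rng=3)
        root = nodes[0]
        assert root.parent is None
        assert root.visits == cycles
        for node in nodes:
            if node.visits:
                assert -1.0 <= node.mean <= 1.0

    def test_unvisited_children_selected_before_revisits(self):
        root = SearchNode(None, visits=3)
        visited = SearchNode(None, parent=root, value_sum=2.7, visits=3)
        fresh = SearchNode(None, parent=root, visits=0)
        root.children = [visited, fresh]
        best = max(root.children,
                   key=lambda ch: ucb1(ch.mean, ch.visits, root.visits))
        assert best is fresh

    def test_determinism_same_seed_same_results(self, quick_model):
        a = optimize("CC(=O)Nc1ccc(O)cc1", QED, quick_model,
                     fragment_steps=4, atom_steps=25, rng=11)
        b = optimize("CC(=O)Nc1ccc(O)cc1", QED, quick_model,
                     fragment_steps=4, atom_steps=25, rng=11)
        assert a == b

    def test_protected_substructure_never_removed(self, quick_model):
        # the amide must survive in every emitted molecule
        cfg = OptimizeConfig(protected_smarts="C(=O)N")
        results = optimize("CC(=O)Nc1ccc(O)cc1", QED, quick_model,
                           fragment_steps=6, atom_steps=20, cfg=cfg, rng=4)
        from rdkit import Chem
        patt = Chem.MolFromSmarts("C(=O)N")
        for smiles, _ in results:
            assert Chem.MolFromSmiles(smiles).HasSubstructMatch(patt)


class TestRankAndReport:
    def test_top_one_is_best(self, quick_model):
        results = [("CCO", 0.4), ("CCN", 0.6)]
        report = rank_and_report(sorted(results, key=lambda r: -r[1]),
                                 "CCO", top_k=1)
        assert len(report) == 1
        assert report.iloc[0]["smiles"] == "CCN"

    def test_similarity_in_unit_interval_and_identity(self):
        results = [("CCO", 1.0), ("Cc1ccccc1", 0.5)]
        report = rank_and_report(results, "CCO", top_k=2)
        assert report.iloc[0]["similarity"] == 1.0
        assert all(0 <= s <= 1 for s in report["similarity"])

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            rank_and_report([], "CCO")
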