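"""Generator model: encoding invariances, masked sampling, training."""

import numpy as np
import pytest
from rdkit import Chem

from fragopt.chem_graph import (
    DEFAULT_BONDS,
    DEFAULT_VOCAB,
    MolGraph,
    free_valence,
    parse_smiles,
)
from fragopt.dataset import serialize_fragment
from fragopt.gcn_model import (
    GeneratorModel,
    ModelConfig,
    Proposal,
    TrainConfig,
    apply_proposal,
    init_params,
    train,
)


@pytest.fixture(scope="module")
def untrained():
    cfg = ModelConfig()
    return GeneratorModel(init_params(cfg, seed=5), cfg)


class TestEncode:
    def test_empty_graph_encodes_to_zero(self, untrained):
        _, h_g = untrained.encode(MolGraph())
        assert np.allclose(h_g, 0.0)

    def test_single_atom_graph_state_equals_node_state(self, untrained):
        h_n, h_g = untrained.encode(parse_smiles("C"))
        assert np.allclose(h_g, h_n[0])

    def test_permutation_invariance_of_graph_state(self, untrained):
        g = parse_smiles("CC(=O)Nc1ccccc1")
        # reversed atom numbering of the same molecule
        n = g.n_atoms
        perm = list(reversed(range(n)))
        g2 = MolGraph([g.atoms[perm[i]] for i in range(n)],
                      {(min(perm.index(i), perm.index(j)),
                        max(perm.index(i), perm.index(j))): o
                       for (i, j), o in g.bonds.items()})
        _, h1 = untrained.encode(g)
        _, h2 = untrained.encode(g2)
        assert np.allclose(h1, h2, atol=1e-4)

    def test_fast_inference_matches_training_forward(self, untrained):
        """The float32 inference path reproduces the autodiff forward."""
        from fragopt.autodiff import no_grad
        from fragopt.dataset import GenerationStep
        from fragopt.gcn_model import _Batch, _encode_batch

        g = parse_smiles("CC(=O)Nc1ccc(O)cc1")
        h_n, h_g = untrained.encode(g)
        batch = _Batch([GenerationStep(g, DEFAULT_VOCAB.stop_label, [])],
                       untrained.cfg, DEFAULT_VOCAB, DEFAULT_BONDS)
        with no_grad():
            tn, tg = _encode_batch(untrained.params, untrained.cfg, batch)
        assert np.allclose(h_n, tn.data, atol=1e-3)
        assert np.allclose(h_g, tg.data[0], atol=1e-3)


class TestHeads:
    def test_atom_probabilities_sum_to_one(self, untrained):
        p = untrained.atom_distribution(parse_smiles("CCO"))
        assert p.shape == (10,)
        assert np.all(p >= 0) and abs(p.sum() - 1) < 1e-6

    def test_bond_probabilities_one_row_per_existing_atom(self, untrained):
        g = parse_smiles("CCO")
        probs = untrained.bond_distribution(g, atom_label=0)
        assert probs.shape == (3, 4)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_bond_head_rejects_stop_label(self, untrained):
        with pytest.raises(ValueError):
            untrained.bond_distribution(parse_smiles("C"),
                                        DEFAULT_VOCAB.stop_label)


class TestMaskedSampling:
    def test_saturated_atoms_never_receive_bonds(self, untrained):
        """10^3 sampled steps on molecules with saturated atoms stay valid."""
        rng = np.random.default_rng(0)
        g = parse_smiles("FC(F)(F)c1ccccc1")  # CF3 carbon is saturated
        sat = [i for i in range(g.n_atoms) if free_valence(g, i) == 0]
        assert sat
        for _ in range(100):
            prop = untrained.sample_step(g, rng)
            if prop is None:
                continue
            for u in sat:
                assert prop.bond_labels[u] == DEFAULT_BONDS.none_label
            assert apply_proposal(g, prop).is_valence_valid()

    def test_sampling_never_violates_valence(self, untrained, random_molecules):
        rng = np.random.default_rng(1)
        checked = 0
        for s in random_molecules[:60]:
            g = parse_smiles(s)
            for _ in range(5):
                prop = untrained.sample_step(g, rng)
                if prop is None:
                    continue
                out = apply_proposal(g, prop)
                assert out.is_valence_valid() and out.is_connected()
                checked += 1
        assert checked > 100

    def test_fully_masked_state_forces_stop(self, untrained):
        g = parse_smiles("FC(F)(F)F")  # every atom saturated
        rng = np.random.default_rng(2)
        assert all(untrained.sample_step(g, rng) is None for _ in range(20))

    def test_greedy_mode_is_deterministic(self, untrained):
        g = parse_smiles("CCO")
        a = untrained.sample_step(g, greedy=True)
        b = untrained.sample_step(g, greedy=True)
        if a is None:
            assert b is None
        else:
            assert (a.atom_label, a.bond_labels) == (b.atom_label, b.bond_labels)

    def test_top_proposals_ranked_and_masked(self, untrained):
        g = parse_smiles("CCO")
        props = untrained.top_proposals(g, k=5)
        assert len(props) == 5
        assert all(props[i].prob >= props[i + 1].prob for i in range(4))
        for p in props:
            if p.atom_label != DEFAULT_VOCAB.stop_label:
                assert apply_proposal(g, p).is_valence_valid()


class TestTraining:
    def test_loss_decreases_on_toy_corpus(self, corpus_records):
        frags = [r.graph for r in corpus_records[:50]]
        steps = [s for f in frags for s in serialize_fragment(f)]
        result = train(steps, TrainConfig(learning_rate=1e-3, batch_size=32,
                                          epochs=8, eval_epoch=8, seed=0))
        first, last = result.history[0], result.history[-1]
        assert last["train_loss"] < 0.5 * first["train_loss"]

    def test_same_seed_identical_final_loss(self, tiny_fragment_records):
        steps = [s for r in tiny_fragment_records[:5]
                 for s in serialize_fragment(r.graph)]
        cfg = TrainConfig(learning_rate=1e-3, batch_size=8, epochs=2,
                          eval_epoch=2, seed=9)
        a = train(steps, cfg).history[-1]["train_loss"]
        b = train(steps, cfg).history[-1]["train_loss"]
        assert a == b

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig(epochs=1))

    def test_stop_steps_have_no_bond_loss_term(self):
        """A corpus of single atoms trains on atom labels only."""
        steps = serialize_fragment(parse_smiles("C"))
        result = train(steps, TrainConfig(learning_rate=5e-3, batch_size=2,
                                          epochs=30, eval_epoch=30, seed=0))
        # perfectly learnable: the only labels are C then stop
        p0 = result.model.atom_distribution(MolGraph())
        p1 = result.model.atom_distribution(parse_smiles("C"))
        assert int(np.argmax(p0)) == DEFAULT_VOCAB.index("C")
        assert int(np.argmax(p1)) == DEFAULT_VOCAB.stop_label


class TestPersistence:
    def test_checkpoint_round_trip(self, untrained, tmp_path):
        path = tmp_path / "model.npz"
        untrained.save(path)
        back = GeneratorModel.load(path)
        g = parse_smiles("CCO")
        assert np.allclose(untrained.atom_distribution(g),
                           back.atom_distribution(g))

    def test_vocab_mismatch_refused(self, untrained, tmp_path):
        from fragopt.chem_graph import AtomVocab
        path = tmp_path / "model.npz"
        untrained.save(path)
        other = AtomVocab(("C", "N", "O", "F", "P", "S", "Cl", "Br", "B"),
                          (4, 3, 2, 1, 5, 6, 1, 1, 3))
        with pytest.raises(ValueError, match="vocabulary"):
            GeneratorModel.load(path, expect_vocab=other)
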