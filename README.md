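# fragopt

Fragment-wise Monte Carlo tree search for molecular lead optimization.

## The problem

Lead optimization starts from a specific molecule and asks for close
relatives that score better on some objective — drug-likeness, a
property like penalized logP, or a predicted activity.  Methods that
generate SMILES strings token-by-token can emit unparseable strings and
drift far from the starting structure.  `fragopt` instead edits the
molecular *graph* directly: an outer Monte Carlo tree search removes
and adds whole fragments through single bonds, and each added fragment
is grown atom-by-atom by an inner tree search guided by a graph-network
generator trained on a fragment corpus.  Because every edit is a
valence-checked graph operation, **every molecule the search emits is
chemically valid** (validity ≡ 1), and because edits are local, results
stay similar to the seed.

## The method in brief

Both searches select nodes by the UCB1 rule

    x̄ + c · sqrt(2 · ln(n_p) / n)

(mean reward x̄, node visits n, parent visits n_p, c = √2; unvisited
nodes first).  The outer search expands a molecule by (a) every
fragment removal — cut a disconnecting single bond, keep the larger
component — and (b) fragment additions produced by the inner search at
a random free-valence atom, filtered ε-greedily by score.  New children
are scored by the evaluation function directly (no rollout — an
arbitrary starting molecule has no terminal state) and the maximum
child reward, squashed into [−1, 1], is backpropagated.

The inner search grows a fragment from the empty graph, one atom and
its bonds per step, using a trained generator: a 6-layer
message-passing encoder (128-dim, bond-order-conditioned messages, sum
pooling) feeding an atom head (softmax over 9 elements + stop) and a
GRU bond head (softmax over single/double/triple/none per existing
atom, BFS order).  Sampling is valence-masked; generation stops on the
stop label or an all-"none" bond step.  Completed fragments are
attached to the parent and the attached molecule's score is the reward.

The generator trains on fragments obtained by cutting every ring/
non-ring bond of a corpus molecule (teacher-forced cross-entropy on
BFS-serialized steps, Adam).  See `docs/methods.md` for the full
account.

## Worked example

```bash
cd examples
python 01_build_fragment_corpus.py   # corpus -> 377 unique fragments
python 02_train_generator.py         # ~3 min: writes generator.npz
python 04_optimize_qed.py            # optimize paracetamol's QED
```

`04_optimize_qed.py` prints (numbers from this exact run):

```
seed CC(=O)Nc1ccc(O)cc1: QED 0.595
148 molecules generated; top 5:
 rank                                    smiles score similarity
    1 CC(=O)N(CCF)c1ccc(O)c(C2CC3(C2)CC2CC23)c1 0.923       0.16
    2      CC(=O)N(CC1(OCl)CC1C(C)C)c1ccc(O)cc1 0.907       0.24
    3        CC(=O)N(CC1(C)CC1C(C)C)c1ccc(O)cc1 0.902       0.27
    4       COC1(CN(C(C)=O)c2ccc(O)cc2)CC1C(C)C 0.900       0.26
    5           CC(=O)N(CC1CC1C(C)C)c1ccc(O)cc1 0.888       0.28
```

The seed (paracetamol) has QED 0.595; in 20 fragment-wise steps of 100
atom-wise steps each, the search raises the best QED above 0.92.
Scores are plain RDKit QED values; similarity is the ECFP4 Tanimoto
coefficient to the seed.  At this desk scale — a 500-molecule training
corpus — similarities are modest; full-scale training pushes generated
fragments toward common chemotypes and keeps analogues closer to the
seed.

The same machinery runs from the shell:

```bash
fragopt train --corpus molecules.smi --checkpoint model.npz --epochs 20
fragopt optimize --checkpoint model.npz --seed-smiles "CC(=O)Nc1ccc(O)cc1" \
        --score qed --fragment-steps 20 --atom-steps 100 --seed 7 --out out.csv
fragopt metrics --generated out.csv --corpus molecules.smi
```

Scores: `qed`, `plogp` (logP − SA − ring penalty), `plogp_sim`
(similarity-constrained), or `custom:<file.py>` exposing
`score(smiles) -> float` — the route for external activity predictors.

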