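# Methods

`fragopt` optimizes a given molecule against an arbitrary scalar
evaluation function by editing its graph fragment-by-fragment.  Two
nested Monte Carlo tree searches do the work: an outer search over
molecules whose actions remove or add fragments through single bonds,
and an inner search that grows each added fragment atom-by-atom, guided
by a learned graph-network generator.  Because every edit goes through
valence-checked graph operations, every molecule the method ever emits
is chemically valid by construction (validity ≡ 1) — the structural
property that distinguishes graph-based editing from string-based
(SMILES) generation, where a large share of sampled strings fail to
parse.

## Molecular graph model

Molecules are kekulized heavy-atom graphs: atoms are indices into a
9-element vocabulary (C, N, O, F, P, S, Cl, Br, I — the conventional
drug-like screening set), bonds carry integer orders 1/2/3, and
hydrogens are implicit.  An atom's free valence is its element's maximum
valence (C 4, N 3, O 2, F 1, P 5, S 6, Cl 1, Br 1, I 1) minus its
heavy-bond order sum.  Formal charges, stereochemistry and isotopes are
stripped on input: the generator's node features are plain atom-type
one-hots, so none of these attributes could inform it.  Molecules whose
charge-stripped form violates valence (e.g. nitro groups written as
N⁺/O⁻) are rejected on parsing and skipped (logged) during corpus
construction.  Parsing renumbers atoms by RDKit's canonical ranking, so
"atom 0" of any parsed graph is a deterministic canonical root.

There is no aromatic bond type anywhere: aromatic rings are represented
as Kekulé structures with alternating single/double bonds, which keeps
the bond-prediction head at 4 classes (single, double, triple, none).

## Fragment corpus

The generator trains on fragments, not whole molecules.  A molecule is
fragmented by cutting every bond that joins a ring atom to a non-ring
atom (ring membership by the parent molecule's SSSR rings); connected
components are the fragments, with open valences filled by implicit
hydrogens rather than attachment-point dummy atoms — the generator must
emit plain molecules.  Bonds between two ring atoms or two non-ring
atoms are never cut, so an ethyl substituent stays intact and biphenyl
stays whole.  Across a corpus, fragments are deduplicated by canonical
SMILES; the number of source molecules per fragment is retained
(`source_count`) as a frequency weight for analysis, though training
uses each unique fragment once.  Fragments above `max_atoms`
(default 15) are dropped and logged.

On the bundled 500-molecule fixture this yields 377 unique fragments of
7.5 ± 3.6 heavy atoms (MW 113 ± 51); a 250k-molecule screening corpus
yields tens of thousands of fragments of ~10.6 ± 3.2 atoms, so the
15-atom cap covers the realistic range with >1 SD of headroom.

## Serialization and training

Each fragment becomes `n_atoms + 1` supervised steps by BFS order from
canonical atom 0 (frontier ties broken by ascending index).  Step *t*
presents the induced subgraph on the first *t* atoms; targets are the
element of atom *t* and, for each existing atom in BFS order, the order
of its bond to the new atom ("none" if absent).  The final step carries
the stop label.  Step 0 has the empty graph as state (encoded as a zero
vector), so the first atom of a fragment is modeled too.  Replaying the
steps reconstructs the fragment exactly; this round trip is asserted
over the whole corpus in the test suite.  One canonical serialization
per fragment is used (no BFS-root augmentation) to keep training
desk-scale; augmentation over random roots is a config switch away in
principle but not enabled anywhere.

The generator has three parts:

1. **Encoder** — six message-passing layers over the state graph.  Each
   layer computes `h_i' = ReLU(W_self h_i + b + Σ_j c_ji W_{t(ji)} h_j)`
   where the sum runs over bonded neighbors, `t(ji)` is the bond order
   of edge j–i (each order has its own weight matrix — this is how the
   3-dimensional edge features enter), and `c_ji = 1/√(deg_j · deg_i)`
   is the symmetric degree normalization.  Hidden width 128.  Sum
   pooling over nodes yields the 128-dim graph state `h_g`.  A plain
   order-blind convolution is available behind
   `ModelConfig(edge_conditioned=False)`.
2. **Atom head** — two fully connected layers (hidden 64, ReLU) from
   `h_g` to a 10-way softmax (9 elements + stop).
3. **Bond head** — a 2-layer GRU with 256-dim state, initialized from a
   linear projection of `[Emb(atom); h_g]` (atom embedding 64-dim), fed
   the node hidden states in BFS order, emitting a 4-way softmax per
   existing atom through a 64-hidden FC head.  Both GRU layers start
   from the same projected state.

Training is teacher-forced: the bond head receives the label atom, not
the atom head's prediction.  The loss of one step is its atom
cross-entropy plus the sum of its bond cross-entropies (no bond term for
stop steps); batches average this over their steps.  Optimization is
Adam (lr 1e-4, batch 128) with global-norm gradient clipping at 5.0 and
no schedule.  The full-scale recipe trains 50 epochs and uses the
epoch-20 parameters for search; desk-scale runs in this repository train
20 epochs directly.  Fragments (not steps) are split 4:1 into
train/test so all steps of a fragment land on one side.

The network and its gradients are implemented on a small in-repo
reverse-mode autodiff core (`fragopt.autodiff`) — dense ops, row
gather/scatter for message passing, fused softmax cross-entropy —
verified against central finite differences to ~1e-9 relative error.
Inference runs a separate plain-NumPy forward path with float32 weight
copies (tree search calls the model tens of thousands of times on tiny
graphs, where autodiff bookkeeping would dominate); a test asserts the
two paths agree.

## Sampling and the terminal rule

A generation step samples an atom label, then bond labels sequentially
over existing atoms in BFS order under a running valence mask: a bond
order is masked out if it exceeds the free valence of the existing atom
or the remaining valence of the new atom (decremented as bonds
accumulate within the step).  "None" is always available.  The state is
terminal when the atom head emits the stop label **or** every bond label
comes out "none" — the two terminal conditions of the method; the
all-none rule also covers dead ends where the mask forbids every bond.

## Inner search (atom-wise)

Grows one fragment for a given parent molecule and attachment site.
Nodes hold partial fragments (root = empty graph).  Per cycle:
selection by UCB1 (`x̄ + c√(2 ln n_p / n)`, unvisited first, c = √2);
expansion adds up to k = 5 children from the generator's ranked
proposals (one greedy-bond candidate per element plus the stop
proposal, ranked by joint probability, valence-masked); rollout
completes the best new child by sampling at temperature 1.0 until
terminal, hard-capped at 15 atoms; the completed fragment is attached
to the parent — fragment side, its first generated atom; parent side,
the site chosen by the outer search — and the evaluation of the
attached molecule, squashed to [−1, 1], is backpropagated with one
visit per node on the path.  The model conditions only on the growing
fragment, not the parent: it was trained on isolated fragments, and
feeding it parent context it never saw during training would put it off
distribution.  An empty fragment (immediate stop) backpropagates the
parent's own squashed score and contributes no output; a fragment whose
first atom is saturated cannot be attached and backpropagates −1.
Every scored molecule is recorded; the search returns them
deduplicated, ranked by raw score.

## Outer search (fragment-wise)

Nodes hold whole molecules (root = the starting molecule).  Per cycle:

1. **Selection** by the same UCB1 rule to a leaf.
2. **Expansion** — removal children: for every single bond whose
   deletion splits the molecule, the component with more atoms (ties:
   lexicographically smaller canonical SMILES, for determinism);
   addition children: one inner search at a uniformly random
   free-valence atom, filtered ε-greedily (ε = 0.2: with probability
   0.8 keep the top-5 by raw score, else 5 random).
3. **Evaluation** — each new child is scored by the evaluation function
   directly.  There is no rollout: an arbitrary starting molecule has
   no natural terminal state, and deep rollouts would drift from the
   seed, against the purpose of lead optimization.
4. **Backpropagation** — the maximum squashed child reward is added
   along the root path, one visit per node.

Rewards are squashed into [−1, 1] before backpropagation: scorers with
a declared [0, 1] range (QED, activity models) map linearly (2r − 1);
unbounded scorers (penalized logP) go through tanh(r/10).  The
constraint sentinel −inf maps to −1.

All children ever added are emitted, deduplicated by canonical SMILES
and ranked by raw score (the seed itself is excluded).  An optional
protected-substructure mask (SMARTS) drops any removal child that no
longer contains the pattern, so structures known to matter are never
cut away.  A seed with no disconnecting single bond and no free valence
(e.g. N₂) raises a no-expandable-edit error.

Experiment presets mirror the reference protocols: unconstrained QED
runs 20 fragment-wise × 100 atom-wise steps; constrained penalized-logP
and activity runs use 2 × 100.  The constrained similarity threshold
defaults to δ = 0.4 (configurable).

## Scoring

* `qed` — RDKit's QED, range [0, 1].
* `plogp` — Crippen logP − SA score (RDKit contrib) − largest-ring
  penalty (atoms beyond six in the largest ring), unnormalized.  Some
  literature z-scores the three terms against a reference corpus; the
  unnormalized difference is used here and the transform handles its
  unbounded range.
* `plogp_sim` — penalized logP gated by ECFP4 (radius 2, 2048 bits)
  Tanimoto ≥ δ to the seed.
* `custom:<path.py>` — any file exposing `score(smiles) -> float`; this
  is the route for external activity predictors, which are deliberately
  not bundled.

All scorers are pure functions of the canonical SMILES and are cached.

## Synthetic data and what it does not show

The bundled corpus (`data/druglike_synthetic_500.smi`) is a constructed
stand-in for a large public screening library: ~80 well-known drug
structures plus seeded output of the procedural generator, which
assembles molecules from common ring systems (benzene, pyridine,
pyrrole, thiophene, furan, saturated N/O heterocycles) and single-atom
growth with drug-like element frequencies, 8–25 heavy atoms, all
valence-checked.  It reproduces the *structural* regime of drug-like
chemistry — ring/chain mixture, element ratios, fragment sizes — which
is what the fragmenter, serializer and generator consume.  It does not
carry real bioactivity, real physicochemical property distributions, or
the chemotype diversity of a 250k-molecule library; consequently,
passing tests demonstrate the machinery (validity, reconstruction,
improvement direction), not the absolute objective values reachable
with full-scale training, which require the real corpus and hundreds of
seeds.

## Numerical and design choices

* Encoder activation ReLU throughout (stated for the heads; assumed for
  the encoder).  GRU initial-state projection is linear.
* Desk-scale problem sizes: 500-molecule corpus → 377 fragments → ~3.2k
  steps; 20 training epochs; 10 seeds × 20 × 100 search steps.  Chosen
  so the full pipeline runs in minutes on one CPU.
* The tiny-overfit recipe (≤10 fragments) scales the optimizer to
  lr 3e-3, batch 8 for 20 epochs: the full-scale settings would give
  only ~20 parameter updates on so small a set.  Recovery is checked
  distributionally — 300 samples must regenerate ≥9/10 training
  fragments exactly — because deterministic greedy decoding cannot
  reproduce ten different fragments from the single shared empty-state
  root (fragments that are prefixes of one another need both "stop" and
  "continue" from identical states).
* Checkpoints are self-describing (.npz with config, vocabulary and its
  fingerprint); loading refuses a mismatched vocabulary.
* Determinism: all randomness flows through a single
  `numpy.random.Generator`; identical seed and configuration reproduce
  identical outputs bit-for-bit (asserted for the CLI CSV).

## Known limitations

* Fragment attachment uses only single bonds, and fragments attach by
  their first generated atom; complex fused-ring growth is out of reach
  of the edit set (a property shared with the method itself, which
  trades diversity for similarity to the seed).
* The inner search proposes one candidate per element per expansion
  (greedy bonds), not the full joint (atom × bond-sequence) top-k,
  which is exponential.
* No retrosynthesis or synthesizability filtering beyond the SA term in
  penalized logP; no 3-D structure, charges, stereochemistry or
  isotopes.
* Training at 250k-molecule scale is supported by configuration but not
  exercised here.
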