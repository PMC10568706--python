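"""The three-part fragment generator: encoder, atom head, bond head.

Architecture
------------
* **Feature extraction** — a 6-layer message-passing network over the
  molecular graph.  Node features are 9-dim atom-type one-hots; edge
  features are 3-dim bond-order one-hots, consumed by giving each bond
  order its own message weight matrix (a plain symmetric-normalised
  graph convolution, which ignores bond orders, is available behind
  ``ModelConfig.edge_conditioned=False``).  Messages are normalised by
  1/sqrt(deg_j * deg_i); sum pooling over node states yields the
  128-dim graph state ``h_g``.  The empty graph encodes to ``h_g = 0``,
  so the very first atom of a fragment is modelled too.
* **Atom prediction** — two fully connected layers (hidden 64, ReLU)
  from ``h_g`` to a 10-way softmax: nine elements plus the "empty atom"
  stop label.
* **Bond prediction** — a 2-layer GRU whose initial state is a linear
  projection of ``[Emb(atom); h_g]`` to 256 dims, fed the node hidden
  states in BFS order, emitting a 4-way softmax per existing atom
  (single/double/triple/no-bond) through a 64-hidden FC head.

Training is teacher-forced: the bond head always receives the *label*
atom, never the atom head's output.  Losses are per-label cross
entropies; a step's loss is its atom term plus the sum of its bond
terms, averaged over the steps in a batch.  Optimisation is Adam with
global-norm gradient clipping.

Sampling applies valence masks so a generated step can never exceed the
maximum valence of either bond endpoint; the terminal conditions are
"stop label sampled" or "no bond sampled for any existing atom".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, no_grad
from .chem_graph import (
    AtomVocab,
    BondVocab,
    DEFAULT_BONDS,
    DEFAULT_VOCAB,
    MolGraph,
    free_valence,
)
from .dataset import GenerationStep

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "Proposal",
    "GeneratorModel",
    "TrainResult",
    "train",
    "apply_proposal",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults are the full-scale model)."""

    mpnn_layers: int = 6
    hidden_dim: int = 128
    atom_hidden: int = 64
    bond_gru_layers: int = 2
    gru_state_dim: int = 256
    atom_embed_dim: int = 64
    bond_hidden: int = 64
    node_feature_dim: int = 9
    edge_feature_dim: int = 3
    atom_out_dim: int = 10
    bond_out_dim: int = 4
    edge_conditioned: bool = True

    def validate(self, vocab: AtomVocab, bonds: BondVocab) -> None:
        if self.atom_out_dim != vocab.n_labels:
            raise ValueError("atom_out_dim must equal |elements| + 1")
        if self.bond_out_dim != bonds.n_labels:
            raise ValueError("bond_out_dim must equal |orders| + 1")
        if self.node_feature_dim != len(vocab.elements):
            raise ValueError("node_feature_dim must equal |elements|")
        if self.edge_feature_dim != len(bonds.orders):
            raise ValueError("edge_feature_dim must equal |orders|")


@dataclass
class TrainConfig:
    """Optimisation settings (defaults follow the full-scale recipe)."""

    learning_rate: float = 1e-4
    batch_size: int = 128
    epochs: int = 50
    eval_epoch: int = 20
    seed: int = 0
    grad_clip: float = 5.0

    def __post_init__(self):
        for name in ("learning_rate", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Proposal:
    """One sampled/ranked generation step: an atom and its bonds."""

    atom_label: int
    bond_labels: list[int] = field(default_factory=list)
    prob: float = 1.0

    def is_stop(self, vocab: AtomVocab, bonds: BondVocab, state_nonempty: bool) -> bool:
        if self.atom_label == vocab.stop_label:
            return True
        if state_nonempty and all(b == bonds.none_label for b in self.bond_labels):
            return True
        return False


def _glorot(rng, fan_in, fan_out, shape=None):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape or (fan_in, fan_out))


def init_params(cfg: ModelConfig, seed: int = 0) -> dict[str, Tensor]:
    rng = np.random.default_rng(seed)
    P: dict[str, Tensor] = {}
    H, S = cfg.hidden_dim, cfg.gru_state_dim
    din = cfg.node_feature_dim
    for l in range(cfg.mpnn_layers):
        P[f"enc{l}.Wself"] = ad.parameter(_glorot(rng, din, H))
        P[f"enc{l}.b"] = ad.parameter(np.zeros(H))
        if cfg.edge_conditioned:
            for t in range(cfg.edge_feature_dim):
                P[f"enc{l}.W{t}"] = ad.parameter(_glorot(rng, din, H))
        else:
            P[f"enc{l}.Wnb"] = ad.parameter(_glorot(rng, din, H))
        din = H
    P["atom.W1"] = ad.parameter(_glorot(rng, H, cfg.atom_hidden))
    P["atom.b1"] = ad.parameter(np.zeros(cfg.atom_hidden))
    P["atom.W2"] = ad.parameter(_glorot(rng, cfg.atom_hidden, cfg.atom_out_dim))
    P["atom.b2"] = ad.parameter(np.zeros(cfg.atom_out_dim))
    P["bond.E"] = ad.parameter(
        rng.normal(0, 0.1, size=(cfg.atom_out_dim, cfg.atom_embed_dim)))
    P["bond.P"] = ad.parameter(_glorot(rng, cfg.atom_embed_dim + H, S))
    P["bond.p"] = ad.parameter(np.zeros(S))
    din = H
    for l in range(cfg.bond_gru_layers):
        P[f"gru{l}.Wx"] = ad.parameter(_glorot(rng, din, S, (din, 3 * S)))
        P[f"gru{l}.Uzr"] = ad.parameter(_glorot(rng, S, S, (S, 2 * S)))
        P[f"gru{l}.Uh"] = ad.parameter(_glorot(rng, S, S))
        P[f"gru{l}.bzr"] = ad.parameter(np.zeros(2 * S))
        P[f"gru{l}.bh"] = ad.parameter(np.zeros(S))
        din = S
    P["bondout.W1"] = ad.parameter(_glorot(rng, S, cfg.bond_hidden))
    P["bondout.b1"] = ad.parameter(np.zeros(cfg.bond_hidden))
    P["bondout.W2"] = ad.parameter(_glorot(rng, cfg.bond_hidden, cfg.bond_out_dim))
    P["bondout.b2"] = ad.parameter(np.zeros(cfg.bond_out_dim))
    return P


# ---------------------------------------------------------------------------
# Batched forward pass
# ---------------------------------------------------------------------------

class _Batch:
    """Block-diagonal packing of the state graphs of a list of steps."""

    def __init__(self, steps: list[GenerationStep], cfg: ModelConfig,
                 vocab: AtomVocab, bonds: BondVocab):
        self.steps = steps
        B = len(steps)
        node_rows, graph_id, offsets = [], [], []
        n = 0
        for b, st in enumerate(steps):
            offsets.append(n)
            for a in st.state.atoms:
                row = np.zeros(cfg.node_feature_dim)
                row[a] = 1.0
                node_rows.append(row)
                graph_id.append(b)
            n += st.state.n_atoms
        self.n_nodes = n
        self.n_graphs = B
        self.x = (np.asarray(node_rows) if node_rows
                  else np.zeros((0, cfg.node_feature_dim)))
        self.graph_id = np.asarray(graph_id, dtype=np.intp)
        # directed edges grouped by bond type, with symmetric normalisation
        src = {t: [] for t in range(len(bonds.orders))}
        dst = {t: [] for t in range(len(bonds.orders))}
        coeff = {t: [] for t in range(len(bonds.orders))}
        for b, st in enumerate(steps):
            off = offsets[b]
            deg = [max(st.state.degree(i), 1) for i in range(st.state.n_atoms)]
            for (i, j), o in st.state.bonds.items():
                t = bonds.orders.index(o)
                c = 1.0 / np.sqrt(deg[i] * deg[j])
                for a, bb in ((i, j), (j, i)):
                    src[t].append(off + a)
                    dst[t].append(off + bb)
                    coeff[t].append(c)
        self.edges = [
            (np.asarray(src[t], dtype=np.intp), np.asarray(dst[t], dtype=np.intp),
             np.asarray(coeff[t]))
            for t in range(len(bonds.orders))
        ]
        self.atom_labels = np.asarray([st.atom_label for st in steps], dtype=np.intp)
        # bond-head subproblem: non-stop steps with at least one existing atom
        rows = [b for b, st in enumerate(steps)
                if st.atom_label != vocab.stop_label and st.state.n_atoms > 0]
        self.bond_rows = np.asarray(rows, dtype=np.intp)
        if rows:
            L = max(steps[b].state.n_atoms for b in rows)
            idx = np.full((len(rows), L), n, dtype=np.intp)  # n = pad row
            lab = np.zeros((len(rows), L), dtype=np.intp)
            msk = np.zeros((len(rows), L))
            for r, b in enumerate(rows):
                st = steps[b]
                k = st.state.n_atoms
                idx[r, :k] = offsets[b] + np.arange(k)
                lab[r, :k] = st.bond_labels
                msk[r, :k] = 1.0
            self.seq_idx, self.seq_labels, self.seq_mask = idx, lab, msk
        else:
            self.seq_idx = np.zeros((0, 0), dtype=np.intp)
            self.seq_labels = np.zeros((0, 0), dtype=np.intp)
            self.seq_mask = np.zeros((0, 0))


def _encode_batch(params, cfg: ModelConfig, batch: _Batch):
    """Run message passing; return (h_nodes, h_graph) Tensors."""
    if batch.n_nodes == 0:
        h_n = Tensor(np.zeros((0, cfg.hidden_dim)))
        h_g = Tensor(np.zeros((batch.n_graphs, cfg.hidden_dim)))
        return h_n, h_g
    h = Tensor(batch.x)
    for l in range(cfg.mpnn_layers):
        pre = ad.add(ad.matmul(h, params[f"enc{l}.Wself"]), params[f"enc{l}.b"])
        for t, (src, dst, coeff) in enumerate(batch.edges):
            if len(src) == 0:
                continue
            w = (params[f"enc{l}.W{t}"] if cfg.edge_conditioned
                 else params[f"enc{l}.Wnb"])
            msg = ad.matmul(ad.scale_rows(ad.gather_rows(h, src), coeff), w)
            pre = ad.add(pre, ad.scatter_add_rows(msg, dst, batch.n_nodes))
        h = ad.relu(pre)
    h_g = ad.scatter_add_rows(h, batch.graph_id, batch.n_graphs)
    return h, h_g


def _atom_logits(params, h_g: Tensor) -> Tensor:
    hidden = ad.relu(ad.add(ad.matmul(h_g, params["atom.W1"]), params["atom.b1"]))
    return ad.add(ad.matmul(hidden, params["atom.W2"]), params["atom.b2"])


def _gru_cell(params, l: int, x: Tensor, hprev: Tensor, S: int) -> Tensor:
    xz, xr, xh = ad.split(ad.matmul(x, params[f"gru{l}.Wx"]), [S, S, S], axis=-1)
    hz, hr = ad.split(
        ad.add(ad.matmul(hprev, params[f"gru{l}.Uzr"]), params[f"gru{l}.bzr"]),
        [S, S], axis=-1)
    z = ad.sigmoid(ad.add(xz, hz))
    r = ad.sigmoid(ad.add(xr, hr))
    cand = ad.tanh(ad.add(ad.add(xh, ad.matmul(ad.mul(r, hprev),
                                               params[f"gru{l}.Uh"])),
                          params[f"gru{l}.bh"]))
    # h' = (1 - z) * hprev + z * cand
    return ad.add(hprev, ad.mul(z, ad.sub(cand, hprev)))


def _bond_logit_sequence(params, cfg: ModelConfig, h_n: Tensor, h_g_rows: Tensor,
                         atom_labels, seq_idx) -> list[Tensor]:
    """Per-position bond logits for a padded batch of BFS node sequences.

    ``h_g_rows`` are the graph states of the bond-head rows; ``atom_labels``
    the teacher-forced (or sampled) new-atom labels; ``seq_idx`` the padded
    (B', L) global node indices, padding pointing at an all-zero row.
    """
    S = cfg.gru_state_dim
    emb = ad.gather_rows(params["bond.E"], np.asarray(atom_labels, dtype=np.intp))
    s0 = ad.add(ad.matmul(ad.concat([emb, h_g_rows], axis=-1), params["bond.P"]),
                params["bond.p"])
    states = [s0 for _ in range(cfg.bond_gru_layers)]
    h_ext = ad.concat([h_n, Tensor(np.zeros((1, cfg.hidden_dim)))], axis=0)
    logits_per_t = []
    for t in range(seq_idx.shape[1]):
        x = ad.gather_rows(h_ext, seq_idx[:, t])
        for l in range(cfg.bond_gru_layers):
            states[l] = _gru_cell(params, l, x, states[l], S)
            x = states[l]
        hid = ad.relu(ad.add(ad.matmul(x, params["bondout.W1"]),
                             params["bondout.b1"]))
        logits_per_t.append(ad.add(ad.matmul(hid, params["bondout.W2"]),
                                   params["bondout.b2"]))
    return logits_per_t


def _loss_on_batch(params, cfg, vocab, bonds, batch: _Batch) -> Tensor:
    """Mean over steps of (atom CE + summed bond CEs)."""
    h_n, h_g = _encode_batch(params, cfg, batch)
    logits_a = _atom_logits(params, h_g)
    loss = ad.softmax_cross_entropy(logits_a, batch.atom_labels)
    if len(batch.bond_rows):
        h_g_rows = ad.gather_rows(h_g, batch.bond_rows)
        labels = batch.atom_labels[batch.bond_rows]  # teacher forcing
        logits_t = _bond_logit_sequence(params, cfg, h_n, h_g_rows,
                                        labels, batch.seq_idx)
        for t, lg in enumerate(logits_t):
            loss = ad.add(loss, ad.softmax_cross_entropy(
                lg, batch.seq_labels[:, t], weights=batch.seq_mask[:, t]))
    return ad.mul(loss, Tensor(1.0 / len(batch.steps)))


# ---------------------------------------------------------------------------
# Fast inference path (plain NumPy, no graph recording)
#
# Numerically identical to the Tensor forward above (asserted by tests);
# exists because tree search calls the model tens of thousands of times on
# single small graphs, where autodiff bookkeeping dominates the matmuls.
# ---------------------------------------------------------------------------

def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


def _np_encode(pd, cfg: ModelConfig, g: MolGraph, bonds: BondVocab):
    n = g.n_atoms
    if n == 0:
        return (np.zeros((0, cfg.hidden_dim), dtype=np.float32),
                np.zeros(cfg.hidden_dim, dtype=np.float32))
    x = np.zeros((n, cfg.node_feature_dim), dtype=np.float32)
    x[np.arange(n), g.atoms] = 1.0
    deg = [max(g.degree(i), 1) for i in range(n)]
    edges = {t: ([], [], []) for t in range(len(bonds.orders))}
    for (i, j), o in g.bonds.items():
        t = bonds.orders.index(o)
        c = 1.0 / np.sqrt(deg[i] * deg[j])
        for a, b in ((i, j), (j, i)):
            edges[t][0].append(a)
            edges[t][1].append(b)
            edges[t][2].append(c)
    h = x
    for l in range(cfg.mpnn_layers):
        pre = h @ pd[f"enc{l}.Wself"] + pd[f"enc{l}.b"]
        for t, (src, dst, coeff) in edges.items():
            if not src:
                continue
            w = pd[f"enc{l}.W{t}"] if cfg.edge_conditioned else pd[f"enc{l}.Wnb"]
            msg = (np.asarray(coeff, dtype=np.float32)[:, None] * h[src]) @ w
            np.add.at(pre, dst, msg)
        h = np.maximum(pre, 0.0)
    return h, h.sum(axis=0)


def _np_atom_logits(pd, h_g):
    hid = np.maximum(h_g @ pd["atom.W1"] + pd["atom.b1"], 0.0)
    return hid @ pd["atom.W2"] + pd["atom.b2"]


def _np_bond_probs(pd, cfg: ModelConfig, h_n, h_g, atom_labels,
                   temperature: float = 1.0):
    """(len(atom_labels), n_atoms, 4) bond probabilities, batched over labels."""
    S = cfg.gru_state_dim
    labels = np.asarray(atom_labels, dtype=np.intp)
    m, n = len(labels), h_n.shape[0]
    emb = pd["bond.E"][labels]
    s0 = (np.concatenate([emb, np.tile(h_g, (m, 1))], axis=1)
          @ pd["bond.P"] + pd["bond.p"])
    states = [s0.copy() for _ in range(cfg.bond_gru_layers)]
    xp0 = h_n @ pd["gru0.Wx"]  # layer-0 input is shared across labels
    out = np.empty((m, n, cfg.bond_out_dim))
    for t in range(n):
        xp = np.broadcast_to(xp0[t], (m, 3 * S))
        for l in range(cfg.bond_gru_layers):
            if l > 0:
                xp = states[l - 1] @ pd[f"gru{l}.Wx"]
            h = states[l]
            hp = h @ pd[f"gru{l}.Uzr"] + pd[f"gru{l}.bzr"]
            z = _sig(xp[:, :S] + hp[:, :S])
            r = _sig(xp[:, S:2 * S] + hp[:, S:])
            cand = np.tanh(xp[:, 2 * S:] + (r * h) @ pd[f"gru{l}.Uh"]
                           + pd[f"gru{l}.bh"])
            states[l] = h + z * (cand - h)
        hid = np.maximum(states[-1] @ pd["bondout.W1"] + pd["bondout.b1"], 0.0)
        out[:, t, :] = hid @ pd["bondout.W2"] + pd["bondout.b2"]
    return ad.softmax(out / temperature, axis=-1)


# ---------------------------------------------------------------------------
# The user-facing model
# ---------------------------------------------------------------------------

class GeneratorModel:
    """Trained fragment generator with masked sampling."""

    def __init__(self, params: dict[str, Tensor], cfg: ModelConfig,
                 vocab: AtomVocab = DEFAULT_VOCAB,
                 bonds: BondVocab = DEFAULT_BONDS):
        cfg.validate(vocab, bonds)
        self.params = params
        self.cfg = cfg
        self.vocab = vocab
        self.bonds = bonds
        self._fp: dict[str, np.ndarray] | None = None

    @property
    def _fast(self) -> dict[str, np.ndarray]:
        """float32 weight copies for the inference path (built lazily).

        Call :meth:`invalidate_cache` after mutating ``params`` in place.
        """
        if self._fp is None:
            self._fp = {k: v.data.astype(np.float32) for k, v in self.params.items()}
        return self._fp

    def invalidate_cache(self) -> None:
        self._fp = None

    # -- encoding ----------------------------------------------------------
    def encode(self, g: MolGraph):
        """Node and graph hidden states of one (possibly empty) graph."""
        for a in g.atoms:
            if not 0 <= a < len(self.vocab.elements):
                raise ValueError(f"node feature {a} outside vocabulary")
        return _np_encode(self._fast, self.cfg, g, self.bonds)

    def atom_distribution(self, g: MolGraph, temperature: float = 1.0):
        _, h_g = self.encode(g)
        return ad.softmax(_np_atom_logits(self._fast, h_g) / temperature)

    def bond_distribution(self, g: MolGraph, atom_label: int,
                          temperature: float = 1.0):
        """(n_atoms, 4) bond probabilities for a new atom of the given type."""
        if atom_label == self.vocab.stop_label:
            raise ValueError("bond prediction is undefined for the stop label")
        if g.n_atoms == 0:
            raise ValueError("bond prediction requires an existing atom")
        h_n, h_g = self.encode(g)
        return _np_bond_probs(self._fast, self.cfg, h_n, h_g,
                              [atom_label], temperature)[0]

    # -- sampling ----------------------------------------------------------
    def _masked_bond_labels(self, g: MolGraph, atom_label: int, probs,
                            rng, greedy: bool) -> list[int]:
        """Sequentially pick bond labels under the valence mask."""
        none = self.bonds.none_label
        remaining = self.vocab.max_valence[atom_label]
        labels = []
        for u in range(g.n_atoms):
            mask = np.zeros(self.bonds.n_labels)
            mask[none] = 1.0
            fv = free_valence(g, u)
            for k, order in enumerate(self.bonds.orders):
                if order <= fv and order <= remaining:
                    mask[k] = 1.0
            p = probs[u] * mask
            total = p.sum()
            if total <= 0:
                labels.append(none)
                continue
            p = p / total
            lab = int(np.argmax(p)) if greedy else int(rng.choice(len(p), p=p))
            labels.append(lab)
            if lab != none:
                remaining -= self.bonds.orders[lab]
        return labels

    def sample_step(self, g: MolGraph, rng=None, temperature: float = 1.0,
                    greedy: bool = False) -> Proposal | None:
        """Sample one generation step; ``None`` signals the terminal state.

        Terminal when the atom head picks the stop label, or when every bond
        label comes out "none" for a non-empty state (either sampled or
        forced by the valence mask).
        """
        if rng is None:
            rng = np.random.default_rng()
        h_n, h_g = self.encode(g)
        p_atom = ad.softmax(_np_atom_logits(self._fast, h_g) / temperature)
        atom_label = (int(np.argmax(p_atom)) if greedy
                      else int(rng.choice(len(p_atom), p=p_atom)))
        if atom_label == self.vocab.stop_label:
            return None
        if g.n_atoms == 0:
            return Proposal(atom_label, [], float(p_atom[atom_label]))
        probs = _np_bond_probs(self._fast, self.cfg, h_n, h_g,
                               [atom_label], temperature)[0]
        labels = self._masked_bond_labels(g, atom_label, probs, rng, greedy)
        if all(lab == self.bonds.none_label for lab in labels):
            return None
        joint = float(p_atom[atom_label])
        return Proposal(atom_label, labels, joint)

    def top_proposals(self, g: MolGraph, k: int = 5,
                      temperature: float = 1.0) -> list[Proposal]:
        """The ``k`` highest-probability next-step proposals, valence-masked.

        One candidate per atom label (bonds chosen greedily under the mask)
        plus the stop proposal, ranked by joint probability.  Used as the
        expansion policy of the atom-wise search.
        """
        h_n, h_g = self.encode(g)
        p_atom = ad.softmax(_np_atom_logits(self._fast, h_g) / temperature)
        candidates = [Proposal(self.vocab.stop_label, [],
                               float(p_atom[self.vocab.stop_label]))]
        all_labels = list(range(len(self.vocab.elements)))
        if g.n_atoms == 0:
            candidates.extend(Proposal(lab, [], float(p_atom[lab]))
                              for lab in all_labels)
        else:
            probs = _np_bond_probs(self._fast, self.cfg, h_n, h_g,
                                   all_labels, temperature)
            for label in all_labels:
                labels = self._masked_bond_labels(g, label, probs[label],
                                                  rng=None, greedy=True)
                joint = float(p_atom[label])
                for u, lab in enumerate(labels):
                    joint *= float(probs[label, u, lab])
                candidates.append(Proposal(label, labels, joint))
        candidates.sort(key=lambda p: -p.prob)
        return candidates[:k]

    def reconstructs_greedily(self, frag: MolGraph) -> bool:
        """Whether teacher-forced greedy decoding reproduces ``frag`` exactly.

        Walks the fragment's own BFS serialization; at every step the model's
        argmax atom label and masked-argmax bond labels must equal the truth.
        """
        from .dataset import serialize_fragment

        for step in serialize_fragment(frag):
            p_atom = self.atom_distribution(step.state)
            if int(np.argmax(p_atom)) != step.atom_label:
                return False
            if step.atom_label == self.vocab.stop_label or step.state.n_atoms == 0:
                continue
            probs = self.bond_distribution(step.state, step.atom_label)
            labels = self._masked_bond_labels(
                step.state, step.atom_label, probs, rng=None, greedy=True)
            if labels != step.bond_labels:
                return False
        return True

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "config": asdict(self.cfg),
            "vocab": {"elements": list(self.vocab.elements),
                      "max_valence": list(self.vocab.max_valence)},
            "bond_orders": list(self.bonds.orders),
            "vocab_fingerprint": self.vocab.fingerprint(),
        }
        arrays = {k.replace(".", "__"): v.data for k, v in self.params.items()}
        np.savez_compressed(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path,
             expect_vocab: AtomVocab | None = None) -> "GeneratorModel":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["__meta__"]))
            params = {k.replace("__", "."): ad.parameter(npz[k])
                      for k in npz.files if k != "__meta__"}
        vocab = AtomVocab(tuple(meta["vocab"]["elements"]),
                          tuple(meta["vocab"]["max_valence"]))
        if expect_vocab is not None and vocab.fingerprint() != expect_vocab.fingerprint():
            raise ValueError(
                "checkpoint vocabulary does not match the requested vocabulary: "
                f"{vocab.fingerprint()} != {expect_vocab.fingerprint()}")
        bonds = BondVocab(tuple(meta["bond_orders"]))
        cfg = ModelConfig(**meta["config"])
        return cls(params, cfg, vocab, bonds)


def apply_proposal(g: MolGraph, proposal: Proposal,
                   bonds: BondVocab = DEFAULT_BONDS) -> MolGraph:
    """Apply a non-terminal generation step to a partial fragment."""
    out = g.copy()
    t = out.add_atom(proposal.atom_label)
    for u, lab in enumerate(proposal.bond_labels):
        if lab != bonds.none_label:
            out.add_bond(u, t, bonds.orders[lab])
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float, clip: float):
        self.params = params
        self.lr = lr
        self.clip = clip
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        grads = {k: (v.grad if v.grad is not None else np.zeros_like(v.data))
                 for k, v in self.params.items()}
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        scale = min(1.0, self.clip / (norm + 1e-12))
        self.t += 1
        for k, p in self.params.items():
            g = grads[k] * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


@dataclass
class TrainResult:
    model: "GeneratorModel"          # parameters after the final epoch
    eval_model: "GeneratorModel | None"  # snapshot at cfg.eval_epoch
    history: list[dict]              # per-epoch train (and test) losses


def _snapshot(model: GeneratorModel) -> GeneratorModel:
    params = {k: ad.parameter(v.data.copy()) for k, v in model.params.items()}
    return GeneratorModel(params, model.cfg, model.vocab, model.bonds)


def train(steps: list[GenerationStep], cfg: TrainConfig,
          vocab: AtomVocab = DEFAULT_VOCAB, bonds: BondVocab = DEFAULT_BONDS,
          model_cfg: ModelConfig | None = None,
          test_steps: list[GenerationStep] | None = None,
          progress: bool = False) -> TrainResult:
    """Train the generator on serialized fragment steps.

    Returns per-epoch losses and two parameter sets: the final epoch and a
    snapshot at ``cfg.eval_epoch`` (the epoch whose parameters are used for
    search at full scale).
    """
    if not steps:
        raise ValueError("training requires a non-empty step list")
    model_cfg = model_cfg or ModelConfig()
    model = GeneratorModel(init_params(model_cfg, cfg.seed), model_cfg,
                           vocab, bonds)
    opt = _Adam(model.params, cfg.learning_rate, cfg.grad_clip)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    eval_model = None
    iterator = range(1, cfg.epochs + 1)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="train")
    for epoch in iterator:
        order = rng.permutation(len(steps))
        total = 0.0
        for lo in range(0, len(steps), cfg.batch_size):
            chunk = [steps[i] for i in order[lo:lo + cfg.batch_size]]
            batch = _Batch(chunk, model_cfg, vocab, bonds)
            opt.zero_grad()
            loss = _loss_on_batch(model.params, model_cfg, vocab, bonds, batch)
            loss.backward()
            opt.step()
            total += loss.item() * len(chunk)
        entry = {"epoch": epoch, "train_loss": total / len(steps)}
        if test_steps:
            with no_grad():
                tb = _Batch(test_steps, model_cfg, vocab, bonds)
                entry["test_loss"] = _loss_on_batch(
                    model.params, model_cfg, vocab, bonds, tb).item()
        history.append(entry)
        if epoch == cfg.eval_epoch:
            eval_model = _snapshot(model)
    return TrainResult(model, eval_model, history)
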