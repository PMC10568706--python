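"""Molecular-graph data model and graph-editing primitives.

Molecules are represented as kekulized heavy-atom graphs: a list of atom
types (indices into an :class:`AtomVocab`) and a set of bonds with integer
orders 1/2/3.  Hydrogens are implicit; an atom's free valence is the gap
between its element's maximum valence and the sum of its heavy-atom bond
orders.  Aromatic rings are always stored as alternating single/double
Kekulé bonds so no aromatic bond type exists anywhere in the model.

Two editing primitives drive the outer search: :func:`enumerate_removals`
(cut a single acyclic bond, keep the larger half) and
:func:`attach_fragment` (join two graphs with one new single bond).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AtomVocab",
    "BondVocab",
    "MolGraph",
    "AttachmentSite",
    "ChemGraphError",
    "InvalidSmilesError",
    "OutOfVocabError",
    "ValenceError",
    "parse_smiles",
    "write_smiles",
    "canonical_smiles",
    "free_valence",
    "enumerate_removals",
    "attach_fragment",
    "bfs_order",
    "DEFAULT_VOCAB",
]


class ChemGraphError(ValueError):
    """Base error for molecular-graph operations."""


class InvalidSmilesError(ChemGraphError):
    """The SMILES string could not be parsed or sanitized."""


class OutOfVocabError(ChemGraphError):
    """A molecule contains an element outside the atom vocabulary."""


class ValenceError(ChemGraphError):
    """An edit would exceed an atom's maximum valence."""


# Standard maximum valences for the neutral heavy elements of drug-like
# chemistry (the conventional ZINC element set).
_MAX_VALENCE = {
    "C": 4, "N": 3, "O": 2, "F": 1, "P": 5, "S": 6, "Cl": 1, "Br": 1, "I": 1,
}


@dataclass(frozen=True)
class AtomVocab:
    """Ordered element vocabulary plus the terminal "empty atom" label.

    The atom-prediction head of the generator emits ``len(elements) + 1``
    classes; index ``stop_label`` means "stop growing this fragment".
    """

    elements: tuple[str, ...] = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
    max_valence: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.max_valence is None:
            object.__setattr__(
                self, "max_valence",
                tuple(_MAX_VALENCE[e] for e in self.elements),
            )
        if len(self.max_valence) != len(self.elements):
            raise ValueError("max_valence must align with elements")

    @property
    def stop_label(self) -> int:
        return len(self.elements)

    @property
    def n_labels(self) -> int:
        """Output dimension of the atom head (elements + stop)."""
        return len(self.elements) + 1

    def index(self, symbol: str) -> int:
        try:
            return self.elements.index(symbol)
        except ValueError:
            raise OutOfVocabError(
                f"element {symbol!r} is not in the atom vocabulary "
                f"{self.elements}"
            ) from None

    def fingerprint(self) -> str:
        return ",".join(f"{e}:{v}" for e, v in zip(self.elements, self.max_valence))


@dataclass(frozen=True)
class BondVocab:
    """Bond orders single/double/triple plus the "no bond" label.

    The bond-prediction head emits 4 classes; index ``none_label`` means no
    bond between the new atom and an existing atom.  There is deliberately
    no aromatic label: all rings are kekulized.
    """

    orders: tuple[int, ...] = (1, 2, 3)

    @property
    def none_label(self) -> int:
        return len(self.orders)

    @property
    def n_labels(self) -> int:
        return len(self.orders) + 1


DEFAULT_VOCAB = AtomVocab()
DEFAULT_BONDS = BondVocab()


class MolGraph:
    """A connected, kekulized, valence-valid heavy-atom graph.

    Parameters
    ----------
    atoms
        Element indices into ``vocab``.
    bonds
        Mapping ``(i, j) -> order`` with ``i < j`` and order in {1, 2, 3}.
    vocab
        Atom vocabulary used for element symbols and valence limits.
    """

    __slots__ = ("atoms", "bonds", "vocab", "_smiles")

    def __init__(self, atoms=(), bonds=None, vocab: AtomVocab = DEFAULT_VOCAB):
        self.atoms: list[int] = list(atoms)
        self.bonds: dict[tuple[int, int], int] = dict(bonds or {})
        self.vocab = vocab
        self._smiles: str | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def symbol(self, i: int) -> str:
        return self.vocab.elements[self.atoms[i]]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for (a, b) in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def bond_order_sum(self, i: int) -> int:
        return sum(o for (a, b), o in self.bonds.items() if a == i or b == i)

    def degree(self, i: int) -> int:
        return sum(1 for (a, b) in self.bonds if a == i or b == i)

    def copy(self) -> "MolGraph":
        return MolGraph(self.atoms, self.bonds, self.vocab)

    # -- mutation (invalidates the cached SMILES) --------------------------
    def add_atom(self, element_index: int) -> int:
        if not 0 <= element_index < len(self.vocab.elements):
            raise OutOfVocabError(f"element index {element_index} out of range")
        self.atoms.append(element_index)
        self._smiles = None
        return len(self.atoms) - 1

    def add_bond(self, i: int, j: int, order: int) -> None:
        if i == j:
            raise ChemGraphError("self-bonds are not allowed")
        key = (min(i, j), max(i, j))
        if key in self.bonds:
            raise ChemGraphError(f"bond {key} already exists")
        if order not in (1, 2, 3):
            raise ChemGraphError(f"bond order must be 1/2/3, got {order}")
        for k in key:
            if free_valence(self, k) < order:
                raise ValenceError(
                    f"adding a bond of order {order} at atom {k} "
                    f"({self.symbol(k)}) exceeds its maximum valence"
                )
        self.bonds[key] = order
        self._smiles = None

    # -- structure checks --------------------------------------------------
    def is_connected(self) -> bool:
        if self.n_atoms == 0:
            return True
        seen = {0}
        queue = deque([0])
        adj = self._adjacency()
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        return len(seen) == self.n_atoms

    def is_valence_valid(self) -> bool:
        return all(free_valence(self, i) >= 0 for i in range(self.n_atoms))

    def _adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for (a, b) in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        for lst in adj:
            lst.sort()
        return adj

    # -- interop -----------------------------------------------------------
    def to_rdkit(self) -> Chem.Mol:
        rw = Chem.RWMol()
        for idx in self.atoms:
            rw.AddAtom(Chem.Atom(self.vocab.elements[idx]))
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                     3: Chem.BondType.TRIPLE}
        for (i, j), o in self.bonds.items():
            rw.AddBond(i, j, order_map[o])
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol

    def canonical(self) -> str:
        if self._smiles is None:
            self._smiles = Chem.MolToSmiles(self.to_rdkit())
        return self._smiles

    def __eq__(self, other) -> bool:  # isomorphism via canonical SMILES
        return isinstance(other, MolGraph) and self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def __repr__(self) -> str:
        return f"MolGraph({self.canonical()!r})" if self.n_atoms else "MolGraph(<empty>)"


@dataclass(frozen=True)
class AttachmentSite:
    """A pair of atoms, one in each graph, that can accept one single bond."""

    parent_atom: int
    fragment_atom: int


# ---------------------------------------------------------------------------
# SMILES I/O
# ---------------------------------------------------------------------------

def parse_smiles(s: str, vocab: AtomVocab = DEFAULT_VOCAB) -> MolGraph:
    """Parse a SMILES string into a kekulized :class:`MolGraph`.

    Formal charges and stereochemistry are stripped (the model's node
    features are plain atom-type one-hots).  Atoms are renumbered by
    RDKit's canonical ranking so that atom 0 of any parsed graph is the
    canonical root used for BFS serialization.

    Raises
    ------
    InvalidSmilesError
        If the string cannot be parsed, or is disconnected, or stripping
        charges leaves an unsanitizable molecule.
    OutOfVocabError
        If an element is outside ``vocab``.
    """
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise InvalidSmilesError(f"cannot parse SMILES {s!r}")
    if mol.GetNumAtoms() == 0:
        raise InvalidSmilesError(f"SMILES {s!r} has no atoms")
    Chem.RemoveStereochemistry(mol)
    changed = False
    for atom in mol.GetAtoms():
        if atom.GetFormalCharge() != 0:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(0)
            changed = True
        if atom.GetIsotope() != 0:
            atom.SetIsotope(0)
    if changed:
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:
            raise InvalidSmilesError(
                f"SMILES {s!r} is not valence-valid after charge stripping"
            ) from exc
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in vocab.elements:
            raise OutOfVocabError(
                f"element {atom.GetSymbol()!r} in {s!r} is outside the "
                f"vocabulary {vocab.elements}"
            )
    return _from_rdkit(mol, vocab)


def _from_rdkit(mol: Chem.Mol, vocab: AtomVocab) -> MolGraph:
    """Convert a sanitized RDKit mol to a MolGraph in canonical atom order."""
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    if len(Chem.GetMolFrags(mol)) > 1:
        raise InvalidSmilesError("disconnected molecules are not supported")
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    # position of the atom that lands at each canonical index
    g = MolGraph(vocab=vocab)
    order = sorted(range(mol.GetNumAtoms()), key=lambda a: ranks[a])
    remap = {old: new for new, old in enumerate(order)}
    for old in order:
        g.atoms.append(vocab.index(mol.GetAtomWithIdx(old).GetSymbol()))
    for bond in mol.GetBonds():
        i = remap[bond.GetBeginAtomIdx()]
        j = remap[bond.GetEndAtomIdx()]
        o = int(bond.GetBondTypeAsDouble())
        if o not in (1, 2, 3):
            raise InvalidSmilesError(
                f"unsupported bond order {bond.GetBondTypeAsDouble()}"
            )
        g.bonds[(min(i, j), max(i, j))] = o
    if not g.is_valence_valid():
        raise InvalidSmilesError("molecule violates maximum-valence rules")
    return g


def write_smiles(g: MolGraph) -> str:
    """Canonical SMILES of a graph (round-trips through :func:`parse_smiles`)."""
    return g.canonical()


def canonical_smiles(s: str, vocab: AtomVocab = DEFAULT_VOCAB) -> str:
    """Canonical form of a SMILES string under the package's conventions."""
    return write_smiles(parse_smiles(s, vocab))


# ---------------------------------------------------------------------------
# Valence and editing primitives
# ---------------------------------------------------------------------------

def free_valence(g: MolGraph, i: int) -> int:
    """Number of additional bond-order units atom ``i`` can accept."""
    if not 0 <= i < g.n_atoms:
        raise IndexError(f"atom index {i} out of range for {g.n_atoms} atoms")
    return g.vocab.max_valence[g.atoms[i]] - g.bond_order_sum(i)


def _components_without_bond(g: MolGraph, drop: tuple[int, int]) -> list[set[int]]:
    adj = g._adjacency()
    a, b = drop
    adj[a] = [v for v in adj[a] if v != b]
    adj[b] = [v for v in adj[b] if v != a]
    seen: set[int] = set()
    comps = []
    for start in range(g.n_atoms):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.append(comp)
    return comps


def extract_component(g: MolGraph, atoms: set[int]) -> MolGraph:
    """Induced subgraph on ``atoms``, renumbered to canonical atom order."""
    sub = MolGraph(vocab=g.vocab)
    remap = {}
    for old in sorted(atoms):
        remap[old] = len(sub.atoms)
        sub.atoms.append(g.atoms[old])
    for (i, j), o in g.bonds.items():
        if i in atoms and j in atoms:
            sub.bonds[(remap[i], remap[j])] = o
    return parse_smiles(sub.canonical(), g.vocab)


def enumerate_removals(g: MolGraph) -> list[MolGraph]:
    """All fragment-removal children of a molecule.

    For every single bond whose deletion splits the molecule in two, the
    connected component with more atoms becomes a child (the smaller side
    is the removed fragment).  Ties keep the component whose canonical
    SMILES sorts first.  Children are deduplicated by canonical SMILES.
    """
    children: dict[str, MolGraph] = {}
    for (i, j), order in g.bonds.items():
        if order != 1:
            continue
        comps = _components_without_bond(g, (i, j))
        if len(comps) != 2:
            continue  # ring bond: molecule stays connected
        first, second = comps
        if len(first) != len(second):
            keep = first if len(first) > len(second) else second
            child = extract_component(g, keep)
        else:
            cand = sorted(
                (extract_component(g, comp) for comp in comps),
                key=lambda c: c.canonical(),
            )
            child = cand[0]
        children.setdefault(child.canonical(), child)
    return list(children.values())


def attach_fragment(parent: MolGraph, frag: MolGraph, site: AttachmentSite) -> MolGraph:
    """Join ``parent`` and ``frag`` with one single bond at ``site``.

    Raises :class:`ValenceError` if either endpoint has no free valence.
    """
    if free_valence(parent, site.parent_atom) < 1:
        raise ValenceError(
            f"parent atom {site.parent_atom} has no free valence"
        )
    if free_valence(frag, site.fragment_atom) < 1:
        raise ValenceError(
            f"fragment atom {site.fragment_atom} has no free valence"
        )
    out = parent.copy()
    offset = out.n_atoms
    out.atoms.extend(frag.atoms)
    for (i, j), o in frag.bonds.items():
        out.bonds[(i + offset, j + offset)] = o
    out._smiles = None
    out.add_bond(site.parent_atom, site.fragment_atom + offset, 1)
    return out


def bfs_order(g: MolGraph, root: int = 0) -> list[int]:
    """Breadth-first atom order from ``root``.

    Equal-depth frontier atoms are visited in ascending index order, so the
    order is deterministic; with atoms in canonical order (as produced by
    :func:`parse_smiles`) the same fragment always serializes identically.
    """
    if not 0 <= root < g.n_atoms:
        raise IndexError(f"root {root} out of range for {g.n_atoms} atoms")
    adj = g._adjacency()
    order = [root]
    seen = {root}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                order.append(v)
                queue.append(v)
    if len(order) != g.n_atoms:
        raise ChemGraphError("bfs_order requires a connected graph")
    return order
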