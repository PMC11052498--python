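"""Molecular holograms: hashed substructure-fragment count fingerprints.

A hologram is a fixed-length integer vector obtained by (1) enumerating
every connected heavy-atom induced subgraph of a molecule within a size
window, (2) canonicalizing each fragment into a text key under a set of
*distinction flags* controlling which atom/bond attributes matter, and
(3) hashing keys into one of twelve prime-length bins.  Prime lengths
reduce systematic hash collisions; collisions that do occur are part of
the descriptor, as in classical hologram QSAR.

Distinction flags
-----------------
A   atom element
B   bond order
C   heavy-atom connectivity (degree in the parent molecule)
H   attached hydrogen count
Ch  chirality (CIP code where assigned)
DA  hydrogen-bond donor/acceptor annotation

Fragments are counted once per distinct heavy-atom vertex set.  Canonical
keys are produced by Weisfeiler-Lehman iterative neighborhood refinement
over the flag-selected labels, and binned with CRC-32 -- both choices are
platform-independent, so holograms are bit-reproducible across runs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import donor_acceptor_flags, mol_from_smiles

__all__ = [
    "PRIME_LENGTHS",
    "FLAGS",
    "HologramParams",
    "Hologram",
    "enumerate_fragments",
    "fragment_key",
    "build_hologram",
    "hologram_matrix",
    "HologramFingerprinter",
]

#: The twelve admissible hologram lengths.
PRIME_LENGTHS = (53, 59, 61, 71, 83, 97, 151, 199, 257, 307, 353, 401)

#: Recognised fragment-distinction flags.
FLAGS = ("A", "B", "C", "H", "Ch", "DA")

#: Safety cap on fragments enumerated per molecule.
DEFAULT_FRAGMENT_CAP = 2_000_000


@dataclass(frozen=True)
class HologramParams:
    """Hologram construction parameters (fragment window, flags, length)."""

    size_min: int = 2
    size_max: int = 4
    flags: tuple = ("A", "Ch")
    length: int = 257

    def __post_init__(self):
        if not 1 <= self.size_min <= self.size_max:
            raise ValueError(
                f"need 1 <= size_min <= size_max (got {self.size_min}, {self.size_max})"
            )
        if self.length not in PRIME_LENGTHS:
            raise ValueError(f"length must be one of {PRIME_LENGTHS} (got {self.length})")
        if not self.flags:
            raise ValueError("at least one distinction flag is required")
        for f in self.flags:
            if f not in FLAGS:
                raise ValueError(f"unknown distinction flag {f!r}; known: {FLAGS}")


@dataclass(frozen=True)
class Hologram:
    """Fixed-length fragment-count vector; ``total`` fragments conserved."""

    length: int
    counts: tuple

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def __post_init__(self):
        if len(self.counts) != self.length:
            raise ValueError("counts length differs from declared hologram length")
        if any(c < 0 for c in self.counts):
            raise ValueError("hologram counts must be non-negative")


def _heavy_graph(mol) -> nx.Graph:
    """Heavy-atom graph with the attributes fragment keys may draw on."""
    from rdkit import Chem

    donors, acceptors = donor_acceptor_flags(mol)
    g = nx.Graph()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        i = atom.GetIdx()
        g.add_node(
            i,
            element=atom.GetSymbol(),
            degree=sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1),
            h_count=atom.GetTotalNumHs(includeNeighbors=True),
            chirality=atom.GetPropsAsDict().get("_CIPCode", ""),
            da=f"{int(donors[i])}{int(acceptors[i])}",
        )
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        g.add_edge(a.GetIdx(), b.GetIdx(), order=str(bond.GetBondType()))
    return g


def enumerate_fragments(
    graph: nx.Graph, size_min: int, size_max: int, cap: int = DEFAULT_FRAGMENT_CAP
) -> list[tuple]:
    """All connected induced subgraphs with size_min..size_max heavy atoms.

    Each fragment is returned once per distinct vertex set, as a sorted
    tuple of node ids.  Enumeration follows the ESU scheme (extend a
    growing connected set only with exclusive neighbors of larger id),
    which visits every connected vertex set exactly once.

    Raises ``OverflowError`` if more than ``cap`` fragments would be
    produced -- enumeration is never silently truncated.
    """
    if size_min < 1:
        raise ValueError(f"size_min must be >= 1 (got {size_min})")
    if graph.number_of_nodes() == 0:
        raise ValueError("graph has no heavy atoms")
    out: list[tuple] = []

    def emit(subset: frozenset):
        if len(out) >= cap:
            raise OverflowError(
                f"fragment enumeration exceeded cap of {cap}; "
                "raise the cap or narrow the size window"
            )
        out.append(tuple(sorted(subset)))

    def extend(subset: frozenset, extension: set, neighborhood: frozenset, root: int):
        if len(subset) >= size_min:
            emit(subset)
        if len(subset) == size_max:
            return
        ext = set(extension)
        while ext:
            w = ext.pop()
            # only exclusive neighbors of w extend the set, so every
            # connected vertex set is reached exactly once (ESU)
            w_nbrs = set(graph.neighbors(w))
            new_ext = ext | {u for u in w_nbrs
                             if u > root and u not in subset and u not in neighborhood}
            extend(subset | {w}, new_ext, neighborhood | w_nbrs, root)

    for v in sorted(graph.nodes):
        nbrs = frozenset(graph.neighbors(v))
        extend(frozenset({v}), {u for u in nbrs if u > v}, nbrs, v)
    return out


def fragment_key(graph: nx.Graph, atoms: Sequence[int], flags: Sequence[str]) -> str:
    """Canonical text key of an induced fragment under distinction flags.

    Invariant under atom input ordering: node labels are assembled from the
    flag-selected attributes and the fragment is reduced to a
    Weisfeiler-Lehman refinement hash with the bond label on edges.
    """
    for f in flags:
        if f not in FLAGS:
            raise ValueError(f"unknown distinction flag {f!r}; known: {FLAGS}")
    sub = graph.subgraph(atoms)
    if sub.number_of_nodes() > 1 and not nx.is_connected(sub):
        raise ValueError("fragment atoms do not induce a connected subgraph")
    h = nx.Graph()
    for n, d in sub.nodes(data=True):
        parts = []
        if "A" in flags:
            parts.append(d["element"])
        if "C" in flags:
            parts.append(str(d["degree"]))
        if "H" in flags:
            parts.append(str(d["h_count"]))
        if "Ch" in flags:
            parts.append(d["chirality"])
        if "DA" in flags:
            parts.append(d["da"])
        h.add_node(n, label="|".join(parts))
    for a, b, d in sub.edges(data=True):
        h.add_edge(a, b, label=d["order"] if "B" in flags else "-")
    wl = nx.weisfeiler_lehman_graph_hash(
        h, node_attr="label", edge_attr="label",
        iterations=max(2, h.number_of_nodes()),
    )
    return f"{h.number_of_nodes()}:{wl}"


def _bin_index(key: str, length: int) -> int:
    return zlib.crc32(key.encode("utf-8")) % length


def build_hologram(keys: Iterable[str], params: HologramParams) -> Hologram:
    """Hash a multiset of fragment keys into a prime-length count vector."""
    counts = [0] * params.length
    for key in keys:
        counts[_bin_index(key, params.length)] += 1
    return Hologram(length=params.length, counts=tuple(counts))


def hologram_for_mol(mol, params: HologramParams, cap: int = DEFAULT_FRAGMENT_CAP) -> Hologram:
    """Hologram of a single (RDKit) molecule."""
    g = _heavy_graph(mol)
    frags = enumerate_fragments(g, params.size_min, params.size_max, cap=cap)
    keys = [fragment_key(g, atoms, params.flags) for atoms in frags]
    return build_hologram(keys, params)


class HologramFingerprinter(TransformerMixin, BaseEstimator):
    """Transform molecules into hologram count matrices.

    Stateless apart from its parameters (``fit`` only validates them), so
    it composes with scikit-learn pipelines ahead of a PLS regressor.

    Parameters
    ----------
    size_min, size_max : int
        Fragment size window in heavy atoms (default 2-4).
    flags : sequence of str
        Distinction flags, subset of A/B/C/H/Ch/DA (default ``("A","Ch")``).
    length : int
        Hologram length, one of the twelve admissible primes (default 257).
    """

    def __init__(self, size_min: int = 2, size_max: int = 4,
                 flags: Sequence[str] = ("A", "Ch"), length: int = 257,
                 cap: int = DEFAULT_FRAGMENT_CAP):
        self.size_min = size_min
        self.size_max = size_max
        self.flags = flags
        self.length = length
        self.cap = cap

    def _params(self) -> HologramParams:
        return HologramParams(self.size_min, self.size_max, tuple(self.flags), self.length)

    def fit(self, X, y=None):
        self._params()
        self.n_features_out_ = self.length
        return self

    def transform(self, X) -> np.ndarray:
        """Rows are holograms of the input molecules (RDKit Mol or SMILES)."""
        params = self._params()
        rows = []
        for i, m in enumerate(X):
            mol = mol_from_smiles(m) if isinstance(m, str) else m
            if mol is None:
                raise ValueError(f"unparsable structure at position {i}")
            rows.append(hologram_for_mol(mol, params, cap=self.cap).counts)
        return np.asarray(rows, dtype=float)


def hologram_matrix(cset, params: HologramParams) -> np.ndarray:
    """Hologram descriptor matrix (n compounds x hologram length)."""
    fp = HologramFingerprinter(params.size_min, params.size_max, params.flags, params.length)
    mols = []
    for r in cset:
        if r.smiles is None:
            raise ValueError(f"compound {r.ordinal} has no structure")
        mol = mol_from_smiles(r.smiles)
        if mol is None:
            raise ValueError(f"compound {r.ordinal}: unparsable SMILES {r.smiles!r}")
        mols.append(mol)
    return fp.fit(mols).transform(mols)
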