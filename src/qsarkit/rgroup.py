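"""Topomer-style R-group cutting, contributions and fragment screening.

A congeneric series is cut at labeled acyclic single bonds into a common
skeleton plus substituent fragments (Ra, Rb, Rc, ...).  Each fragment is
given a standard 3D pose (deterministic embedding; attachment vector on a
fixed axis) and a steric + electrostatic field vector on a shared
fragment lattice.  A PLS model over the concatenated per-position field
vectors then decomposes additively:

    prediction = intercept + sum over positions of contribution(fragment)

where contribution = sum of (coefficient x descriptor) over that
position's columns.  The decomposition is exact by linearity, so
substituent replacement changes the prediction by exactly the
contribution difference -- the basis of the screening step, which ranks
library fragments by contribution subject to a cap on the field distance
from a query fragment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from rdkit import Chem

from .chem import atom_parameters, embed_3d, mol_from_smiles
from .fields import LatticeSpec, comsia_fields, ProbeSpec
from .pls import PLSRegressionNIPALS

__all__ = [
    "RGroupCutSpec",
    "Fragment",
    "RGroupDecomposition",
    "FragmentContribution",
    "cut_rgroups",
    "group_contributions",
    "fragment_distance",
    "screen_library",
    "assemble",
    "assemble_and_predict",
    "TopomerFieldModel",
    "position_labels",
]

#: Shared lattice on which every fragment field vector is evaluated.
#: Fragments are posed with the attachment at the origin pointing along -x,
#: so the box is asymmetric in x.  2 A spacing as in the molecule lattices.
FRAGMENT_LATTICE = LatticeSpec(origin=(-4.0, -10.0, -10.0), spacing=2.0, dims=(9, 11, 11))

_FRAGMENT_PROBE = ProbeSpec(vdw_radius=1.0)


def position_labels(n: int) -> list[str]:
    """Ra, Rb, Rc, ... position labels."""
    return [f"R{chr(ord('a') + i)}" for i in range(n)]


@dataclass(frozen=True)
class Fragment:
    """A substituent with one attachment point, stored as SMILES with ``*``."""

    smiles: str

    def mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(f"unparsable fragment SMILES {self.smiles!r}")
        n_att = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
        if n_att != 1:
            raise ValueError(f"fragment {self.smiles!r} must have exactly one "
                             f"attachment point (found {n_att})")
        return mol

    def canonical(self) -> str:
        return Chem.MolToSmiles(self.mol())

    def is_hydrogen(self) -> bool:
        """True for the bare-hydrogen substituent ``*[H]``."""
        return all(a.GetAtomicNum() <= 1 for a in self.mol().GetAtoms())


@dataclass(frozen=True)
class RGroupCutSpec:
    """Scaffold with numbered attachment dummies defining the cut bonds.

    ``scaffold`` is a SMILES whose ``[*:1]``, ``[*:2]``, ... dummies mark
    the acyclic single bonds to cut; dummy map numbers order the position
    labels Ra, Rb, ...
    """

    scaffold: str

    def scaffold_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.scaffold)
        if mol is None:
            raise ValueError(f"unparsable scaffold SMILES {self.scaffold!r}")
        return mol

    def attachment_maps(self) -> list[int]:
        maps = sorted(a.GetAtomMapNum() for a in self.scaffold_mol().GetAtoms()
                      if a.GetAtomicNum() == 0)
        if not maps or len(set(maps)) != len(maps) or 0 in maps:
            raise ValueError("scaffold dummies need unique non-zero map numbers")
        return maps

    def labels(self) -> list[str]:
        return position_labels(len(self.attachment_maps()))

    def core_query(self) -> tuple[Chem.Mol, dict]:
        """Scaffold with dummies stripped + {map number: core atom index}."""
        mol = Chem.RWMol(self.scaffold_mol())
        anchors = {}
        dummies = []
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() == 0:
                nbrs = atom.GetNeighbors()
                if len(nbrs) != 1:
                    raise ValueError("attachment dummies must be terminal")
                bond = mol.GetBondBetweenAtoms(atom.GetIdx(), nbrs[0].GetIdx())
                if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
                    raise ValueError("cut bonds must be acyclic single bonds")
                anchors[atom.GetAtomMapNum()] = nbrs[0].GetIdx()
                dummies.append(atom.GetIdx())
        for idx in sorted(dummies, reverse=True):
            mol.RemoveAtom(idx)
            # removing atom idx shifts higher indices down by one
            anchors = {m: (i - 1 if i > idx else i) for m, i in anchors.items()}
        core = mol.GetMol()
        Chem.SanitizeMol(core)
        return core, anchors


@dataclass
class RGroupDecomposition:
    """Result of cutting one molecule: skeleton + labeled fragments."""

    spec: RGroupCutSpec
    core_atoms: tuple
    fragments: dict            # label -> Fragment
    fragment_atoms: dict       # label -> tuple of parent atom indices


def cut_rgroups(mol, spec: RGroupCutSpec) -> RGroupDecomposition:
    """Cut a molecule into common skeleton + labeled R-group fragments.

    The scaffold must match exactly once.  Fragment atom sets and the
    core partition the heavy atoms; a position carrying only hydrogen
    yields the fragment ``*[H]``.
    """
    if isinstance(mol, str):
        mol = mol_from_smiles(mol)
    core, anchors = spec.core_query()
    distinct = mol.GetSubstructMatches(core, uniquify=True)
    if len(distinct) != 1:
        raise ValueError(f"scaffold must match exactly once (got {len(distinct)} matches)")
    labels = spec.labels()
    maps = spec.attachment_maps()
    # the bare core may have automorphisms: try every orientation and keep
    # those that route all substituents through labeled anchors, then pick
    # the lexicographically smallest assignment for determinism
    candidates = []
    for match in mol.GetSubstructMatches(core, uniquify=False):
        parts = _try_partition(mol, match, anchors, labels, maps)
        if parts is not None:
            fragments, fragment_atoms = parts
            key = tuple(fragments[lb].canonical() for lb in labels)
            candidates.append((key, match, fragments, fragment_atoms))
    if not candidates:
        raise ValueError(
            "no scaffold orientation partitions the molecule: some substituent "
            "is attached to an unlabeled scaffold position")
    _, match, fragments, fragment_atoms = min(candidates, key=lambda c: c[0])
    return RGroupDecomposition(spec=spec, core_atoms=tuple(match),
                               fragments=fragments, fragment_atoms=fragment_atoms)


def _try_partition(mol, match, anchors, labels, maps):
    core_atoms = set(match)
    fragment_atoms: dict[str, tuple] = {}
    fragments: dict[str, Fragment] = {}
    claimed: set[int] = set()
    for label, mapno in zip(labels, maps):
        anchor = match[anchors[mapno]]
        ext = [nb.GetIdx() for nb in mol.GetAtomWithIdx(anchor).GetNeighbors()
               if nb.GetIdx() not in core_atoms]
        if not ext:
            fragments[label] = Fragment("*[H]")
            fragment_atoms[label] = ()
            continue
        # collect the connected substituent hanging off this anchor
        seen: set[int] = set()
        stack = list(ext)
        while stack:
            i = stack.pop()
            if i in seen or i in core_atoms:
                continue
            seen.add(i)
            stack.extend(nb.GetIdx() for nb in mol.GetAtomWithIdx(i).GetNeighbors())
        if seen & claimed:
            return None
        claimed |= seen
        fragment_atoms[label] = tuple(sorted(seen))
        fragments[label] = Fragment(_extract_fragment_smiles(mol, anchor, seen))
    if set(range(mol.GetNumAtoms())) - core_atoms - claimed:
        return None
    return fragments, fragment_atoms


def _extract_fragment_smiles(mol, anchor: int, atoms: set) -> str:
    em = Chem.RWMol(mol)
    dummy = em.AddAtom(Chem.Atom(0))
    first = None
    for nb in mol.GetAtomWithIdx(anchor).GetNeighbors():
        if nb.GetIdx() in atoms:
            first = nb.GetIdx()
            break
    bond = mol.GetBondBetweenAtoms(anchor, first)
    em.AddBond(dummy, first, bond.GetBondType())
    em.RemoveBond(anchor, first)
    keep = atoms | {dummy}
    for idx in sorted(set(range(em.GetNumAtoms())) - keep, reverse=True):
        em.RemoveAtom(idx)
    frag = em.GetMol()
    Chem.SanitizeMol(frag)
    return Chem.MolToSmiles(frag)


# ---------------------------------------------------------------------------
# Contributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentContribution:
    """Additive activity contribution of one labeled fragment (pIC50 units)."""

    label: str
    value: float


def group_contributions(coefficients: np.ndarray, intercept: float,
                        x: np.ndarray, assignment: Sequence[str]
                        ) -> list[FragmentContribution]:
    """Decompose a linear-model prediction into per-label contributions.

    Every descriptor column must be assigned to exactly one label (e.g.
    'core', 'Ra', 'Rb', 'Rc'); contribution(label) is the sum of
    coefficient x descriptor over that label's columns, so that
    intercept + sum of contributions equals the model prediction exactly.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    assignment = list(assignment)
    if len(assignment) != len(x) or len(coefficients) != len(x):
        raise ValueError("assignment, coefficients and descriptors disagree in length")
    if any(a is None or a == "" for a in assignment):
        bad = [i for i, a in enumerate(assignment) if a is None or a == ""]
        raise ValueError(f"unassigned descriptor columns: {bad[:10]}")
    labels = list(dict.fromkeys(assignment))
    terms = coefficients * x
    out = []
    for label in labels:
        mask = np.array([a == label for a in assignment])
        out.append(FragmentContribution(label=label, value=float(terms[mask].sum())))
    return out


# ---------------------------------------------------------------------------
# Fragment fields, distance, model
# ---------------------------------------------------------------------------

def _pose_fragment(frag: Fragment, seed: int = 1234) -> tuple[np.ndarray, dict]:
    """Deterministic standard pose: attachment neighbor at the origin, the
    attachment direction along -x, the farthest off-axis atom in the +y
    half of the xy-plane.  Returns heavy-atom coords + parameters."""
    mol = frag.mol()
    dummy = next(a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
    if frag.is_hydrogen():
        return np.zeros((0, 3)), {k: np.zeros(0) for k in
                                  ("radius", "epsilon", "charge",
                                   "hydrophobicity", "donor", "acceptor")}
    # replace the dummy by H so embedding sees a valid molecule
    em = Chem.RWMol(mol)
    em.GetAtomWithIdx(dummy).SetAtomicNum(1)
    probe_mol = em.GetMol()
    Chem.SanitizeMol(probe_mol)
    embedded = embed_3d(Chem.RemoveHs(probe_mol), seed=seed)
    # embed_3d removed the marker H; recover the attachment direction by
    # re-adding coordinates: use the anchor's position and neighbors
    anchor_in_frag = next(a.GetIdx() for a in mol.GetAtoms()
                          if any(nb.GetAtomicNum() == 0 for nb in a.GetNeighbors()))
    # map fragment heavy atoms (minus dummy) onto the embedded mol: order is
    # preserved by RemoveHs since the dummy became an (removed) hydrogen
    heavy_order = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 0]
    coords = np.asarray(embedded.GetConformer().GetPositions(), dtype=float)
    anchor_pos = heavy_order.index(anchor_in_frag)

    coords = coords - coords[anchor_pos]
    # attachment direction: from the anchor away from the fragment centroid
    if len(coords) > 1:
        centroid = coords.mean(axis=0)
        direction = -centroid
        if np.linalg.norm(direction) < 1e-8:
            direction = np.array([-1.0, 0.0, 0.0])
    else:
        direction = np.array([-1.0, 0.0, 0.0])
    coords = _rotate_onto(coords, direction / np.linalg.norm(direction),
                          np.array([-1.0, 0.0, 0.0]))
    coords = _fix_axial_rotation(coords)
    params = atom_parameters(Chem.RemoveHs(embedded))
    return coords, params


def _rotate_onto(coords: np.ndarray, v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    c = float(np.dot(v_from, v_to))
    axis = np.cross(v_from, v_to)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return coords
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0]) if abs(v_from[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = np.cross(v_from, perp)
        axis /= np.linalg.norm(axis)
        s, c = 0.0, -1.0
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + 2 * K @ K
        return coords @ R.T
    axis /= s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    return coords @ R.T


def _fix_axial_rotation(coords: np.ndarray) -> np.ndarray:
    off = coords[:, 1] ** 2 + coords[:, 2] ** 2
    if len(off) == 0 or off.max() < 1e-10:
        return coords
    i = int(np.argmax(off))
    theta = np.arctan2(coords[i, 2], coords[i, 1])
    ct, st = np.cos(-theta), np.sin(-theta)
    R = np.array([[1, 0, 0], [0, ct, -st], [0, st, ct]])
    return coords @ R.T


def fragment_field_vector(frag: Fragment, lattice: LatticeSpec = FRAGMENT_LATTICE,
                          attenuation: float = 0.3, seed: int = 1234) -> np.ndarray:
    """Steric + electrostatic Gaussian field vector of a posed fragment."""
    coords, params = _pose_fragment(frag, seed=seed)
    if len(coords) == 0:
        return np.zeros(2 * lattice.n_points)
    f = comsia_fields(coords, params, lattice, probe=_FRAGMENT_PROBE,
                      attenuation=attenuation)
    return np.concatenate([f["S"], f["E"]])


def fragment_distance(f1: Fragment, f2: Fragment,
                      lattice: LatticeSpec = FRAGMENT_LATTICE) -> float:
    """Field distance between two fragments on the shared fragment lattice.

    Root-sum-square difference of the standardized field vectors: each of
    the steric and electrostatic sub-blocks is scaled by the pooled
    standard deviation of that sub-block over the pair, which makes the
    distance symmetric, zero for identical fragments, and insensitive to
    the different natural units of the two fields.
    """
    v1, v2 = fragment_field_vector(f1, lattice), fragment_field_vector(f2, lattice)
    m = lattice.n_points
    d2 = 0.0
    for sl in (slice(0, m), slice(m, 2 * m)):
        pooled = np.concatenate([v1[sl], v2[sl]]).std()
        if pooled > 0:
            d2 += (((v1[sl] - v2[sl]) / pooled) ** 2).sum()
    return float(np.sqrt(d2))


class TopomerFieldModel:
    """PLS over concatenated per-position fragment field vectors.

    Fit on a series described by per-position fragment choices; the model
    is linear in the descriptors, so predictions decompose exactly into
    intercept + per-position fragment contributions.  The scaffold's own
    (constant) term is part of the intercept.
    """

    def __init__(self, positions: Sequence[str], n_components: int = 4,
                 lattice: LatticeSpec = FRAGMENT_LATTICE, attenuation: float = 0.3,
                 embed_seed: int = 1234):
        self.positions = list(positions)
        self.n_components = n_components
        self.lattice = lattice
        self.attenuation = attenuation
        self.embed_seed = embed_seed
        self._cache: dict[str, np.ndarray] = {}

    def _descriptor(self, frag: Fragment) -> np.ndarray:
        key = frag.canonical()
        if key not in self._cache:
            self._cache[key] = fragment_field_vector(
                frag, self.lattice, self.attenuation, self.embed_seed)
        return self._cache[key]

    def design_matrix(self, choices: Iterable[dict]) -> np.ndarray:
        rows = []
        for ch in choices:
            missing = [p for p in self.positions if p not in ch]
            if missing:
                raise ValueError(f"missing fragment choice for position(s) {missing}")
            rows.append(np.concatenate([self._descriptor(ch[p]) for p in self.positions]))
        return np.asarray(rows)

    def column_assignment(self) -> list[str]:
        m = 2 * self.lattice.n_points
        return [p for p in self.positions for _ in range(m)]

    def fit(self, choices: Sequence[dict], y) -> "TopomerFieldModel":
        X = self.design_matrix(choices)
        self.pls_ = PLSRegressionNIPALS(n_components=self.n_components).fit(X, y)
        return self

    @property
    def intercept_(self) -> float:
        return float(self.pls_.intercept_)

    def predict(self, choices: Sequence[dict]) -> np.ndarray:
        return self.pls_.predict(self.design_matrix(choices))

    def contribution(self, position: str, frag: Fragment) -> float:
        """Additive contribution of ``frag`` at ``position`` (pIC50 units)."""
        if position not in self.positions:
            raise ValueError(f"unknown position {position!r}")
        m = 2 * self.lattice.n_points
        k = self.positions.index(position)
        coef = self.pls_.coef_[k * m:(k + 1) * m]
        return float(coef @ self._descriptor(frag))

    def contributions(self, choice: dict) -> list[FragmentContribution]:
        x = self.design_matrix([choice])[0]
        return group_contributions(self.pls_.coef_, self.intercept_, x,
                                   self.column_assignment())


def screen_library(library: Sequence[Fragment], query: Fragment, model: TopomerFieldModel,
                   position: str, max_distance: float = np.inf,
                   min_contribution: float = -np.inf) -> list[dict]:
    """Rank library fragments for one position against a query fragment.

    Keeps fragments with field distance <= max_distance from the query and
    model contribution >= min_contribution; sorts by contribution
    descending, ties by distance ascending (then SMILES, for a total
    deterministic order).
    """
    rows = []
    for frag in library:
        d = fragment_distance(query, frag, model.lattice)
        c = model.contribution(position, frag)
        if d <= max_distance and c >= min_contribution:
            rows.append({"fragment": frag, "smiles": frag.canonical(),
                         "distance": d, "contribution": c})
    rows.sort(key=lambda r: (-r["contribution"], r["distance"], r["smiles"]))
    return rows


def assemble(spec: RGroupCutSpec, fragments: dict) -> Chem.Mol:
    """Attach labeled fragments onto the scaffold's attachment points.

    Raises on valence violations (sanitization failure names the label).
    """
    combined = spec.scaffold_mol()
    labels = spec.labels()
    maps = spec.attachment_maps()
    hydrogen_maps = []
    for label, mapno in zip(labels, maps):
        if label not in fragments:
            raise ValueError(f"no fragment supplied for position {label}")
        frag = fragments[label]
        if frag.is_hydrogen():
            hydrogen_maps.append(mapno)
            continue
        fmol = frag.mol()
        for atom in fmol.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomMapNum(mapno)
        combined = Chem.CombineMols(combined, fmol)
    # positions carrying bare hydrogen: drop the dummy, the anchor regains an H
    em = Chem.RWMol(combined)
    for idx in sorted((a.GetIdx() for a in em.GetAtoms()
                       if a.GetAtomicNum() == 0 and a.GetAtomMapNum() in hydrogen_maps),
                      reverse=True):
        em.RemoveAtom(idx)
    mol = Chem.molzip(em.GetMol()) if len(hydrogen_maps) < len(maps) else em.GetMol()
    if mol is None:
        raise ValueError("fragment attachment failed")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise ValueError(f"valence violation while attaching fragments: {exc}")
    return mol


def assemble_and_predict(spec: RGroupCutSpec, fragments: dict,
                         model: TopomerFieldModel) -> tuple[Chem.Mol, float, list]:
    """Build a candidate molecule and predict its activity additively.

    Returns (molecule, predicted pIC50, contribution breakdown); the
    prediction equals intercept + sum of contributions by construction.
    """
    mol = assemble(spec, fragments)
    contribs = model.contributions(fragments)
    pred = model.intercept_ + sum(c.value for c in contribs)
    return mol, float(pred), contribs
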