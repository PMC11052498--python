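"""Synthetic congeneric series and random molecular graphs.

Ground-truth generators that let every pipeline stage be tested without
external downloads.  The series generator emulates the structure the
analysis assumes about a congeneric inhibitor set: a common scaffold with
a few substitution positions whose fragments contribute *additively* to
pIC50, plus Gaussian measurement noise

    pIC50 = base + sum over positions of c(position, fragment) + N(0, sd).

The default spec mirrors the three-position (Ra/Rb/Rc) topology of the
series this package's fixtures come from, without claiming its exact
chemistry: an aromatic bicyclic core and four small substituents per
position (64 combinations), with true contributions spanning about 1.5
pIC50 units -- the scale of published R-group contribution values.

All randomness flows through an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
import numpy as np

from rdkit import Chem

from .datasets import CompoundRecord, CompoundSet
from .rgroup import Fragment, RGroupCutSpec, assemble

__all__ = [
    "SyntheticSeriesSpec",
    "default_series_spec",
    "generate_rgroup_series",
    "generate_random_graphs",
]


@dataclass(frozen=True)
class SyntheticSeriesSpec:
    """Recipe for an additive congeneric series with known ground truth."""

    scaffold: str
    libraries: dict                     # position label -> list of Fragment
    true_contributions: dict            # (position, canonical smiles) -> pIC50
    base_activity: float = 5.0
    noise_sd: float = 0.1
    n: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        n_combos = int(np.prod([len(v) for v in self.libraries.values()]))
        if self.n > n_combos:
            raise ValueError(
                f"n={self.n} exceeds the {n_combos} enumerable fragment combinations")

    def positions(self) -> list[str]:
        return list(self.libraries)

    def true_activity(self, choice: dict) -> float:
        """Noise-free activity of one fragment assignment."""
        return self.base_activity + sum(
            self.true_contributions[(p, f.canonical())] for p, f in choice.items())


#: Three-position aromatic core used by the default spec.
DEFAULT_SCAFFOLD = "[*:1]c1ccc2nc([*:2])c([*:3])nc2c1"

_DEFAULT_LIBRARIES = {
    "Ra": ["*C", "*Cl", "*C#N", "*OC"],
    "Rb": ["*[H]", "*C", "*CO", "*c1ccccc1"],
    "Rc": ["*[H]", "*N", "*CC", "*C(C)C"],
}

# fixed true contributions (pIC50 units), spanning ~1.5 units per position
_DEFAULT_CONTRIBUTIONS = {
    "Ra": [0.00, 0.45, 0.90, 1.40],
    "Rb": [0.00, 0.30, 0.85, 1.25],
    "Rc": [0.00, 0.50, 0.75, 1.50],
}


def default_series_spec(n: int = 60, noise_sd: float = 0.1, seed: int = 0
                        ) -> SyntheticSeriesSpec:
    """The package's standard synthetic study condition (see module docs)."""
    libraries = {p: [Fragment(s) for s in smis] for p, smis in _DEFAULT_LIBRARIES.items()}
    contribs = {}
    for p, frags in libraries.items():
        for frag, c in zip(frags, _DEFAULT_CONTRIBUTIONS[p]):
            contribs[(p, frag.canonical())] = c
    return SyntheticSeriesSpec(
        scaffold=DEFAULT_SCAFFOLD, libraries=libraries,
        true_contributions=contribs, base_activity=5.0,
        noise_sd=noise_sd, n=n, seed=seed,
    )


def generate_rgroup_series(spec: SyntheticSeriesSpec, build_structures: bool = True
                           ) -> tuple[CompoundSet, list[dict]]:
    """Sample ``spec.n`` distinct molecules with additive noisy activities.

    Returns (compound set, per-compound fragment choices).  The choices
    carry the ground truth; compound ``meta`` records the noise-free
    activity.  Fixed seed -> identical output.
    """
    rng = np.random.default_rng(spec.seed)
    positions = spec.positions()
    combos = list(product(*[range(len(spec.libraries[p])) for p in positions]))
    picks = rng.choice(len(combos), size=spec.n, replace=False)
    cut = RGroupCutSpec(spec.scaffold)
    records, choices = [], []
    for ordinal, ci in enumerate(picks, start=1):
        choice = {p: spec.libraries[p][j] for p, j in zip(positions, combos[ci])}
        truth = spec.true_activity(choice)
        activity = truth + rng.normal(0.0, spec.noise_sd)
        smiles = None
        if build_structures:
            smiles = Chem.MolToSmiles(assemble(cut, choice))
        records.append(CompoundRecord(
            ordinal=ordinal, pic50=float(activity), smiles=smiles,
            meta={"true_pic50": truth,
                  **{p: choice[p].canonical() for p in positions}},
        ))
        choices.append(choice)
    cset = CompoundSet(records, provenance=f"synthetic(seed={spec.seed})")
    return cset, choices


# ---------------------------------------------------------------------------
# Random molecular graphs
# ---------------------------------------------------------------------------

_ELEMENTS = [("C", 4), ("N", 3), ("O", 2)]


def generate_random_graphs(n: int, size_range: tuple = (3, 12),
                           seed: int = 0, ring_prob: float = 0.4) -> list[Chem.Mol]:
    """Valence-valid random molecular graphs for property tests.

    Grows a random tree over C/N/O atoms, optionally closes one ring, and
    sanitizes.  Seed-reproducible; every returned molecule passes RDKit
    valence checks.
    """
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid size range {size_range}")
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        size = int(rng.integers(lo, hi + 1))
        em = Chem.RWMol()
        valence = []
        sym, val = _ELEMENTS[rng.integers(len(_ELEMENTS))]
        em.AddAtom(Chem.Atom(sym))
        valence.append(val)
        free = [0] * 1
        degrees = [0]
        for _ in range(size - 1):
            candidates = [i for i in range(em.GetNumAtoms()) if degrees[i] < valence[i]]
            if not candidates:
                break
            parent = int(rng.choice(candidates))
            sym, val = _ELEMENTS[rng.integers(len(_ELEMENTS))]
            idx = em.AddAtom(Chem.Atom(sym))
            valence.append(val)
            degrees.append(0)
            em.AddBond(parent, idx, Chem.BondType.SINGLE)
            degrees[parent] += 1
            degrees[idx] += 1
        # optionally close one ring between two distant open atoms
        if em.GetNumAtoms() >= 5 and rng.random() < ring_prob:
            open_atoms = [i for i in range(em.GetNumAtoms()) if degrees[i] < valence[i]]
            rng.shuffle(open_atoms)
            for a in open_atoms:
                for b in open_atoms:
                    if b > a and em.GetBondBetweenAtoms(a, b) is None:
                        path = Chem.GetShortestPath(em.GetMol(), a, b)
                        if len(path) >= 4:
                            em.AddBond(a, b, Chem.BondType.SINGLE)
                            degrees[a] += 1
                            degrees[b] += 1
                            break
                else:
                    continue
                break
        mol = em.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        out.append(mol)
    return out
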