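"""Shared RDKit helpers: parsing, atom typing, charges, 3D embedding."""

from __future__ import annotations

from typing import Optional

import numpy as np

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem import rdMolDescriptors

# the C++ logger is chatty about dummy-atom hydrogens during fragment work
RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "mol_from_smiles",
    "donor_acceptor_flags",
    "gasteiger_charges",
    "atom_parameters",
    "embed_3d",
    "VDW_PARAMS",
]

# vdW radius (Angstrom) and Lennard-Jones well depth (kcal/mol) per element.
# Standard literature values for the elements occurring in drug-like series.
VDW_PARAMS = {
    "H": (1.20, 0.042), "C": (1.70, 0.107), "N": (1.55, 0.095),
    "O": (1.52, 0.116), "F": (1.47, 0.109), "P": (1.80, 0.314),
    "S": (1.80, 0.314), "Cl": (1.75, 0.250), "Br": (1.85, 0.340),
    "I": (1.98, 0.400), "B": (1.92, 0.180), "Si": (2.10, 0.320),
}


def mol_from_smiles(smiles: str) -> Optional[Chem.Mol]:
    """Parse SMILES and assign stereochemistry (CIP codes where defined)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is not None:
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return mol


def donor_acceptor_flags(mol) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom hydrogen-bond donor/acceptor indicators.

    Simple perception rule: donor = N or O bearing at least one hydrogen;
    acceptor = N or O (excluding positively charged and pyrrole-type
    nitrogens without lone pairs is deliberately not attempted -- the rule
    is documented, deterministic and adequate for indicator fields).
    """
    n = mol.GetNumAtoms()
    donors = np.zeros(n, dtype=bool)
    acceptors = np.zeros(n, dtype=bool)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() in ("N", "O"):
            i = atom.GetIdx()
            acceptors[i] = atom.GetFormalCharge() <= 0
            donors[i] = atom.GetTotalNumHs(includeNeighbors=True) > 0
    return donors, acceptors


def gasteiger_charges(mol) -> np.ndarray:
    """Gasteiger partial charges per heavy atom, hydrogens folded in.

    The iterative partial-equalization-of-orbital-electronegativity scheme;
    the charge of implicit/explicit hydrogens is added onto the heavy atom
    they bind, so the heavy-atom sum conserves the total molecular charge.
    """
    AllChem.ComputeGasteigerCharges(mol)
    charges = []
    for atom in mol.GetAtoms():
        q = atom.GetDoubleProp("_GasteigerCharge")
        q += atom.GetDoubleProp("_GasteigerHCharge")
        charges.append(q)
    return np.asarray(charges)


def atom_parameters(mol) -> dict:
    """Deterministic per-atom parameter table for field calculations.

    Returns arrays (over all atoms of ``mol``) of: vdW radius, LJ well
    depth, Gasteiger partial charge, Crippen atomic hydrophobicity
    contribution, and donor/acceptor indicator weights.

    Raises ``KeyError`` listing any element without vdW parameters.
    """
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    missing = sorted({s for s in symbols if s not in VDW_PARAMS})
    if missing:
        raise KeyError(f"no vdW parameters for element(s): {', '.join(missing)}")
    radii = np.array([VDW_PARAMS[s][0] for s in symbols])
    eps = np.array([VDW_PARAMS[s][1] for s in symbols])
    crippen = np.array([c for c, _ in rdMolDescriptors._CalcCrippenContribs(mol)])
    donors, acceptors = donor_acceptor_flags(mol)
    return {
        "radius": radii,
        "epsilon": eps,
        "charge": gasteiger_charges(mol),
        "hydrophobicity": crippen,
        "donor": donors.astype(float),
        "acceptor": acceptors.astype(float),
    }


def embed_3d(mol, seed: int = 1234) -> Chem.Mol:
    """Deterministically embed a molecule in 3D (ETKDG, fixed seed).

    Hydrogens are added for embedding and removed again, so atom indices
    of the heavy skeleton are preserved.
    """
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(molh, params) != 0:
        # fall back to random coordinates, still seeded
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(molh, params) != 0:
            raise RuntimeError("3D embedding failed")
    return Chem.RemoveHs(molh)
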