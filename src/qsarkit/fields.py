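"""Lattice interaction fields for 3D-QSAR.

Two field families are computed on a rectangular lattice surrounding the
scaffold-aligned series:

* **CoMFA-style potentials** -- Lennard-Jones steric and Coulomb
  electrostatic interaction energies (kcal/mol) of an sp3 carbon probe
  (radius 1.52 A, charge +1), clamped at +/-30 kcal/mol, with a
  distance-dependent dielectric D(r) = r.
* **CoMSIA-style similarity indices** -- Gaussian-attenuated
  (exp(-alpha r^2), alpha = 0.3) similarity fields for steric,
  electrostatic, hydrophobic and H-bond donor/acceptor properties; no
  distance cutoff is needed because the Gaussian decays smoothly.

The lattice uses a 2.0 A spacing and a 4.0 A margin around the union
bounding box of the aligned series by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import atom_parameters

__all__ = [
    "COULOMB_CONSTANT",
    "LatticeSpec",
    "ProbeSpec",
    "FieldBlock",
    "align_to_scaffold",
    "build_lattice",
    "comfa_fields",
    "comsia_fields",
    "filter_columns",
    "ComfaFieldTransformer",
    "ComsiaFieldTransformer",
]

#: Conversion factor for q1*q2/r in e^2/Angstrom -> kcal/mol.
COULOMB_CONSTANT = 332.0636

COMSIA_PROPERTIES = ("S", "E", "H", "D", "A")


@dataclass(frozen=True)
class LatticeSpec:
    """Axis-aligned rectangular lattice: origin + k*spacing per axis."""

    origin: tuple
    spacing: float
    dims: tuple
    margin: float = 4.0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("lattice spacing must be > 0")
        if any(d < 2 for d in self.dims):
            raise ValueError("lattice needs >= 2 points per axis")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def axes(self) -> list[np.ndarray]:
        return [self.origin[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)]

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_points, 3), x fastest-varying last."""
        ax = self.axes()
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass(frozen=True)
class ProbeSpec:
    """Probe atom placed at every lattice point."""

    vdw_radius: float = 1.52
    charge: float = 1.0
    epsilon: float = 0.107
    hydrophobicity: float = 1.0
    donor_weight: float = 1.0
    acceptor_weight: float = 1.0

    def __post_init__(self):
        if self.vdw_radius <= 0:
            raise ValueError("probe radius must be > 0")


#: Default CoMFA probe: sp3 carbon, 1.52 A, +1 charge.
COMFA_PROBE = ProbeSpec()
#: Default CoMSIA probe: radius 1 A, all property weights +1.
COMSIA_PROBE = ProbeSpec(vdw_radius=1.0)


@dataclass
class FieldBlock:
    """Compounds x (lattice point, field type) descriptor matrix."""

    matrix: np.ndarray
    columns: list  # (field_type, lattice_point_index) per column
    cutoff: Optional[float] = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.columns):
            raise ValueError("column metadata length must equal matrix width")

    @staticmethod
    def hstack(blocks: Sequence["FieldBlock"]) -> "FieldBlock":
        return FieldBlock(
            matrix=np.hstack([b.matrix for b in blocks]),
            columns=[c for b in blocks for c in b.columns],
            cutoff=blocks[0].cutoff,
            meta={k: v for b in blocks for k, v in b.meta.items()},
        )


def align_to_scaffold(coords: np.ndarray, template: np.ndarray,
                      atom_map: Sequence[tuple]) -> tuple[np.ndarray, float]:
    """Rigid least-squares superposition (Kabsch) onto a template.

    ``atom_map`` pairs (molecule_atom, template_atom) of at least three
    non-collinear atoms.  Returns the fully transformed coordinates and
    the RMSD over the mapped atoms.  Rotation + translation only.
    """
    coords = np.asarray(coords, dtype=float)
    template = np.asarray(template, dtype=float)
    if len(atom_map) < 3:
        raise ValueError(f"need >= 3 mapped atoms (got {len(atom_map)})")
    mi = [a for a, _ in atom_map]
    ti = [b for _, b in atom_map]
    P = coords[mi]
    Q = template[ti]
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    s = np.linalg.svd(Q0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("mapped template atoms are (near-)collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    aligned = (coords - pc) @ R.T + qc
    rmsd = float(np.sqrt(((aligned[mi] - Q) ** 2).sum() / len(atom_map)))
    return aligned, rmsd


def build_lattice(coord_sets: Sequence[np.ndarray], spacing: float = 2.0,
                  margin: float = 4.0) -> LatticeSpec:
    """Lattice covering the union bounding box of all molecules + margin.

    Both box ends are included; if the expanded extent is not a multiple
    of the spacing the top end is pushed outward to the next grid point.
    """
    arrays = [np.asarray(c, dtype=float) for c in coord_sets if len(c)]
    if not arrays:
        raise ValueError("no coordinates supplied")
    allc = np.vstack(arrays)
    lo = allc.min(axis=0) - margin
    hi = allc.max(axis=0) + margin
    dims = tuple(
        max(2, int(math.ceil((hi[k] - lo[k]) / spacing - 1e-9)) + 1) for k in range(3)
    )
    return LatticeSpec(origin=tuple(lo), spacing=spacing, dims=dims, margin=margin)


def comfa_fields(coords: np.ndarray, params: dict, lattice: LatticeSpec,
                 probe: ProbeSpec = COMFA_PROBE, cutoff: float = 30.0
                 ) -> tuple[np.ndarray, np.ndarray, list]:
    """Steric (Lennard-Jones) and electrostatic (Coulomb) probe energies.

    steric(q)  = sum_j eps_j [ (R_j/r)^12 - 2 (R_j/r)^6 ],
                 R_j = probe radius + atom radius, eps_j = sqrt(eps_p eps_j)
    elec(q)    = sum_j 332.0636 q_p q_j / r^2        (dielectric D(r) = r)

    Both are clamped to [-cutoff, +cutoff] kcal/mol.  A lattice point
    coincident with an atom contributes +cutoff sterically and
    sign(q_p q_j) * cutoff per electrostatic term; such points are listed
    in the returned singular-point metadata.
    """
    pts = lattice.points()
    coords = np.asarray(coords, dtype=float)
    diff = pts[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=2))  # (n_points, n_atoms)
    singular = r < 1e-9

    Rj = probe.vdw_radius + params["radius"]
    epsj = np.sqrt(probe.epsilon * params["epsilon"])
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ratio6 = (Rj[None, :] / np.where(singular, np.nan, r)) ** 6
        steric_terms = epsj[None, :] * (ratio6 ** 2 - 2.0 * ratio6)
        elec_terms = COULOMB_CONSTANT * probe.charge * params["charge"][None, :] / (
            np.where(singular, np.nan, r) ** 2)
    steric_terms = np.where(singular, cutoff, steric_terms)
    elec_terms = np.where(
        singular, np.sign(probe.charge * params["charge"][None, :]) * cutoff, elec_terms)
    steric = np.clip(steric_terms.sum(axis=1), -cutoff, cutoff)
    elec = np.clip(elec_terms.sum(axis=1), -cutoff, cutoff)
    singular_points = sorted(set(np.nonzero(singular)[0].tolist()))
    return steric, elec, singular_points


def comsia_fields(coords: np.ndarray, params: dict, lattice: LatticeSpec,
                  probe: ProbeSpec = COMSIA_PROBE, attenuation: float = 0.3
                  ) -> dict[str, np.ndarray]:
    """Gaussian similarity fields A_k(q) = -sum_i w_probe,k w_ik exp(-a r^2).

    Property weights per atom: steric = (vdW radius)^3 (volume proxy),
    electrostatic = partial charge, hydrophobic = atomic hydrophobicity
    contribution, donor/acceptor = 0/1 indicators.
    """
    pts = lattice.points()
    coords = np.asarray(coords, dtype=float)
    r2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    g = np.exp(-attenuation * r2)
    weights = {
        "S": (params["radius"] ** 3, probe.vdw_radius ** 3),
        "E": (params["charge"], probe.charge),
        "H": (params["hydrophobicity"], probe.hydrophobicity),
        "D": (params["donor"], probe.donor_weight),
        "A": (params["acceptor"], probe.acceptor_weight),
    }
    out = {}
    for k, (w_atom, w_probe) in weights.items():
        if w_atom is None:
            raise ValueError(f"atom weights unassigned for property {k}")
        out[k] = -(g * (w_probe * np.asarray(w_atom))[None, :]).sum(axis=1)
    return out


def filter_columns(block: FieldBlock, min_sigma: float) -> FieldBlock:
    """Drop descriptor columns with standard deviation below ``min_sigma``."""
    if min_sigma < 0:
        raise ValueError("min_sigma must be >= 0")
    sd = block.matrix.std(axis=0, ddof=0)
    keep = sd >= min_sigma if min_sigma > 0 else np.ones(len(sd), dtype=bool)
    if not keep.any():
        raise ValueError(f"column filter at min_sigma={min_sigma} removed every column")
    return FieldBlock(
        matrix=block.matrix[:, keep],
        columns=[c for c, k in zip(block.columns, keep) if k],
        cutoff=block.cutoff,
        meta={**block.meta, "min_sigma": min_sigma},
    )


def _conformer_coords(mol) -> np.ndarray:
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformer")
    return np.asarray(mol.GetConformer().GetPositions(), dtype=float)


class _FieldTransformerBase(TransformerMixin, BaseEstimator):
    """Shared fit logic: lattice from the union bounding box of the series."""

    def fit(self, X, y=None):
        coords = [_conformer_coords(m) for m in X]
        self.lattice_ = build_lattice(coords, spacing=self.spacing, margin=self.margin)
        return self

    def _check_fitted(self):
        if not hasattr(self, "lattice_"):
            raise RuntimeError("transformer is not fitted")


class ComfaFieldTransformer(_FieldTransformerBase):
    """Aligned 3D molecules -> CoMFA steric+electrostatic field block.

    ``fit`` freezes the lattice on the training series; ``transform``
    evaluates probe energies for (possibly new) molecules on that lattice.
    Default geometry: 2.0 A spacing, 4.0 A margin, 30 kcal/mol clamp.
    """

    def __init__(self, spacing: float = 2.0, margin: float = 4.0,
                 cutoff: float = 30.0, probe: ProbeSpec = COMFA_PROBE,
                 min_sigma: float = 0.0):
        self.spacing = spacing
        self.margin = margin
        self.cutoff = cutoff
        self.probe = probe
        self.min_sigma = min_sigma

    def transform(self, X) -> FieldBlock:
        self._check_fitted()
        rows, singulars = [], {}
        for i, mol in enumerate(X):
            params = atom_parameters(mol)
            s, e, sing = comfa_fields(_conformer_coords(mol), params, self.lattice_,
                                      probe=self.probe, cutoff=self.cutoff)
            rows.append(np.concatenate([s, e]))
            if sing:
                singulars[i] = sing
        m = self.lattice_.n_points
        columns = [("S", j) for j in range(m)] + [("E", j) for j in range(m)]
        block = FieldBlock(np.asarray(rows), columns, cutoff=self.cutoff,
                           meta={"singular_points": singulars, "lattice": self.lattice_})
        if self.min_sigma > 0:
            block = filter_columns(block, self.min_sigma)
        return block


class ComsiaFieldTransformer(_FieldTransformerBase):
    """Aligned 3D molecules -> five CoMSIA similarity field blocks (S/E/H/D/A)."""

    def __init__(self, spacing: float = 2.0, margin: float = 4.0,
                 attenuation: float = 0.3, probe: ProbeSpec = COMSIA_PROBE,
                 properties: Sequence[str] = COMSIA_PROPERTIES,
                 min_sigma: float = 0.0):
        self.spacing = spacing
        self.margin = margin
        self.attenuation = attenuation
        self.probe = probe
        self.properties = properties
        self.min_sigma = min_sigma

    def transform(self, X) -> FieldBlock:
        self._check_fitted()
        rows = []
        for mol in X:
            params = atom_parameters(mol)
            f = comsia_fields(_conformer_coords(mol), params, self.lattice_,
                              probe=self.probe, attenuation=self.attenuation)
            rows.append(np.concatenate([f[p] for p in self.properties]))
        m = self.lattice_.n_points
        columns = [(p, j) for p in self.properties for j in range(m)]
        block = FieldBlock(np.asarray(rows), columns, cutoff=None,
                           meta={"attenuation": self.attenuation, "lattice": self.lattice_})
        if self.min_sigma > 0:
            block = filter_columns(block, self.min_sigma)
        return block
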