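"""Compound/activity tables for congeneric QSAR series.

The central container is :class:`CompoundSet`, an ordered collection of
:class:`CompoundRecord` (ordinal number, optional SMILES, IC50 or pIC50,
train/test role).  Activities are handled on the pIC50 scale,
``pIC50 = -log10(IC50 [M])``.

The module also ships two packaged fixtures transcribed from a published
65-compound imidazo[4,5-b]pyridine Aurora-A inhibitor series:

* :func:`load_aurora_table` -- ordinal, substituent names, experimental
  pIC50 and train/test role for all 65 compounds;
* :func:`load_aurora_predictions` -- per-compound predicted pIC50 of the
  four published models (hologram QSAR, CoMFA, CoMSIA, Topomer CoMFA);
* :func:`load_reference_validation` -- the published external-validation
  statistics used as reference context.

Fixture SMILES (``with_smiles=True``) are best-effort synthetic
reconstructions from the scaffold drawing plus substituent names; they are
non-authoritative and no numeric result in this package depends on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "CompoundRecord",
    "CompoundSet",
    "pic50_from_ic50",
    "ordinal_split",
    "load_compound_table",
    "save_compound_table",
    "load_aurora_table",
    "load_aurora_predictions",
    "load_reference_validation",
    "published_model_r2",
]

ROLES = ("train", "test", "unassigned")

#: Non-cross-validated training r^2 of the four published models
#: (best hologram model, CoMFA S/E, CoMSIA S/E/H/D/A, Topomer CoMFA).
#: Reference context for the rm^2 external-validation convention.
PUBLISHED_MODEL_R2 = {
    "hqsar": 0.948,
    "comfa": 0.983,
    "comsia": 0.995,
    "topomer": 0.971,
}


def pic50_from_ic50(ic50: float) -> float:
    """Convert a molar IC50 to pIC50 = -log10(IC50).

    Parameters
    ----------
    ic50 : float
        Half-maximal inhibitory concentration in mol/L; must be finite
        and strictly positive.
    """
    if not math.isfinite(ic50) or ic50 <= 0:
        raise ValueError(f"IC50 must be finite and > 0 (got {ic50!r})")
    return -math.log10(ic50)


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: ordinal number, activity and train/test role."""

    ordinal: int
    pic50: float
    smiles: Optional[str] = None
    ic50: Optional[float] = None
    role: str = "unassigned"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.ordinal < 1:
            raise ValueError(f"ordinal must be a positive integer (got {self.ordinal})")
        if not math.isfinite(self.pic50):
            raise ValueError(f"pIC50 must be finite (compound {self.ordinal})")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES} (got {self.role!r})")
        if self.ic50 is not None:
            expected = pic50_from_ic50(self.ic50)
            if abs(expected - self.pic50) > 1e-9:
                raise ValueError(
                    f"compound {self.ordinal}: pIC50 {self.pic50} inconsistent with "
                    f"IC50 {self.ic50} (expected {expected})"
                )


class CompoundSet:
    """Ordered, ordinal-unique collection of :class:`CompoundRecord`."""

    def __init__(self, records: Iterable[CompoundRecord], provenance: str = ""):
        self.records = list(records)
        self.provenance = provenance
        seen = set()
        for r in self.records:
            if r.ordinal in seen:
                raise ValueError(f"duplicate ordinal {r.ordinal}")
            seen.add(r.ordinal)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, i) -> CompoundRecord:
        return self.records[i]

    def by_ordinal(self, ordinal: int) -> CompoundRecord:
        for r in self.records:
            if r.ordinal == ordinal:
                return r
        raise KeyError(ordinal)

    def subset(self, role: str) -> "CompoundSet":
        return CompoundSet([r for r in self.records if r.role == role],
                           provenance=f"{self.provenance}[{role}]")

    @property
    def train(self) -> "CompoundSet":
        return self.subset("train")

    @property
    def test(self) -> "CompoundSet":
        return self.subset("test")

    def activities(self) -> list[float]:
        return [r.pic50 for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ordinal": [r.ordinal for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "ic50_molar": [r.ic50 for r in self.records],
                "pic50": [r.pic50 for r in self.records],
                "role": [r.role for r in self.records],
            }
        )


def ordinal_split(cset: CompoundSet, period: int = 4, start: int = 2) -> CompoundSet:
    """Assign train/test roles by ordinal number: one compound out of every
    ``period`` (those with ordinal ≡ start mod period) goes to the test set.

    With the 65-compound fixture and the defaults this reproduces the
    published 49/16 train/test partition.
    """
    if len(cset) == 0:
        raise ValueError("cannot split an empty compound set")
    if period < 2:
        raise ValueError(f"period must be >= 2 (got {period})")
    if not 1 <= start <= period:
        raise ValueError(f"start must be in [1, period] (got {start})")
    records = [
        replace(r, role="test" if r.ordinal % period == start % period else "train")
        for r in cset.records
    ]
    return CompoundSet(records, provenance=f"{cset.provenance}|split({period},{start})")


def _resolve_activity(row: dict, ordinal: int, ic50_unit: str) -> tuple[float, Optional[float]]:
    scale = {"M": 1.0, "nM": 1e-9, "uM": 1e-6}[ic50_unit]
    ic50 = row.get("ic50_molar")
    if ic50 is not None and not pd.isna(ic50):
        ic50 = float(ic50) * scale
    else:
        ic50 = None
    pic50 = row.get("pic50")
    if pic50 is not None and not pd.isna(pic50):
        pic50 = float(pic50)
    elif ic50 is not None:
        pic50 = pic50_from_ic50(ic50)
    else:
        raise ValueError(f"compound {ordinal}: neither pic50 nor ic50 given")
    return pic50, ic50


def load_compound_table(path, ic50_unit: str = "M", sep: str = ",") -> CompoundSet:
    """Read a delimited compound table.

    Required columns: ``ordinal`` plus at least one of ``pic50`` /
    ``ic50_molar``.  Optional: ``smiles``, ``role``.  IC50 values are molar
    unless ``ic50_unit`` says otherwise ('nM', 'uM'); units are never
    guessed from magnitudes.
    """
    if ic50_unit not in ("M", "nM", "uM"):
        raise ValueError(f"ic50_unit must be M, nM or uM (got {ic50_unit!r})")
    df = pd.read_csv(path, sep=sep)
    if df.empty and len(df.columns) == 0:
        raise ValueError(f"{path}: empty file")
    if "ordinal" not in df.columns:
        raise ValueError(f"{path}: missing mandatory column 'ordinal'")
    if "pic50" not in df.columns and "ic50_molar" not in df.columns:
        raise ValueError(f"{path}: need a 'pic50' or 'ic50_molar' column")
    records = []
    for lineno, row in enumerate(df.to_dict("records"), start=2):
        try:
            ordinal = int(row["ordinal"])
            pic50, ic50 = _resolve_activity(row, ordinal, ic50_unit)
            smiles = row.get("smiles")
            smiles = None if smiles is None or pd.isna(smiles) else str(smiles)
            role = row.get("role")
            role = "unassigned" if role is None or pd.isna(role) else str(role)
            meta = {k: row[k] for k in row
                    if k not in ("ordinal", "smiles", "ic50_molar", "pic50", "role")}
            records.append(CompoundRecord(ordinal=ordinal, pic50=pic50, smiles=smiles,
                                          ic50=ic50, role=role, meta=meta))
        except (ValueError, KeyError, TypeError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return CompoundSet(records, provenance=str(path))


def save_compound_table(cset: CompoundSet, path, sep: str = ",") -> None:
    """Write a CompoundSet back to delimited text (round-trip safe)."""
    df = cset.to_frame()
    df["pic50"] = df["pic50"].map(lambda v: repr(float(v)))
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("qsarkit.data") / name)


#: Best-effort substituent-name -> fragment SMILES map ('*' marks the
#: attachment).  Synthetic reconstructions; structures are illustrative only.
_SUBSTITUENT_SMILES = {
    "H": "*[H]",
    "Me": "*C",
    "Cl": "*Cl",
    "Br": "*Br",
    "CN": "*C#N",
    "CF3": "*C(F)(F)F",
    "Ph": "*c1ccccc1",
    "Cyclopropyl": "*C1CC1",
    "4-Methoxy-phenyl": "*c1ccc(OC)cc1",
    "3-Hydroxy-phenyl": "*c1cccc(O)c1",
    "Benzo[1.3]dioxole-5-yl": "*c1ccc2OCOc2c1",
    "m-Dimethylamino": "*c1cccc(N(C)C)c1",
    "p-Methoxy": "*c1ccc(OC)cc1",
    "m-Methoxy": "*c1cccc(OC)c1",
    "o-Methoxy": "*c1ccccc1OC",
    "p-Pyrrolidin-1-yl": "*c1ccc(N2CCCC2)cc1",
    "p-Pyrid-2-yl": "*c1ccc(-c2ccccn2)cc1",
    "4-Dimethylamino-phenyl": "*c1ccc(N(C)C)cc1",
    "4-Dimethylaminomethyl-phenyl": "*c1ccc(CN(C)C)cc1",
    "4-Morpholin-4-ylmethyl-phenyl": "*c1ccc(CN2CCOCC2)cc1",
    "Phenylcarbamoylmethyl": "*CC(=O)Nc1ccccc1",
    "Pyridin-3-ylcarbamoylmethyl": "*CC(=O)Nc1cccnc1",
    "(3-Chloro-phenylcarbamoyl)-methyl": "*CC(=O)Nc1cccc(Cl)c1",
    "Phenylcarbamoyl": "*C(=O)Nc1ccccc1",
    "Benzenesulfonyl": "*S(=O)(=O)c1ccccc1",
    "Isobutyl": "*CC(C)C",
    "1-Pyridin-4-yl-ethyl": "*C(C)c1ccncc1",
    "1-Phenyl-ethyl": "*C(C)c1ccccc1",
    "Pyridin-4-ylmethyl": "*Cc1ccncc1",
    "Pyridin-3-ylmethyl": "*Cc1cccnc1",
    "Pyrimidin-5-ylmethyl": "*Cc1cncnc1",
    "4-Chloro-benzyl": "*Cc1ccc(Cl)cc1",
    "Cyclopropylmethyl": "*CC1CC1",
    "5-Methyl-isoxazol-3-ylmethyl": "*Cc1cc(C)on1",
    "2-Ethyl-oxazol-4-ylmethyl": "*Cc1coc(CC)n1",
    "1-Methyl-4H-imidazol-2-ylmethyl": "*Cc1nccn1C",
    "Thiazol-4-ylmethyl": "*Cc1cscn1",
    "Piperazin-1-ylmethyl": "*CN1CCNCC1",
    "Dimethylaminomethyl": "*CN(C)C",
    "Aminomethyl": "*CN",
    "2-Hydroxy-ethoxy": "*OCCO",
    "Piperazin-1-yl": "*N1CCNCC1",
    "4-Methyl-piperazin-1-yl": "*N1CCN(C)CC1",
    "Pyrazol-1-ylmethyl": "*Cn1cccn1",
}

#: Imidazo[4,5-b]pyridine core with the two variable positions marked.
AURORA_SCAFFOLD = "[*:1]c1cnc2[nH]c([*:2])nc2c1"


def substituent_smiles(name: str) -> str:
    """Best-effort fragment SMILES for a substituent name (synthetic)."""
    try:
        return _SUBSTITUENT_SMILES[name]
    except KeyError:
        raise KeyError(f"no SMILES reconstruction for substituent {name!r}") from None


def _assemble_smiles(r1: str, r2: str) -> Optional[str]:
    """Best-effort full-molecule SMILES from the two substituent names."""
    from rdkit import Chem

    from .rgroup import Fragment, RGroupCutSpec, assemble

    if r1 not in _SUBSTITUENT_SMILES or r2 not in _SUBSTITUENT_SMILES:
        return None
    try:
        mol = assemble(RGroupCutSpec(AURORA_SCAFFOLD),
                       {"Ra": Fragment(_SUBSTITUENT_SMILES[r1]),
                        "Rb": Fragment(_SUBSTITUENT_SMILES[r2])})
    except ValueError:
        return None
    return Chem.MolToSmiles(mol)


def load_aurora_table(with_smiles: bool = False) -> CompoundSet:
    """The packaged 65-compound Aurora-A inhibitor fixture.

    Ordinals, substituent names, experimental pIC50 and the published
    train/test partition (test = ordinal ≡ 2 mod 4; 49 train / 16 test).
    With ``with_smiles=True``, attaches best-effort synthetic SMILES
    reconstructions (non-authoritative; some substituent patterns may fail
    to reconstruct and stay None).
    """
    cset = load_compound_table(_data_path("aurora_pic50.csv"))
    if with_smiles:
        records = [
            replace(r, smiles=_assemble_smiles(r.meta.get("r1"), r.meta.get("r2")))
            for r in cset.records
        ]
        cset = CompoundSet(records, provenance=cset.provenance + "+smiles(synthetic)")
    return cset


def load_aurora_predictions() -> pd.DataFrame:
    """Per-compound predicted pIC50 of the four published models.

    Columns: ordinal, pic50_exp, hqsar, comfa, comsia, topomer.  The
    train/test partition follows :func:`load_aurora_table`.
    """
    df = pd.read_csv(_data_path("aurora_model_predictions.csv"))
    df["role"] = ["test" if o % 4 == 2 else "train" for o in df["ordinal"]]
    return df


def load_reference_validation() -> pd.DataFrame:
    """Published external-validation statistics (reference context only)."""
    return pd.read_csv(_data_path("aurora_validation_reference.csv"), index_col="metric")


def published_model_r2(model: str) -> float:
    """Published non-cross-validated training r^2 for one of the four models."""
    return PUBLISHED_MODEL_R2[model]
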