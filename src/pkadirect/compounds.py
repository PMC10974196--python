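"""The benzoic-acid benchmark panel and compound-set I/O.

The built-in panel is the eleven substituted benzoic acids used to
benchmark density functionals for direct-approach pKa prediction:
the parent acid plus bromo-, chloro-, methoxy-, cyano- and 2,6-dimethyl
derivatives probing inductive, conjugative and ortho effects.  Reference
pKa values are the experimental constants tabulated by PubChem (NIH).
Ring positions are numbered with the carboxyl carbon as position 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from rdkit import Chem

__all__ = ["Compound", "builtin_compounds", "load_compounds", "write_compounds"]

_ALLOWED_GROUPS = {"H", "CH3", "Br", "Cl", "OCH3", "CN"}
_ALLOWED_POSITIONS = {2, 3, 4, 6}


@dataclass(frozen=True)
class Compound:
    """A named benzoic-acid derivative with reference acidity.

    ``substituents`` maps ring positions (2, 3, 4, 6; carboxyl C = 1) to
    the non-hydrogen group at that position; unlisted positions carry H.
    """

    name: str
    smiles: str
    pka_ref: float
    substituents: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES for {self.name!r}: {self.smiles!r}")
        object.__setattr__(self, "smiles", Chem.MolToSmiles(mol))
        for pos, group in self.substituents.items():
            if pos not in _ALLOWED_POSITIONS:
                raise ValueError(f"{self.name!r}: ring position {pos} not in {sorted(_ALLOWED_POSITIONS)}")
            if group not in _ALLOWED_GROUPS:
                raise ValueError(f"{self.name!r}: unknown substituent group {group!r}")

    def to_mol(self) -> Chem.Mol:
        """RDKit molecule (no explicit hydrogens)."""
        return Chem.MolFromSmiles(self.smiles)


# Panel entries: (name, SMILES from the IUPAC name, substituent map, reference pKa).
_PANEL = [
    ("Benzoic Acid", "OC(=O)c1ccccc1", {}, 4.20),
    ("4-Cyanobenzoic Acid", "OC(=O)c1ccc(C#N)cc1", {4: "CN"}, 3.55),
    ("2,6-Dimethylbenzoic Acid", "OC(=O)c1c(C)cccc1C", {2: "CH3", 6: "CH3"}, 3.24),
    ("4-Bromobenzoic Acid", "OC(=O)c1ccc(Br)cc1", {4: "Br"}, 3.96),
    ("2-Bromobenzoic Acid", "OC(=O)c1ccccc1Br", {2: "Br"}, 2.96),
    ("2-Chlorobenzoic Acid", "OC(=O)c1ccccc1Cl", {2: "Cl"}, 2.96),
    ("3-Chlorobenzoic Acid", "OC(=O)c1cccc(Cl)c1", {3: "Cl"}, 3.83),
    ("4-Chlorobenzoic Acid", "OC(=O)c1ccc(Cl)cc1", {4: "Cl"}, 3.99),
    ("2-Methoxybenzoic Acid", "COc1ccccc1C(=O)O", {2: "OCH3"}, 4.09),
    ("3-Methoxybenzoic Acid", "COc1cccc(C(=O)O)c1", {3: "OCH3"}, 4.10),
    ("4-Methoxybenzoic Acid", "COc1ccc(C(=O)O)cc1", {4: "OCH3"}, 4.50),
]


def builtin_compounds() -> list[Compound]:
    """The eleven-compound benchmark panel, in canonical table order."""
    return [
        Compound(name=name, smiles=smi, substituents=subs, pka_ref=pka)
        for name, smi, subs, pka in _PANEL
    ]


def load_compounds(path: str | Path) -> list[Compound]:
    """Read a compound set from CSV with columns ``name,smiles,pka_ref``.

    Substituent positions are not stored in the CSV; they are left empty
    for loaded compounds (cluster building does not need them).

    Raises
    ------
    ValueError
        If a required column is missing, a pKa does not parse, or a
        SMILES is unparsable (the offending row is named).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in ("name", "smiles", "pka_ref"):
            if col not in header:
                raise ValueError(f"compound CSV {path} is missing required column {col!r}")
        out: list[Compound] = []
        for i, row in enumerate(reader, start=2):
            name = row["name"].strip()
            try:
                pka_ref = float(row["pka_ref"])
            except ValueError as exc:
                raise ValueError(f"row {i} ({name!r}): unparsable pka_ref {row['pka_ref']!r}") from exc
            try:
                out.append(Compound(name=name, smiles=row["smiles"].strip(), pka_ref=pka_ref))
            except ValueError as exc:
                raise ValueError(f"row {i} ({name!r}): {exc}") from exc
    return out


def write_compounds(compounds: list[Compound], path: str | Path) -> None:
    """Write a compound set as ``name,smiles,pka_ref`` CSV (round-trips with load)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "smiles", "pka_ref"])
        for c in compounds:
            writer.writerow([c.name, c.smiles, repr(c.pka_ref)])
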