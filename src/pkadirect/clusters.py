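"""Initial 3D structures for the four species of the deprotonation equilibrium.

Each species carries two explicit water molecules at the reaction center:

* ``acid``      — RCO2H·(H2O)2, neutral singlet: one water accepts a hydrogen
  bond from the acidic H, one donates to the carbonyl O.
* ``base``      — RCO2⁻·(H2O)2, anionic singlet: each water donates one H to
  one carboxylate oxygen.
* ``hydroxide`` — OH⁻·(H2O)2, anionic singlet (fixed template).
* ``water``     — H2O·(H2O)2, neutral singlet (fixed template).

Water placement is purely geometric (hydrogen-bond distance 1.85 Å, linear
donor–H···acceptor contacts, monomer geometry r(OH) = 0.9572 Å,
∠HOH = 104.52°) and is built from solute-derived directions only, so it is
covariant under rigid transforms of the solute.  Solute coordinates come
from RDKit distance-geometry embedding (fixed seed) followed by an MMFF94
relaxation, which reproduces the expected carboxyl rotamer: coplanar with
the ring for unhindered acids, twisted out of plane under the ortho effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .compounds import Compound
from .structures import AtomicStructure

__all__ = [
    "ClusterSpec",
    "EMBED_SEED",
    "HBOND_LENGTH",
    "build_species",
    "embed_3d",
    "place_waters",
]

#: Random seed of the distance-geometry embedding; fixed so structures are
#: bit-reproducible run to run.
EMBED_SEED = 1255

#: Initial hydrogen-bond contact distance (Å) used in every template.
HBOND_LENGTH = 1.85

_OH_BOND = 0.9572  # Å, water monomer
_HOH_ANGLE = np.deg2rad(104.52)

_CARBOXYL_SMARTS = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H]")


@dataclass(frozen=True)
class ClusterSpec:
    """Which of the four species to build.

    ``compound`` is required for acid/base and must be absent for the
    compound-independent hydroxide and water clusters.
    """

    kind: str
    compound: Optional[Compound] = None
    n_explicit_waters: int = field(default=2)

    def __post_init__(self) -> None:
        if self.kind not in {"acid", "base", "hydroxide", "water"}:
            raise ValueError(f"unknown cluster kind {self.kind!r}")
        if self.n_explicit_waters != 2:
            raise ValueError("the model uses exactly two explicit water molecules")
        needs_compound = self.kind in {"acid", "base"}
        if needs_compound and self.compound is None:
            raise ValueError(f"kind {self.kind!r} requires a compound")
        if not needs_compound and self.compound is not None:
            raise ValueError(f"kind {self.kind!r} takes no compound")


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-9:
        raise ValueError("degenerate direction vector")
    return v / n


def _perp_component(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    return _unit(v - float(np.dot(v, axis)) * axis)


def embed_3d(compound: Compound, seed: int = EMBED_SEED) -> AtomicStructure:
    """Deterministic 3D coordinates of the (isolated, protonated) acid.

    The structure carries the full reaction-center role map: carboxyl
    carbon, carbonyl/hydroxyl oxygens, acidic hydrogen, and the ipso and
    (lower-index) ortho ring carbons.  The same compound and seed always
    give bitwise-identical coordinates.
    """
    mol = compound.to_mol()
    matches = mol.GetSubstructMatches(_CARBOXYL_SMARTS)
    if len(matches) != 1:
        raise ValueError(
            f"{compound.name!r} has {len(matches)} carboxylic groups; "
            "exactly one monocarboxylic acid is supported"
        )
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ValueError(f"3D embedding failed for {compound.name!r}")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)

    carboxyl_c, carbonyl_o, hydroxyl_o = mol.GetSubstructMatch(_CARBOXYL_SMARTS)
    acidic_h = next(
        a.GetIdx()
        for a in mol.GetAtomWithIdx(hydroxyl_o).GetNeighbors()
        if a.GetAtomicNum() == 1
    )
    ring_neighbors = [
        a.GetIdx()
        for a in mol.GetAtomWithIdx(carboxyl_c).GetNeighbors()
        if a.GetAtomicNum() == 6
    ]
    if not ring_neighbors:
        raise ValueError(f"{compound.name!r}: carboxyl group is not attached to a carbon")
    ipso = ring_neighbors[0]
    orthos = [
        a.GetIdx()
        for a in mol.GetAtomWithIdx(ipso).GetNeighbors()
        if a.GetIdx() != carboxyl_c and a.GetAtomicNum() == 6 and a.GetIsAromatic()
    ]
    if not orthos:
        raise ValueError(f"{compound.name!r}: carboxyl carbon is not bound to an aromatic ring")
    conf = mol.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    roles = {
        carboxyl_c: "carboxyl_C",
        carbonyl_o: "carbonyl_O",
        hydroxyl_o: "hydroxyl_O",
        acidic_h: "acidic_H",
        ipso: "ring_C_ipso",
        min(orthos): "ring_C_ortho",
    }
    return AtomicStructure(
        elements=tuple(a.GetSymbol() for a in mol.GetAtoms()),
        coordinates=coords,
        charge=0,
        multiplicity=1,
        roles=roles,
        label=f"molecule:{compound.name}",
    ).validate()


def _water_donating_to(
    acceptor: np.ndarray, direction: np.ndarray, perp: np.ndarray
) -> np.ndarray:
    """Water donating one H to ``acceptor`` along unit ``direction``.

    Returns the 3×3 coordinates (O, donating H, free H); the O–H···acceptor
    contact is linear at :data:`HBOND_LENGTH`.
    """
    h_don = acceptor + HBOND_LENGTH * direction
    ow = acceptor + (HBOND_LENGTH + _OH_BOND) * direction
    free_dir = np.cos(_HOH_ANGLE) * (-direction) + np.sin(_HOH_ANGLE) * perp
    h_free = ow + _OH_BOND * free_dir
    return np.array([ow, h_don, h_free])


def _water_accepting_from(
    donor_h: np.ndarray, direction: np.ndarray, perp: np.ndarray
) -> np.ndarray:
    """Water accepting a hydrogen bond on ``donor_h`` along unit ``direction``."""
    ow = donor_h + HBOND_LENGTH * direction
    half = _HOH_ANGLE / 2
    d1 = np.cos(half) * direction + np.sin(half) * perp
    d2 = np.cos(half) * direction - np.sin(half) * perp
    return np.array([ow, ow + _OH_BOND * d1, ow + _OH_BOND * d2])


def place_waters(solute: AtomicStructure) -> AtomicStructure:
    """Append the two explicit waters to an acid or base solute.

    The solute must carry reaction-center roles (``acidic_H`` marks an
    acid; ``carboxylate_O1``/``O2`` mark a base).  Placement uses only
    directions derived from solute atoms, so a rigidly transformed solute
    yields the identically transformed cluster.
    """
    roles = dict(solute.roles)
    coords = solute.coordinates
    c_idx = solute.atoms_with_role("carboxyl_C")
    if not c_idx:
        raise ValueError("solute lacks a carboxyl_C role")
    c = coords[c_idx[0]]

    if solute.atoms_with_role("acidic_H"):
        od = coords[solute.atoms_with_role("carbonyl_O")[0]]
        oh = coords[solute.atoms_with_role("hydroxyl_O")[0]]
        ha = coords[solute.atoms_with_role("acidic_H")[0]]
        # water 1 accepts from the acidic H (contact b)
        u = _unit(ha - oh)
        v = _perp_component(od - c, u)
        w1 = _water_accepting_from(ha, u, v)
        # water 2 donates to the carbonyl O (contact a)
        w = _unit(od - c)
        v2 = _perp_component(oh - c, w)
        w2 = _water_donating_to(od, w, v2)
    elif solute.atoms_with_role("carboxylate_O1"):
        o1 = coords[solute.atoms_with_role("carboxylate_O1")[0]]
        o2 = coords[solute.atoms_with_role("carboxylate_O2")[0]]
        # one water donating to each carboxylate O (contacts a', a'')
        w1 = _water_donating_to(o1, _unit(o1 - c), _perp_component(o2 - c, _unit(o1 - c)))
        w2 = _water_donating_to(o2, _unit(o2 - c), _perp_component(o1 - c, _unit(o2 - c)))
    else:
        raise ValueError("solute roles identify neither an acid nor a carboxylate base")

    n = solute.n_atoms
    for k in range(2):
        roles[n + 3 * k] = "water_O"
        roles[n + 3 * k + 1] = "water_H"
        roles[n + 3 * k + 2] = "water_H"
    return AtomicStructure(
        elements=solute.elements + ("O", "H", "H") * 2,
        coordinates=np.vstack([coords, w1, w2]),
        charge=solute.charge,
        multiplicity=solute.multiplicity,
        roles=roles,
        label=solute.label,
    ).validate()


def _deprotonate(acid: AtomicStructure) -> AtomicStructure:
    """Remove the acidic H, relabel the oxygens as carboxylate O1/O2."""
    h_idx = acid.atoms_with_role("acidic_H")[0]
    keep = [i for i in range(acid.n_atoms) if i != h_idx]
    remap = {old: new for new, old in enumerate(keep)}
    roles: dict[int, str] = {}
    for old, role in acid.roles.items():
        if old == h_idx:
            continue
        if role in ("carbonyl_O", "hydroxyl_O"):
            continue
        roles[remap[old]] = role
    o_old = sorted(acid.atoms_with_role("carbonyl_O") + acid.atoms_with_role("hydroxyl_O"))
    roles[remap[o_old[0]]] = "carboxylate_O1"
    roles[remap[o_old[1]]] = "carboxylate_O2"
    return AtomicStructure(
        elements=tuple(acid.elements[i] for i in keep),
        coordinates=acid.coordinates[keep],
        charge=acid.charge - 1,
        multiplicity=acid.multiplicity,
        roles=roles,
        label=acid.label,
    )


# Fixed templates for the compound-independent species.  Water geometry as
# above; hydrogen bonds 1.85 Å and near-linear.  Chain arrangement for the
# hydroxide cluster (both waters donate to the hydroxide O), cyclic ring
# for the water trimer.
_HYDROXIDE_TEMPLATE = [
    ("O", 0.000000, 0.000000, 0.000000),
    ("H", 0.000000, 0.000000, 0.970000),
    ("O", 2.807200, 0.000000, 0.000000),
    ("H", 1.850000, 0.000000, 0.000000),
    ("H", 3.047187, 0.000000, 0.926627),
    ("O", -0.960119, 2.637905, 0.000000),
    ("H", -0.632737, 1.738431, 0.000000),
    ("H", -1.042199, 2.863419, -0.926627),
]

_WATER_TRIMER_TEMPLATE = [
    ("O", 0.000000, 1.616581, 0.000000),
    ("H", -0.478600, 0.787621, 0.000000),
    ("H", 0.119994, 1.824416, 0.926627),
    ("O", -1.400000, -0.808290, 0.000000),
    ("H", -0.442800, -0.808290, 0.000000),
    ("H", -1.639987, -0.808290, 0.926627),
    ("O", 1.400000, -0.808290, 0.000000),
    ("H", 0.921400, 0.020669, 0.000000),
    ("H", 1.519994, -1.016125, 0.926627),
]


def _from_template(template, charge: int, roles: dict[int, str], label: str) -> AtomicStructure:
    return AtomicStructure(
        elements=tuple(row[0] for row in template),
        coordinates=np.array([row[1:] for row in template]),
        charge=charge,
        multiplicity=1,
        roles=roles,
        label=label,
    ).validate()


def build_species(spec: ClusterSpec, seed: int = EMBED_SEED) -> AtomicStructure:
    """Initial structure for one species of the dissociation equilibrium."""
    if spec.kind == "acid":
        solute = replace(embed_3d(spec.compound, seed), label=f"acid:{spec.compound.name}")
        return place_waters(solute)
    if spec.kind == "base":
        base = _deprotonate(embed_3d(spec.compound, seed))
        return place_waters(replace(base, label=f"base:{spec.compound.name}"))
    if spec.kind == "hydroxide":
        roles = {0: "hydroxyl_O", 2: "water_O", 3: "water_H", 4: "water_H",
                 5: "water_O", 6: "water_H", 7: "water_H"}
        return _from_template(_HYDROXIDE_TEMPLATE, -1, roles, "hydroxide")
    roles = {3 * k + j: ("water_O" if j == 0 else "water_H") for k in range(3) for j in range(3)}
    return _from_template(_WATER_TRIMER_TEMPLATE, 0, roles, "water")
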