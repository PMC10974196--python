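"""Reaction-center geometry diagnostics.

For each acid/base cluster the diagnostics are the hydrogen-bond and
covalent contacts that describe the reaction center —

* acid:  ``a`` carbonyl O···water H, ``b`` water O···acidic H,
  ``c`` the covalent O–H of the acid group;
* base:  ``a_prime`` and ``a_second``, the water-H···carboxylate-O
  contact of each of the two waters;

— plus the twist of the carboxyl moiety against the aromatic ring
(a torsion folded into [0°, 90°]), the acid/base pair average of that
twist, and per-functional bond-length differences against a reference
functional (Δ_length).  Selection is driven by role labels, never atom
order, so all metrics are invariant under rigid transforms and atom
reindexing; roles can be inferred from connectivity for structures parsed
from role-free sources such as engine logs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import permutations
from typing import Mapping

import numpy as np
import pandas as pd

from .structures import AtomicStructure

__all__ = [
    "AnalysisError",
    "DELTA_LENGTH_OUTLIER",
    "DeltaLengthReport",
    "ReactionCenterMetrics",
    "carboxyl_ring_dihedral",
    "delta_length",
    "distance",
    "fold_dihedral",
    "infer_roles",
    "pair_average_dihedral",
    "reaction_center_metrics",
]


class AnalysisError(ValueError):
    """A structure lacks (and cannot be given) the roles an analysis needs."""


#: |Δ_length| above this (Å) is annotated as an outlier in reports — the
#: empirical envelope of functional-to-functional bond-length scatter.
DELTA_LENGTH_OUTLIER = 0.25

_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}


@dataclass(frozen=True)
class ReactionCenterMetrics:
    """Contact lengths (Å) and carboxyl–ring dihedral (deg) of one species."""

    kind: str  # "acid" | "base"
    lengths: Mapping[str, float]
    dihedral: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lengths", dict(self.lengths))
        expected = {"a", "b", "c"} if self.kind == "acid" else {"a_prime", "a_second"}
        if set(self.lengths) != expected:
            raise ValueError(f"{self.kind} metrics need labels {sorted(expected)}, got {sorted(self.lengths)}")
        for label, value in self.lengths.items():
            if not (0 < value < 5):
                raise ValueError(f"length {label}={value:.3f} Å outside (0, 5)")
        if not (0 <= self.dihedral <= 90):
            raise ValueError(f"dihedral {self.dihedral} outside [0, 90]")


def distance(structure: AtomicStructure, i: int, j: int) -> float:
    """Euclidean distance (Å) between atom centers ``i`` and ``j``."""
    n = structure.n_atoms
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"atom index out of range for {n}-atom structure: ({i}, {j})")
    if i == j:
        raise ValueError("distance requires two distinct atoms")
    return float(np.linalg.norm(structure.coordinates[i] - structure.coordinates[j]))


def fold_dihedral(theta_deg: float) -> float:
    """Fold any torsion angle into [0°, 90°]: f(θ) = f(−θ) = f(180°−θ)."""
    t = abs(theta_deg) % 180.0
    return 180.0 - t if t > 90.0 else t


def _torsion_deg(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1u, v), w))
    return float(np.degrees(np.arctan2(y, x)))


def _bonded(structure: AtomicStructure) -> list[set[int]]:
    coords = structure.coordinates
    n = structure.n_atoms
    neighbors: list[set[int]] = [set() for _ in range(n)]
    radii = [_COVALENT_RADII.get(el, 0.77) for el in structure.elements]
    for i in range(n):
        for j in range(i + 1, n):
            cutoff = (radii[i] + radii[j]) * 1.2
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                neighbors[i].add(j)
                neighbors[j].add(i)
    return neighbors


def infer_roles(structure: AtomicStructure) -> AtomicStructure:
    """Assign reaction-center roles from connectivity.

    Carboxyl C is the carbon bonded to two oxygens; waters are oxygens
    bonded to exactly two hydrogens and nothing else; an H on a carboxyl
    oxygen marks the acid form, its absence the carboxylate.  Bonds use a
    covalent-radius cutoff scaled by 1.2.
    """
    nb = _bonded(structure)
    els = structure.elements
    roles: dict[int, str] = {}

    water_os = [
        i for i, el in enumerate(els)
        if el == "O" and len(nb[i]) == 2 and all(els[j] == "H" for j in nb[i])
    ]
    for o in water_os:
        roles[o] = "water_O"
        for h in nb[o]:
            roles[h] = "water_H"

    carboxyl_cs = [
        i for i, el in enumerate(els)
        if el == "C" and sum(els[j] == "O" and j not in water_os for j in nb[i]) == 2
    ]
    if len(carboxyl_cs) != 1:
        raise AnalysisError(
            f"expected exactly one carboxyl carbon, found {len(carboxyl_cs)}"
        )
    c = carboxyl_cs[0]
    roles[c] = "carboxyl_C"
    oxygens = sorted(j for j in nb[c] if els[j] == "O")
    o_h = {o: [h for h in nb[o] if els[h] == "H" and h not in roles] for o in oxygens}
    protonated = [o for o in oxygens if o_h[o]]
    if protonated:  # acid form
        hydroxyl = protonated[0]
        carbonyl = next(o for o in oxygens if o != hydroxyl)
        roles[hydroxyl] = "hydroxyl_O"
        roles[carbonyl] = "carbonyl_O"
        roles[o_h[hydroxyl][0]] = "acidic_H"
    else:  # carboxylate
        roles[oxygens[0]] = "carboxylate_O1"
        roles[oxygens[1]] = "carboxylate_O2"

    ring_neighbors = [j for j in nb[c] if els[j] == "C"]
    if ring_neighbors:
        ipso = ring_neighbors[0]
        roles[ipso] = "ring_C_ipso"
        orthos = [j for j in nb[ipso] if j != c and els[j] == "C"]
        if orthos:
            roles[min(orthos)] = "ring_C_ortho"

    return replace(structure, roles=roles)


def _ensure_roles(structure: AtomicStructure) -> AtomicStructure:
    if structure.atoms_with_role("carboxyl_C"):
        return structure
    return infer_roles(structure)


def carboxyl_ring_dihedral(structure: AtomicStructure, method: str = "torsion") -> float:
    """Twist of the carboxyl/carboxylate moiety against the ring, in [0°, 90°].

    ``method="torsion"`` (default) uses the ortho-C → ipso-C → carboxyl-C
    → carboxyl-O 4-atom torsion; ``method="plane"`` uses the angle between
    the best-fit aromatic-ring plane and the carboxyl plane.
    """
    structure = _ensure_roles(structure)
    missing = [
        r for r in ("ring_C_ortho", "ring_C_ipso", "carboxyl_C")
        if not structure.atoms_with_role(r)
    ]
    if missing:
        raise AnalysisError(
            f"cannot measure carboxyl-ring dihedral; missing roles: {', '.join(missing)} "
            "(is the input aromatic?)"
        )
    c = structure.atoms_with_role("carboxyl_C")[0]
    ipso = structure.atoms_with_role("ring_C_ipso")[0]
    ortho = structure.atoms_with_role("ring_C_ortho")[0]
    o_roles = ("carbonyl_O", "carboxylate_O1")
    o_idx = next(
        (structure.atoms_with_role(r)[0] for r in o_roles if structure.atoms_with_role(r)),
        None,
    )
    if o_idx is None:
        raise AnalysisError("cannot measure carboxyl-ring dihedral; missing roles: carbonyl_O")
    xyz = structure.coordinates
    if method == "torsion":
        return fold_dihedral(_torsion_deg(xyz[ortho], xyz[ipso], xyz[c], xyz[o_idx]))
    if method == "plane":
        nb = _bonded(structure)
        ring = {ipso, ortho}
        frontier = [ortho]
        while frontier:
            a = frontier.pop()
            for j in nb[a]:
                if structure.elements[j] == "C" and j != c and j not in ring:
                    ring.add(j)
                    frontier.append(j)
        ring_pts = xyz[sorted(ring)] - xyz[sorted(ring)].mean(axis=0)
        ring_normal = np.linalg.svd(ring_pts)[2][2]
        o_all = [
            structure.atoms_with_role(r)[0]
            for r in ("carbonyl_O", "hydroxyl_O", "carboxylate_O1", "carboxylate_O2")
            if structure.atoms_with_role(r)
        ]
        carb_normal = np.cross(xyz[o_all[0]] - xyz[c], xyz[o_all[1]] - xyz[c])
        carb_normal /= np.linalg.norm(carb_normal)
        cosang = abs(float(np.dot(ring_normal, carb_normal)))
        return fold_dihedral(float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
    raise ValueError(f"unknown method {method!r}; use 'torsion' or 'plane'")


def _waters(structure: AtomicStructure) -> list[tuple[int, list[int]]]:
    """(water O, its H atoms) pairs, H assigned to the nearest water O."""
    os_ = structure.atoms_with_role("water_O")
    hs = structure.atoms_with_role("water_H")
    groups: dict[int, list[int]] = {o: [] for o in os_}
    for h in hs:
        nearest = min(os_, key=lambda o: distance(structure, h, o))
        groups[nearest].append(h)
    return sorted(groups.items())


def reaction_center_metrics(structure: AtomicStructure) -> ReactionCenterMetrics:
    """Measure the reaction-center contacts and the carboxyl–ring twist."""
    structure = _ensure_roles(structure)
    if not structure.atoms_with_role("water_O"):
        raise AnalysisError("missing water_O role: no explicit waters in the structure")
    waters = _waters(structure)
    water_hs = structure.atoms_with_role("water_H")
    dihedral = carboxyl_ring_dihedral(structure)

    if structure.atoms_with_role("acidic_H"):
        carbonyl = structure.atoms_with_role("carbonyl_O")[0]
        hydroxyl = structure.atoms_with_role("hydroxyl_O")[0]
        acidic_h = structure.atoms_with_role("acidic_H")[0]
        lengths = {
            "a": min(distance(structure, carbonyl, h) for h in water_hs),
            "b": min(distance(structure, acidic_h, o) for o, _ in waters),
            "c": distance(structure, hydroxyl, acidic_h),
        }
        return ReactionCenterMetrics(kind="acid", lengths=lengths, dihedral=dihedral)

    o1s = structure.atoms_with_role("carboxylate_O1")
    o2s = structure.atoms_with_role("carboxylate_O2")
    if not (o1s and o2s):
        raise AnalysisError("missing carboxylate_O1/carboxylate_O2 roles")
    if len(waters) != 2:
        raise AnalysisError(f"carboxylate metrics need two waters, found {len(waters)}")

    def contact(water: tuple[int, list[int]], o: int) -> float:
        return min(distance(structure, h, o) for h in water[1])

    # each water donates to one carboxylate O; pick the assignment with the
    # minimal total contact length (ties resolved by enumeration order,
    # i.e. by ascending atom index)
    best = None
    for perm in permutations(range(2)):
        total = contact(waters[perm[0]], o1s[0]) + contact(waters[perm[1]], o2s[0])
        if best is None or total < best[0] - 1e-12:
            best = (total, perm)
    _, perm = best
    lengths = {
        "a_prime": contact(waters[perm[0]], o1s[0]),
        "a_second": contact(waters[perm[1]], o2s[0]),
    }
    return ReactionCenterMetrics(kind="base", lengths=lengths, dihedral=dihedral)


def pair_average_dihedral(acid_deg: float, base_deg: float) -> float:
    """Mean carboxyl–ring twist of an acid/conjugate-base pair."""
    for v in (acid_deg, base_deg):
        if not (0 <= v <= 90):
            raise ValueError(f"dihedral {v} outside [0, 90]")
    return (acid_deg + base_deg) / 2.0


@dataclass(frozen=True)
class DeltaLengthReport:
    """Signed per-label bond-length differences against a reference functional."""

    reference_functional: str
    table: pd.DataFrame  # columns: compound, functional, label, delta, outlier

    @property
    def outliers(self) -> pd.DataFrame:
        return self.table[self.table["outlier"]]


def delta_length(
    metrics: Mapping[str, Mapping[str, ReactionCenterMetrics]],
    reference_functional: str,
) -> DeltaLengthReport:
    """Δ_length: per-compound, per-label differences functional − reference.

    ``metrics`` maps functional → compound → :class:`ReactionCenterMetrics`.
    The reference functional's own rows are identically zero; any |Δ| above
    :data:`DELTA_LENGTH_OUTLIER` is flagged.
    """
    if reference_functional not in metrics:
        raise AnalysisError(f"reference functional {reference_functional!r} not present")
    reference = metrics[reference_functional]
    rows = []
    for functional in metrics:
        for compound, m in metrics[functional].items():
            if compound not in reference:
                raise AnalysisError(
                    f"reference functional {reference_functional!r} has no entry for {compound!r}"
                )
            ref_m = reference[compound]
            for label, value in m.lengths.items():
                delta = value - ref_m.lengths[label]
                rows.append(
                    {
                        "compound": compound,
                        "functional": functional,
                        "label": label,
                        "delta": delta,
                        "outlier": abs(delta) > DELTA_LENGTH_OUTLIER,
                    }
                )
    return DeltaLengthReport(
        reference_functional=reference_functional,
        table=pd.DataFrame(rows, columns=["compound", "functional", "label", "delta", "outlier"]),
    )
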