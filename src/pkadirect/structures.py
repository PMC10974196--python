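"""Cartesian structures with reaction-center role labels, and XYZ I/O.

The XYZ dialect is the standard one (count line, comment line, element
x y z rows); the comment line carries ``key=value`` metadata for cluster
kind, charge, multiplicity, an optional species label and the role map,
so a written cluster round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = ["AtomicStructure", "ROLE_LABELS", "read_xyz", "write_xyz"]

ROLE_LABELS = frozenset(
    {
        "carboxyl_C",
        "carbonyl_O",
        "hydroxyl_O",
        "acidic_H",
        "carboxylate_O1",
        "carboxylate_O2",
        "water_O",
        "water_H",
        "ring_C_ipso",
        "ring_C_ortho",
    }
)

_MIN_PAIR_DISTANCE = 0.5  # Å; anything closer is an unphysical clash


@dataclass(frozen=True)
class AtomicStructure:
    """Elements + Cartesian coordinates (Å) + charge/multiplicity + roles.

    ``roles`` is a partial map atom index → reaction-center role;
    ``label`` identifies the species (e.g. ``"acid:Benzoic Acid"``) and is
    what table-driven engines key on.
    """

    elements: tuple[str, ...]
    coordinates: np.ndarray
    charge: int = 0
    multiplicity: int = 1
    roles: Mapping[int, str] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "roles", dict(self.roles))
        if coords.shape != (len(self.elements), 3):
            raise ValueError(
                f"coordinates shape {coords.shape} does not match {len(self.elements)} elements"
            )
        if self.multiplicity < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.multiplicity}")
        for idx, role in self.roles.items():
            if not (0 <= idx < len(self.elements)):
                raise ValueError(f"role index {idx} out of range")
            if role not in ROLE_LABELS:
                raise ValueError(f"unknown role label {role!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def validate(self) -> "AtomicStructure":
        """Check finiteness and the minimum interatomic distance; return self."""
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if self.n_atoms >= 2:
            diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
            dist = np.sqrt((diff**2).sum(axis=-1))
            np.fill_diagonal(dist, np.inf)
            dmin = float(dist.min())
            if dmin <= _MIN_PAIR_DISTANCE:
                i, j = np.unravel_index(int(dist.argmin()), dist.shape)
                raise ValueError(
                    f"atoms {i} ({self.elements[i]}) and {j} ({self.elements[j]}) "
                    f"clash at {dmin:.3f} Å"
                )
        return self

    def formula_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for el in self.elements:
            counts[el] = counts.get(el, 0) + 1
        return counts

    def atoms_with_role(self, role: str) -> list[int]:
        return sorted(i for i, r in self.roles.items() if r == role)

    def transformed(self, rotation: np.ndarray, translation: Iterable[float]) -> "AtomicStructure":
        """Rigid-body transform: x → R·x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(list(translation), dtype=float)
        return replace(self, coordinates=self.coordinates @ rotation.T + translation)


def write_xyz(structure: AtomicStructure, path: str | Path | None = None) -> str:
    """Serialize to XYZ text; also write it to ``path`` if given."""
    meta = [f"charge={structure.charge}", f"multiplicity={structure.multiplicity}"]
    if structure.label:
        # the comment line is whitespace-tokenized on read, so escape spaces
        meta.append(f"label={structure.label.replace(' ', '%20')}")
    if structure.roles:
        roles = ",".join(f"{i}:{r}" for i, r in sorted(structure.roles.items()))
        meta.append(f"roles={roles}")
    lines = [str(structure.n_atoms), " ".join(meta)]
    for el, (x, y, z) in zip(structure.elements, structure.coordinates):
        lines.append(f"{el:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_xyz(source: str | Path) -> AtomicStructure:
    """Parse XYZ text (or a path to an XYZ file) written by :func:`write_xyz`.

    Plain third-party XYZ files (arbitrary comment line) parse too; the
    metadata then defaults to a neutral singlet with no roles.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    lines = text.splitlines()
    if len(lines) < 2:
        raise ValueError("XYZ input has fewer than two lines")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"bad XYZ count line: {lines[0]!r}") from exc
    charge, multiplicity, label = 0, 1, ""
    roles: dict[int, str] = {}
    for token in lines[1].split():
        if "=" not in token:
            continue
        key, _, value = token.partition("=")
        if key == "charge":
            charge = int(value)
        elif key == "multiplicity":
            multiplicity = int(value)
        elif key == "label":
            label = value.replace("%20", " ")
        elif key == "roles" and value:
            for pair in value.split(","):
                idx, _, role = pair.partition(":")
                roles[int(idx)] = role
    if len(lines) < 2 + n:
        raise ValueError(f"XYZ input declares {n} atoms but has {len(lines) - 2} coordinate lines")
    elements: list[str] = []
    coords: list[list[float]] = []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"bad XYZ coordinate line: {line!r}")
        elements.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    return AtomicStructure(
        elements=tuple(elements),
        coordinates=np.array(coords),
        charge=charge,
        multiplicity=multiplicity,
        roles=roles,
        label=label,
    )
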