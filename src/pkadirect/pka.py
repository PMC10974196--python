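"""Thermochemistry of the direct deprotonation approach.

The acid dissociation of a carboxylic acid is modelled as the explicit
ionogenic reaction in water,

    RCO2H·(H2O)2 + OH-·(H2O)2  ⇌  RCO2-·(H2O)2 + H2O·(H2O)2   (all solvated)

so the reaction free energy is assembled directly from the Gibbs free
energies of the four micro-solvated species,

    ΔG_dep = G(base) + G(water) - G(hydroxide) - G(acid)

and converted to a pKa through the water anchor

    pKa = ΔG_dep / (2.302·R·T) + 15.74

where 15.74 is the pKa of water at 298.15 K.  No empirical correction
factors, fits or experimental proton energies enter the conversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "GAS_CONSTANT",
    "HARTREE_TO_J_PER_MOL",
    "LOG10_FACTOR",
    "PKA_WATER",
    "STANDARD_TEMPERATURE",
    "PkaRecord",
    "delta_g_dep",
    "delta_g_from_pka",
    "pka_from_delta_g",
    "records_from_csv",
    "records_to_csv",
]

#: Gas constant R in J mol^-1 K^-1.
GAS_CONSTANT = 8.31446

#: 1 Hartree expressed in J mol^-1 (CODATA-consistent).
HARTREE_TO_J_PER_MOL = 2_625_499.6

#: Decadic-logarithm factor as conventionally printed in the pKa equation.
#: The exact value is ln(10) = 2.302585...; the difference is below the
#: 0.01 pKa reporting grain on this panel.  Pass ``log10_factor=math.log(10)``
#: to any conversion function to use the exact value.
LOG10_FACTOR = 2.302

#: pKa of water — the additive anchor of the conversion.  Valid at 298.15 K.
PKA_WATER = 15.74

#: Temperature (K) at which the water anchor holds.
STANDARD_TEMPERATURE = 298.15


def _check_temperature(temperature: float) -> None:
    if not math.isfinite(temperature) or temperature <= 0:
        raise ValueError(f"temperature must be positive and finite, got {temperature!r}")
    if abs(temperature - STANDARD_TEMPERATURE) > 1e-9:
        warnings.warn(
            "the 15.74 water-pKa anchor is only valid at 298.15 K; "
            f"using it at {temperature} K is an extrapolation",
            stacklevel=3,
        )


def delta_g_dep(
    g_base: float,
    g_water: float,
    g_hydroxide: float,
    g_acid: float,
) -> float:
    """Reaction free energy of the deprotonation equilibrium, in J/mol.

    Parameters are the Gibbs free energies (Hartree) of the four
    micro-solvated species: conjugate base, water trimer, hydroxide
    cluster and acid, each with its two explicit waters.
    """
    energies = (g_base, g_water, g_hydroxide, g_acid)
    if not all(math.isfinite(g) for g in energies):
        raise ValueError(f"all species energies must be finite, got {energies}")
    return (g_base + g_water - g_hydroxide - g_acid) * HARTREE_TO_J_PER_MOL


def pka_from_delta_g(
    delta_g: float,
    temperature: float = STANDARD_TEMPERATURE,
    *,
    log10_factor: float = LOG10_FACTOR,
) -> float:
    """Convert a deprotonation free energy (J/mol) to a pKa.

    At 298.15 K one pKa unit corresponds to 2.302·R·T ≈ 5706.6 J/mol;
    ΔG_dep = 0 returns the water anchor, 15.74.
    """
    _check_temperature(temperature)
    if not math.isfinite(delta_g):
        raise ValueError(f"delta_g must be finite, got {delta_g!r}")
    return delta_g / (log10_factor * GAS_CONSTANT * temperature) + PKA_WATER


def delta_g_from_pka(
    pka: float,
    temperature: float = STANDARD_TEMPERATURE,
    *,
    log10_factor: float = LOG10_FACTOR,
) -> float:
    """Exact inverse of :func:`pka_from_delta_g`, in J/mol."""
    _check_temperature(temperature)
    if not math.isfinite(pka):
        raise ValueError(f"pka must be finite, got {pka!r}")
    return (pka - PKA_WATER) * log10_factor * GAS_CONSTANT * temperature


@dataclass(frozen=True)
class PkaRecord:
    """One compound × functional result: ΔG_dep (J/mol) and the derived pKa."""

    compound: str
    functional: str
    delta_g_dep: float
    pka: float = field(default=None)  # type: ignore[assignment]
    temperature: float = STANDARD_TEMPERATURE

    def __post_init__(self) -> None:
        if self.pka is None:
            object.__setattr__(
                self, "pka", pka_from_delta_g(self.delta_g_dep, self.temperature)
            )
        else:
            expected = pka_from_delta_g(self.delta_g_dep, self.temperature)
            if abs(expected - self.pka) > 1e-9:
                raise ValueError(
                    f"inconsistent record: pka {self.pka} does not match "
                    f"delta_g_dep {self.delta_g_dep} J/mol (expected {expected})"
                )


def records_to_csv(records: list[PkaRecord]) -> str:
    """Serialize records as CSV (full precision; rounding happens in reports)."""
    lines = ["compound,functional,delta_g_dep_J_per_mol,pka"]
    for r in records:
        name = f'"{r.compound}"' if "," in r.compound else r.compound
        lines.append(f"{name},{r.functional},{r.delta_g_dep!r},{r.pka!r}")
    return "\n".join(lines) + "\n"


def records_from_csv(text: str) -> list[PkaRecord]:
    """Inverse of :func:`records_to_csv`."""
    import csv
    import io

    reader = csv.DictReader(io.StringIO(text))
    for col in ("compound", "functional", "delta_g_dep_J_per_mol", "pka"):
        if col not in (reader.fieldnames or []):
            raise ValueError(f"records CSV is missing required column {col!r}")
    return [
        PkaRecord(
            compound=row["compound"],
            functional=row["functional"],
            delta_g_dep=float(row["delta_g_dep_J_per_mol"]),
            pka=float(row["pka"]),
        )
        for row in reader
    ]
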