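"""Gaussian-dialect input decks and output logs.

Covers the three text artefacts a Gaussian-style engine exchanges:

* :func:`write_input` — an opt+freq input deck (route line, title,
  charge/multiplicity, Cartesian block);
* :func:`parse_log` — extraction of the final thermochemistry
  ("Sum of electronic and thermal Free Energies"), the harmonic frequency
  block, the last orientation block, charge/multiplicity, the
  normal-termination flag and the elapsed wall time;
* :func:`write_log` — a synthetic log emitter used as the round-trip
  oracle for the parser and by the mock engine's log-directory workflow.

Only fields actually present in the log are reported; a truncated log
yields ``converged=False`` with whatever could be read.
"""

from __future__ import annotations

import re

import numpy as np

from .structures import AtomicStructure
from .engines import QMResult, QMSettings

__all__ = ["SUPPORTED_FUNCTIONALS", "parse_log", "write_input", "write_log"]

#: Functional labels accepted on a route line, in benchmark column order.
SUPPORTED_FUNCTIONALS = (
    "CAM-B3LYP",
    "B3PW91",
    "PBE1PBE",
    "PBEPBE",
    "TPSSTPSS",
    "WB97XD",
)

_SYMBOL_TO_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "Cl": 17, "Br": 35}
_Z_TO_SYMBOL = {z: s for s, z in _SYMBOL_TO_Z.items()}


def write_input(structure: AtomicStructure, settings: QMSettings) -> str:
    """Gaussian-dialect input deck for a geometry + frequency optimization."""
    if settings.functional not in SUPPORTED_FUNCTIONALS:
        raise ValueError(
            f"unsupported functional {settings.functional!r}; "
            f"supported: {', '.join(SUPPORTED_FUNCTIONALS)}"
        )
    structure.validate()
    route = f"# opt freq {settings.functional}/{settings.basis}"
    if settings.solvation:
        route += f" scrf=({settings.solvation.lower()},solvent={settings.solvent})"
    title = structure.label or "cluster"
    lines = [route, "", title, "", f"{structure.charge} {structure.multiplicity}"]
    for el, (x, y, z) in zip(structure.elements, structure.coordinates):
        lines.append(f" {el:<2s} {x:14.8f} {y:14.8f} {z:14.8f}")
    lines.append("")
    return "\n".join(lines) + "\n"


def write_log(result: QMResult, settings: QMSettings | None = None) -> str:
    """Emit a synthetic Gaussian-style log for ``result``.

    The layout mirrors the blocks :func:`parse_log` reads (orientation
    table, frequency rows, thermochemistry line, elapsed time, termination
    banner) so write→parse round-trips exactly at the printed precision.
    """
    s = result.structure
    out: list[str] = []
    if settings is not None:
        out.append(f" # opt freq {settings.functional}/{settings.basis}")
    out.append(f" Charge =  {s.charge} Multiplicity = {s.multiplicity}")
    out += [
        "                         Standard orientation:",
        " " + "-" * 69,
        " Center     Atomic      Atomic             Coordinates (Angstroms)",
        " Number     Number       Type             X           Y           Z",
        " " + "-" * 69,
    ]
    for i, (el, (x, y, z)) in enumerate(zip(s.elements, s.coordinates), start=1):
        z_num = _SYMBOL_TO_Z[el]
        out.append(f"{i:7d}{z_num:11d}{0:12d}    {x:11.6f} {y:11.6f} {z:11.6f}")
    out.append(" " + "-" * 69)
    if result.frequencies is not None:
        freqs = list(result.frequencies)
        for k in range(0, len(freqs), 3):
            chunk = freqs[k : k + 3]
            out.append(" Frequencies --  " + "".join(f"{f:12.4f}" for f in chunk))
    out.append(
        " Sum of electronic and thermal Free Energies="
        f"  {result.gibbs_free_energy:17.6f}"
    )
    minutes = int(result.wall_time)
    seconds = (result.wall_time - minutes) * 60.0
    out.append(
        f" Elapsed time:       0 days  0 hours {minutes:2d} minutes {seconds:4.1f} seconds."
    )
    if result.converged:
        out.append(" Normal termination of Gaussian 16 at Tue Mar 12 00:00:00 2024.")
    return "\n".join(out) + "\n"


_FREE_ENERGY_RE = re.compile(
    r"Sum of electronic and thermal Free Energies=\s*(-?\d+\.\d+)"
)
_FREQ_RE = re.compile(r"Frequencies\s*--\s*(.*)")
_CHARGE_RE = re.compile(r"Charge\s*=\s*(-?\d+)\s+Multiplicity\s*=\s*(\d+)")
_ELAPSED_RE = re.compile(
    r"Elapsed time:\s*(\d+)\s*days\s*(\d+)\s*hours\s*(\d+)\s*minutes\s*([\d.]+)\s*seconds"
)
_ORIENT_RE = re.compile(r"(Standard|Input) orientation:")


def _parse_orientation(lines: list[str], start: int) -> tuple[list[str], list[list[float]]]:
    elements: list[str] = []
    coords: list[list[float]] = []
    i = start
    dashes = 0
    while i < len(lines):
        line = lines[i]
        if set(line.strip()) == {"-"} and line.strip():
            dashes += 1
            if dashes == 2 and elements:
                break
            i += 1
            continue
        parts = line.split()
        if len(parts) >= 6 and parts[0].isdigit():
            z = int(parts[1])
            elements.append(_Z_TO_SYMBOL.get(z, f"Z{z}"))
            coords.append([float(parts[-3]), float(parts[-2]), float(parts[-1])])
        i += 1
    return elements, coords


def parse_log(text: str) -> QMResult:
    """Parse a Gaussian-dialect log into a :class:`QMResult`.

    The *last* thermochemistry line and the *last* orientation block win
    (multi-step logs re-print both after the final optimization step).

    Raises
    ------
    ValueError
        If no thermochemistry section is present.
    """
    # normalize line endings and trailing whitespace
    lines = [ln.rstrip() for ln in text.replace("\r\n", "\n").replace("\r", "\n").split("\n")]
    body = "\n".join(lines)

    energies = _FREE_ENERGY_RE.findall(body)
    if not energies:
        raise ValueError("no thermochemistry section ('Sum of electronic and thermal Free Energies')")
    gibbs = float(energies[-1])

    charge, multiplicity = 0, 1
    m = _CHARGE_RE.search(body)
    if m:
        charge, multiplicity = int(m.group(1)), int(m.group(2))

    last_orient = None
    for i, ln in enumerate(lines):
        if _ORIENT_RE.search(ln):
            last_orient = i
    elements: list[str] = []
    coords: list[list[float]] = []
    if last_orient is not None:
        elements, coords = _parse_orientation(lines, last_orient + 1)

    freqs: list[float] = []
    for m in _FREQ_RE.finditer(body):
        freqs.extend(float(tok) for tok in m.group(1).split())

    wall_time = 0.0
    m = _ELAPSED_RE.search(body)
    if m:
        days, hours, minutes, seconds = m.groups()
        wall_time = (
            float(days) * 1440.0 + float(hours) * 60.0 + float(minutes) + float(seconds) / 60.0
        )

    converged = "Normal termination" in body
    structure = AtomicStructure(
        elements=tuple(elements),
        coordinates=np.array(coords).reshape(len(elements), 3),
        charge=charge,
        multiplicity=multiplicity,
    )
    return QMResult(
        structure=structure,
        gibbs_free_energy=gibbs,
        frequencies=tuple(freqs) if freqs else None,
        converged=converged,
        wall_time=wall_time,
    )
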