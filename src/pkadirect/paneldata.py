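"""Reference benchmark matrices for the built-in compound panel.

``CALCULATED_PKA`` holds, per functional, the calculated pKa of each
panel compound from the benchmark study this package reproduces; it
drives the deterministic mock engine (whose species energies are
back-derived from these values) and regression-tests the reporting
layer.  Two cells are ``None``: their printed source values are corrupt
(not parseable as a single decimal) and are treated as unavailable
rather than guessed.

``PAIR_AVERAGE_DIHEDRALS`` holds the benchmark's average carboxyl–ring
twist (degrees) of each acid/conjugate-base pair, per functional; large
values mark the ortho-hindered compounds.
"""

from __future__ import annotations

FUNCTIONALS = ("CAM-B3LYP", "B3PW91", "PBE1PBE", "PBEPBE", "TPSSTPSS", "WB97XD")

#: Benchmark column order of the compound panel.
COMPOUND_ORDER = (
    "Benzoic Acid",
    "4-Cyanobenzoic Acid",
    "2,6-Dimethylbenzoic Acid",
    "4-Bromobenzoic Acid",
    "2-Bromobenzoic Acid",
    "2-Chlorobenzoic Acid",
    "3-Chlorobenzoic Acid",
    "4-Chlorobenzoic Acid",
    "2-Methoxybenzoic Acid",
    "3-Methoxybenzoic Acid",
    "4-Methoxybenzoic Acid",
)

_ROWS: dict[str, tuple] = {
    # compound:               CAM-B3LYP B3PW91 PBE1PBE PBEPBE TPSSTPSS WB97XD
    "Benzoic Acid":             (4.35, 3.83, 3.54, 6.07, 5.22, 2.94),
    "4-Cyanobenzoic Acid":      (3.32, 2.96, 2.68, 4.93, 4.22, 1.92),
    "2,6-Dimethylbenzoic Acid": (3.89, 3.39, 3.57, None, 4.81, 2.04),
    "4-Bromobenzoic Acid":      (4.00, 3.27, 3.65, 5.94, 4.77, 2.74),
    "2-Bromobenzoic Acid":      (3.02, 3.86, 2.33, 4.87, 4.18, 1.62),
    "2-Chlorobenzoic Acid":     (3.24, 2.36, 2.36, 3.96, 3.23, 0.78),
    "3-Chlorobenzoic Acid":     (3.91, 3.62, 3.67, 5.91, 5.03, 2.59),
    "4-Chlorobenzoic Acid":     (3.98, 3.77, 3.91, 6.20, 5.30, 2.70),
    "2-Methoxybenzoic Acid":    (4.46, 4.20, 4.28, 6.17, 5.93, 2.83),
    "3-Methoxybenzoic Acid":    (4.54, 3.99, 4.00, 6.21, 5.37, 2.93),
    "4-Methoxybenzoic Acid":    (4.74, 4.76, 4.74, 7.02, None, 3.62),
}

#: functional -> compound -> calculated pKa (None where unavailable).
CALCULATED_PKA: dict[str, dict[str, float | None]] = {
    functional: {name: _ROWS[name][k] for name in COMPOUND_ORDER}
    for k, functional in enumerate(FUNCTIONALS)
}

_DIHEDRAL_ROWS: dict[str, tuple] = {
    "Benzoic Acid":             (0.32, 0.52, 0.36, 0.44, 0.39, 0.72),
    "4-Cyanobenzoic Acid":      (0.67, 0.52, 0.83, 1.12, 0.90, 0.99),
    "2,6-Dimethylbenzoic Acid": (67.03, 68.90, 66.86, 69.07, 63.76, 69.80),
    "4-Bromobenzoic Acid":      (0.41, 0.56, 0.95, 0.70, 1.15, 0.67),
    "2-Bromobenzoic Acid":      (68.30, 69.38, 67.55, 69.80, 67.36, 70.81),
    "2-Chlorobenzoic Acid":     (68.97, 67.085, 66.09, 66.215, 63.82, 70.30),
    "3-Chlorobenzoic Acid":     (0.49, 0.42, 0.31, 0.36, 0.28, 0.50),
    "4-Chlorobenzoic Acid":     (0.47, 0.63, 0.57, 0.73, 0.70, 0.65),
    "2-Methoxybenzoic Acid":    (35.76, 37.56, 33.64, 36.30, 31.91, 43.16),
    "3-Methoxybenzoic Acid":    (0.29, 0.02, 0.23, 0.20, 0.06, 0.48),
    "4-Methoxybenzoic Acid":    (0.28, 0.30, 0.23, 0.40, 0.20, 0.78),
}

#: functional -> compound -> average acid/base carboxyl-ring twist (deg).
PAIR_AVERAGE_DIHEDRALS: dict[str, dict[str, float]] = {
    functional: {name: _DIHEDRAL_ROWS[name][k] for name in COMPOUND_ORDER}
    for k, functional in enumerate(FUNCTIONALS)
}
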