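"""Benchmark statistics and report rendering.

The evaluation layer of the pipeline: per-compound signed errors
(ΔpKa = calc − ref), the mean absolute error per functional, ordinary
least squares of calculated on reference pKa (slope, intercept,
Pearson r and the coefficient of determination r²), per-functional
computational-cost accounting, and calc-vs-ref tables in CSV, markdown
or JSON.  Statistics are computed at full precision and rounded only
when rendered (two decimals, the conventional pKa reporting grain).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BenchmarkTable",
    "DeltaPkaResult",
    "RegressionSummary",
    "cost_summary",
    "delta_pka",
    "mae",
    "read_benchmark_json",
    "regression",
    "render_benchmark",
]


def _as_columns(calc: Sequence[float], ref: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    calc_a = np.asarray(list(calc), dtype=float)
    ref_a = np.asarray(list(ref), dtype=float)
    if calc_a.shape != ref_a.shape or calc_a.ndim != 1:
        raise ValueError(f"column length mismatch: {calc_a.shape} vs {ref_a.shape}")
    return calc_a, ref_a


def mae(calc: Sequence[float], ref: Sequence[float]) -> float:
    """Mean absolute error between calculated and reference pKa columns."""
    calc_a, ref_a = _as_columns(calc, ref)
    if calc_a.size < 1:
        raise ValueError("mae needs at least one compound")
    return float(np.mean(np.abs(calc_a - ref_a)))


@dataclass(frozen=True)
class DeltaPkaResult:
    """Signed per-compound errors and the worst-predicted compound."""

    deltas: pd.Series  # index: compound names (or integers), values: calc - ref
    argmax_abs: object  # index label of the largest |Δ|


def delta_pka(
    calc: Sequence[float],
    ref: Sequence[float],
    compounds: Optional[Sequence[str]] = None,
) -> DeltaPkaResult:
    """Elementwise calc − ref, with the location of the largest |Δ|."""
    calc_a, ref_a = _as_columns(calc, ref)
    index = list(compounds) if compounds is not None else list(range(calc_a.size))
    if len(index) != calc_a.size:
        raise ValueError("compounds length does not match the columns")
    deltas = pd.Series(calc_a - ref_a, index=index, name="delta_pka")
    return DeltaPkaResult(deltas=deltas, argmax_abs=deltas.abs().idxmax())


@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    pearson_r: float
    cod: float  # r**2


def regression(
    calc: Sequence[float],
    ref: Sequence[float],
    *,
    response: str = "calc",
) -> RegressionSummary:
    """OLS fit of the calc-vs-ref correlation.

    By default calculated pKa is the response and the reference the
    predictor; ``response="ref"`` swaps the orientation for exploratory
    comparisons.  The coefficient of determination equals the squared
    Pearson correlation (simple linear regression).
    """
    calc_a, ref_a = _as_columns(calc, ref)
    if calc_a.size < 3:
        raise ValueError("regression needs at least three points")
    x, y = (ref_a, calc_a) if response == "calc" else (calc_a, ref_a)
    if np.std(x) < 1e-15:
        raise ValueError("degenerate predictor column: zero variance")
    fit = stats.linregress(x, y)
    return RegressionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        cod=float(fit.rvalue) ** 2,
    )


def cost_summary(
    times: Mapping[str, Mapping[str, float]],
    pairing: Mapping[str, str],
) -> dict[str, float]:
    """Average computational cost per acid/base conjugated pair, in minutes.

    ``times`` maps functional → species label → wall time; ``pairing``
    maps each acid species label to its conjugate-base label.  The cost of
    one pair is the *sum* of its two wall times; the per-functional figure
    is the mean over pairs.
    """
    if not times or not pairing:
        raise ValueError("cost_summary needs at least one functional and one acid/base pair")
    out: dict[str, float] = {}
    for functional, per_species in times.items():
        pair_costs = []
        for acid_label, base_label in pairing.items():
            if acid_label not in per_species or base_label not in per_species:
                missing = acid_label if acid_label not in per_species else base_label
                raise ValueError(f"unpaired species {missing!r} under functional {functional!r}")
            pair_costs.append(per_species[acid_label] + per_species[base_label])
        out[functional] = float(np.mean(pair_costs))
    return out


@dataclass(frozen=True)
class BenchmarkTable:
    """Calc-vs-ref pKa matrix with derived statistics.

    ``columns`` may contain ``None`` cells for species that failed or
    were unavailable; the MAE row is always recomputed from the stored
    columns over the cells present (never copied in from elsewhere).
    """

    compounds: tuple[str, ...]
    reference: tuple[float, ...]
    columns: Mapping[str, tuple]  # functional -> per-compound pKa (None = missing)
    regression: Mapping[str, RegressionSummary] = field(default_factory=dict)
    cost: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "compounds", tuple(self.compounds))
        object.__setattr__(self, "reference", tuple(float(v) for v in self.reference))
        cols = {
            f: tuple(None if v is None else float(v) for v in col)
            for f, col in self.columns.items()
        }
        object.__setattr__(self, "columns", cols)
        object.__setattr__(self, "regression", dict(self.regression))
        object.__setattr__(self, "cost", dict(self.cost))
        if len(self.reference) != len(self.compounds):
            raise ValueError("reference column length does not match compounds")
        for f, col in cols.items():
            if len(col) != len(self.compounds):
                raise ValueError(f"column {f!r} length does not match compounds")

    @property
    def mae_row(self) -> dict[str, float]:
        """Per-functional MAE recomputed from the stored columns."""
        out: dict[str, float] = {}
        for functional, col in self.columns.items():
            pairs = [(c, r) for c, r in zip(col, self.reference) if c is not None]
            out[functional] = (
                mae([c for c, _ in pairs], [r for _, r in pairs]) if pairs else None
            )
        return out

    @property
    def functionals(self) -> tuple[str, ...]:
        return tuple(self.columns)

    def to_frame(self) -> pd.DataFrame:
        data = {"pKa_ref": self.reference}
        for f in self.functionals:
            data[f] = [np.nan if v is None else v for v in self.columns[f]]
        return pd.DataFrame(data, index=pd.Index(self.compounds, name="COMPOUND"))


_MISSING = "NA"


def _fmt(v) -> str:
    return _MISSING if v is None else f"{v:.2f}"


def render_benchmark(table: BenchmarkTable, format: str = "markdown") -> str:
    """Render the benchmark table; MAE row last, pKa at two decimals.

    ``json`` output round-trips losslessly through
    :func:`read_benchmark_json`; ``csv`` and ``markdown`` are for reading.
    """
    functionals = table.functionals
    mae_row = table.mae_row
    if format == "json":
        payload = {
            "compounds": list(table.compounds),
            "reference": list(table.reference),
            "columns": {f: list(table.columns[f]) for f in functionals},
            "mae_row": {f: mae_row[f] for f in functionals},
            "regression": {
                f: {"slope": r.slope, "intercept": r.intercept,
                    "pearson_r": r.pearson_r, "cod": r.cod}
                for f, r in table.regression.items()
            },
            "cost": dict(table.cost),
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"
    header = ["COMPOUND", "pKa_ref", *functionals]
    rows = []
    for i, name in enumerate(table.compounds):
        rows.append([name, _fmt(table.reference[i]), *(_fmt(table.columns[f][i]) for f in functionals)])
    rows.append(["MAE", "", *(_fmt(mae_row[f]) for f in functionals)])
    if format == "csv":
        buf = io.StringIO()
        print(",".join(header), file=buf)
        for row in rows:
            print(",".join(f'"{c}"' if "," in c else c for c in row), file=buf)
        return buf.getvalue()
    if format == "markdown":
        lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
        for row in rows:
            lines.append("| " + " | ".join(row) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}; use csv, markdown or json")


def read_benchmark_json(text: str) -> BenchmarkTable:
    """Inverse of :func:`render_benchmark` with ``format="json"``."""
    payload = json.loads(text)
    regression_ = {
        f: RegressionSummary(**r) for f, r in payload.get("regression", {}).items()
    }
    return BenchmarkTable(
        compounds=tuple(payload["compounds"]),
        reference=tuple(payload["reference"]),
        columns={f: tuple(col) for f, col in payload["columns"].items()},
        regression=regression_,
        cost=payload.get("cost", {}),
    )


def read_pka_matrix_csv(text: str) -> dict[str, dict[str, float]]:
    """Read a long-format pKa matrix CSV: columns compound, functional, pka."""
    frame = pd.read_csv(io.StringIO(text))
    for col in ("compound", "functional", "pka"):
        if col not in frame.columns:
            raise ValueError(f"pKa matrix CSV is missing required column {col!r}")
    bad = frame[~np.isfinite(pd.to_numeric(frame["pka"], errors="coerce"))]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad.index)
        raise ValueError(f"unparsable pka cells at CSV rows {rows}")
    out: dict[str, dict[str, float]] = {}
    for _, row in frame.iterrows():
        out.setdefault(row["functional"], {})[row["compound"]] = float(row["pka"])
    return out


def read_timings_csv(text: str) -> dict[str, dict[str, float]]:
    """Read a timing table CSV: columns species, functional, minutes."""
    frame = pd.read_csv(io.StringIO(text))
    for col in ("species", "functional", "minutes"):
        if col not in frame.columns:
            raise ValueError(f"timing CSV is missing required column {col!r}")
    out: dict[str, dict[str, float]] = {}
    for _, row in frame.iterrows():
        out.setdefault(row["functional"], {})[row["species"]] = float(row["minutes"])
    return out
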