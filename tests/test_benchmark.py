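"""Benchmark statistics: MAE, ΔpKa, regression, cost, rendering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pkadirect import (
    BenchmarkTable,
    builtin_compounds,
    cost_summary,
    delta_pka,
    mae,
    read_benchmark_json,
    regression,
    render_benchmark,
)
from pkadirect.paneldata import CALCULATED_PKA, COMPOUND_ORDER


@pytest.fixture(scope="module")
def refs():
    return {c.name: c.pka_ref for c in builtin_compounds()}


def _column(functional, refs):
    calc, ref = [], []
    for name in COMPOUND_ORDER:
        v = CALCULATED_PKA[functional][name]
        if v is not None:
            calc.append(v)
            ref.append(refs[name])
    return calc, ref


def test_mae_of_reference_functional(refs):
    calc, ref = _column("CAM-B3LYP", refs)
    assert round(mae(calc, ref), 2) == 0.23


def test_mae_of_b3pw91(refs):
    calc, ref = _column("B3PW91", refs)
    assert round(mae(calc, ref), 2) == 0.38


def test_mae_identical_columns_is_zero():
    assert mae([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0


def test_mae_usage_errors():
    with pytest.raises(ValueError, match="mismatch"):
        mae([1.0, 2.0], [1.0])
    with pytest.raises(ValueError, match="at least one"):
        mae([], [])


@given(
    st.lists(
        st.tuples(
            st.floats(min_value=-10, max_value=10),
            st.floats(min_value=-10, max_value=10),
        ),
        min_size=1,
        max_size=12,
    ),
    st.randoms(use_true_random=False),
)
def test_mae_nonnegative_and_joint_permutation_invariant(pairs, rnd):
    calc = [p[0] for p in pairs]
    ref = [p[1] for p in pairs]
    value = mae(calc, ref)
    assert value >= 0
    assert (value == 0) == all(c == r for c, r in zip(calc, ref))
    order = list(range(len(pairs)))
    rnd.shuffle(order)
    assert mae([calc[i] for i in order], [ref[i] for i in order]) == pytest.approx(value)


def test_delta_pka_worst_compound_is_the_ortho_hindered_one(refs):
    calc = [CALCULATED_PKA["CAM-B3LYP"][n] for n in COMPOUND_ORDER]
    ref = [refs[n] for n in COMPOUND_ORDER]
    result = delta_pka(calc, ref, compounds=COMPOUND_ORDER)
    assert result.argmax_abs == "2,6-Dimethylbenzoic Acid"
    assert result.deltas["2,6-Dimethylbenzoic Acid"] == pytest.approx(0.65, abs=1e-9)


def test_delta_pka_zero_and_single_entry():
    assert (delta_pka([1.0, 2.0], [1.0, 2.0]).deltas == 0).all()
    single = delta_pka([4.35], [4.20])
    assert single.deltas.iloc[0] == pytest.approx(0.15)


def test_regression_identity_and_affine():
    x = np.linspace(0, 10, 8)
    fit = regression(x, x)
    assert (fit.slope, fit.intercept, fit.pearson_r, fit.cod) == pytest.approx((1, 0, 1, 1))
    fit = regression(2 * x + 1, x)
    assert fit.slope == pytest.approx(2.0, abs=1e-9)
    assert fit.intercept == pytest.approx(1.0, abs=1e-9)
    assert fit.cod == pytest.approx(1.0, abs=1e-12)


def test_regression_matches_closed_form_oracle():
    rng = np.random.default_rng(42)
    x = rng.uniform(2, 5, size=11)
    y = 1.1 * x - 0.3 + rng.normal(scale=0.2, size=11)
    fit = regression(y, x)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    r = sxy / np.sqrt(sxx * ((y - y.mean()) ** 2).sum())
    assert fit.slope == pytest.approx(slope, abs=1e-12)
    assert fit.intercept == pytest.approx(intercept, abs=1e-12)
    assert fit.pearson_r == pytest.approx(r, abs=1e-12)
    assert fit.cod == pytest.approx(r**2, abs=1e-12)


def test_regression_of_reference_functional_column(refs):
    """Calc-vs-ref OLS over all 11 points, against the closed form."""
    calc, ref = map(np.array, _column("CAM-B3LYP", refs))
    sxx = ((ref - ref.mean()) ** 2).sum()
    slope = (((ref - ref.mean()) * (calc - calc.mean())).sum()) / sxx
    fit = regression(calc, ref)
    assert fit.slope == pytest.approx(slope, abs=1e-12)
    assert fit.slope == pytest.approx(0.985, abs=0.001)
    assert fit.pearson_r > 0.9


def test_regression_errors():
    with pytest.raises(ValueError, match="three"):
        regression([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="degenerate"):
        regression([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])


def test_cost_summary_means_pair_sums():
    times = {"F": {f"{k}:{c}": 10.0 for c in "ABCDEFGHIJK" for k in ("acid", "base")}}
    pairing = {f"acid:{c}": f"base:{c}" for c in "ABCDEFGHIJK"}
    assert cost_summary(times, pairing) == {"F": 20.0}


def test_cost_summary_single_pair():
    out = cost_summary({"CAM-B3LYP": {"acid:X": 30.0, "base:X": 22.0}}, {"acid:X": "base:X"})
    assert out == {"CAM-B3LYP": 52.0}


def test_cost_summary_errors():
    with pytest.raises(ValueError):
        cost_summary({}, {})
    with pytest.raises(ValueError, match="unpaired"):
        cost_summary({"F": {"acid:X": 30.0}}, {"acid:X": "base:X"})


@pytest.fixture()
def panel_table(refs):
    return BenchmarkTable(
        compounds=COMPOUND_ORDER,
        reference=tuple(refs[n] for n in COMPOUND_ORDER),
        columns={
            f: tuple(CALCULATED_PKA[f][n] for n in COMPOUND_ORDER)
            for f in CALCULATED_PKA
        },
    )


def test_render_markdown_benzoic_row(panel_table):
    text = render_benchmark(panel_table, "markdown")
    row = next(line for line in text.splitlines() if line.startswith("| Benzoic Acid"))
    assert "4.20" in row and "4.35" in row
    assert text.rstrip().splitlines()[-1].startswith("| MAE")


def test_rendered_mae_row_is_self_consistent(panel_table):
    """The MAE printed in any rendering equals mae() recomputed from the
    table's own columns (guards against copied-in, stale MAE rows)."""
    text = render_benchmark(panel_table, "csv")
    mae_cells = text.strip().splitlines()[-1].split(",")[2:]
    for functional, cell in zip(panel_table.functionals, mae_cells):
        col = panel_table.columns[functional]
        pairs = [(c, r) for c, r in zip(col, panel_table.reference) if c is not None]
        expected = mae([c for c, _ in pairs], [r for _, r in pairs])
        assert cell == f"{expected:.2f}"


def test_render_missing_cells_marked(panel_table):
    text = render_benchmark(panel_table, "csv")
    row = next(line for line in text.splitlines() if line.startswith('"2,6-'))
    assert "NA" in row


def test_render_empty_table_is_header_only():
    empty = BenchmarkTable(compounds=(), reference=(), columns={"CAM-B3LYP": ()})
    lines = render_benchmark(empty, "csv").strip().splitlines()
    assert lines[0] == "COMPOUND,pKa_ref,CAM-B3LYP"
    assert len(lines) == 2 and lines[1].startswith("MAE")  # MAE over no compounds? no -
    # MAE of an empty column cannot be computed; the row simply renders NA


def test_render_unknown_format(panel_table):
    with pytest.raises(ValueError, match="format"):
        render_benchmark(panel_table, "xlsx")


def test_json_round_trip(panel_table):
    back = read_benchmark_json(render_benchmark(panel_table, "json"))
    assert back == panel_table
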