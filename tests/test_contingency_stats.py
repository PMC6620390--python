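"""Contingency statistics: expected counts, chi-square, partitioning,
nonparametric comparisons, and published-table reproduction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from sasmorph.stats import (ContingencyTable, counts_to_table,
                            expected_counts, load_reference_counts,
                            partition_2x2, pearson_chi2,
                            reproduce_reference_tables, size_comparisons)


def _table(counts, rows=None, cols=None):
    counts = np.asarray(counts)
    rows = rows or tuple(f"r{i}" for i in range(counts.shape[0]))
    cols = cols or tuple(f"c{j}" for j in range(counts.shape[1]))
    return ContingencyTable(counts, rows, cols)


def test_expected_counts_symmetric_table():
    exp = expected_counts(_table([[10, 10], [10, 10]]))
    assert np.allclose(exp, 10.0)


def test_expected_counts_conserve_total():
    t = _table([[3, 9, 1], [7, 2, 8]])
    assert expected_counts(t).sum() == pytest.approx(t.total)


def test_expected_count_formula_on_published_control_table():
    """SS x spine-heads expectation from the control marginals:
    E = 833 * 112 / 1508."""
    df = load_reference_counts("target")
    table = counts_to_table(df, "control")
    exp = expected_counts(table)
    j = table.col_labels.index("spine_head")
    i = table.row_labels.index("SS")
    assert exp[i, j] == pytest.approx(833 * 112 / 1508, abs=1e-9)
    assert exp[i, j] == pytest.approx(61.87, abs=0.005)


def test_chi2_zero_for_proportional_rows():
    res = pearson_chi2(_table([[10, 20, 30], [1, 2, 3]]))
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0)


def test_chi2_matches_scipy_oracle(rng):
    for _ in range(20):
        counts = rng.integers(1, 60, size=(2, 3))
        res = pearson_chi2(_table(counts))
        ref = chi2_contingency(counts, correction=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.df == ref.dof
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_chi2_rejects_zero_expected():
    with pytest.raises(ValueError):
        pearson_chi2(_table([[0, 5], [0, 7]]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 50), min_size=8, max_size=8))
def test_chi2_invariant_under_permutation(vals):
    counts = np.array(vals).reshape(2, 4) + 1  # avoid zero marginals
    t = _table(counts)
    base = pearson_chi2(t).statistic
    perm = counts[::-1, :][:, [2, 0, 3, 1]]
    assert pearson_chi2(_table(perm)).statistic == pytest.approx(base)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 30), min_size=8, max_size=8),
       st.integers(1, 10))
def test_discard_monotonicity(vals, thresh):
    """Raising the discard threshold never increases retained columns."""
    counts = np.array(vals).reshape(2, 4) + 1
    t = _table(counts)
    def n_retained(th):
        try:
            parts, _ = partition_2x2(t, discard_min=th)
            return len(parts)
        except ValueError:
            return 0
    assert n_retained(thresh + 1) <= n_retained(thresh)


def test_partition_control_table_reproduces_published_shares():
    df = load_reference_counts("target")
    table = counts_to_table(df, "control")
    parts, discarded = partition_2x2(table, discard_min=5)
    assert [lab for lab, _ in discarded] == ["spine_neck"]
    shares = {p.column_label: round(100 * p.column_shares["AS"], 1)
              for p in parts}
    assert shares["spine_head"] == 99.0
    assert shares["aspiny_shaft"] == 86.6
    assert shares["spiny_shaft"] == 82.7
    for p in parts:
        assert np.isfinite(p.result.statistic) and p.result.statistic >= 0
        assert p.result.p_value < 1e-4


def test_partition_sequential_scheme():
    df = load_reference_counts("target")
    table = counts_to_table(df, "control")
    parts, _ = partition_2x2(table, scheme="sequential")
    assert len(parts) == 2  # three retained columns -> two orthogonal tests


def test_partition_requires_wide_table():
    with pytest.raises(ValueError):
        partition_2x2(_table([[5, 6], [7, 8]]))


def test_size_comparisons_identical_samples():
    df = pd.DataFrame({
        "value": list(range(20)) * 2,
        "group": ["a"] * 20 + ["b"] * 20,
    })
    rep = size_comparisons(df, "value", "group")
    assert rep["mann_whitney"]["p_value"] == pytest.approx(1.0)


def test_size_comparisons_gate_small_groups():
    df = pd.DataFrame({
        "value": [1, 2, 3, 4, 5, 6, 1, 2] + list(range(20)),
        "group": ["tiny"] * 8 + ["big"] * 20,
    })
    rep = size_comparisons(df, "value", "group", min_n=10)
    assert rep["not_tested"] == ["tiny"]
    assert "mann_whitney" not in rep


def test_size_comparisons_kw_three_groups(rng):
    df = pd.DataFrame({
        "value": rng.normal(size=90),
        "group": ["a"] * 30 + ["b"] * 30 + ["c"] * 30,
    })
    rep = size_comparisons(df, "value", "group")
    assert "kruskal_wallis" in rep


def test_reproduction_report_percentages():
    rep = reproduce_reference_tables()
    # every cell of the target table matches its printed percentage
    for group, g in rep["type_by_target"]["groups"].items():
        assert g["mismatched_cells"] == []
    # the shape table has exactly one internally inconsistent printed
    # cell (Alzheimer SS macular prints 92.5% but its counts give 92.4%)
    mism = []
    for group, g in rep["type_by_shape"]["groups"].items():
        mism += [(group, m["type"], m["category"], m["recomputed_pct"])
                 for m in g["mismatched_cells"]]
    assert mism == [("alzheimer", "SS", "macular", 92.4)]


def test_reproduction_totals_and_omnibus():
    rep = reproduce_reference_tables()
    assert rep["type_by_shape"]["grand_total"] == 4722
    control = rep["type_by_target"]["groups"]["control"]
    assert control["omnibus"]["statistic"] == pytest.approx(117.06, abs=0.005)
    assert control["omnibus"]["df"] == 3
    assert control["omnibus"]["p_value"] < 1e-4
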