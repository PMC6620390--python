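"""Contingency-table statistics for synapse classifications.

The battery mirrors standard practice in quantitative synaptology:

* an omnibus Pearson chi-square on the 2 x k table of synapse type
  against target or shape category, expected counts ``E_ij = Ti*Tj/T``
  from the marginal totals, no continuity correction;
* a partitioning of a significant omnibus test into 2 x 2 tables (each
  retained category against the pooled others) to localise which
  categories drive the association, discarding categories whose minimum
  *observed* count falls below 5;
* nonparametric size comparisons of SAS metrics: Kruskal-Wallis across
  >= 3 groups, Mann-Whitney U between two, Kolmogorov-Smirnov for
  distribution shape — withheld for groups below a minimum n.

The module also re-derives every percentage, omnibus statistic and
partition share of the published human transentorhinal-cortex count
tables from their raw counts (packaged under ``sasmorph/data``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

COLUMN_VS_REST = "column_vs_rest"
SEQUENTIAL = "sequential"

#: default minimum observed count below which a category is discarded
#: from the chi-square partitioning
DEFAULT_DISCARD_MIN = 5


@dataclass
class ContingencyTable:
    """Labeled nonnegative integer count matrix with marginals."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        self.row_labels = tuple(self.row_labels)
        self.col_labels = tuple(self.col_labels)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match the count matrix shape")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ContingencyTable":
        return cls(df.to_numpy(), tuple(map(str, df.index)),
                   tuple(map(str, df.columns)))


@dataclass
class ChiSquareResult:
    """Pearson chi-square outcome with the expected-count matrix."""

    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    discarded_cells: list = field(default_factory=list)


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Independence expectations E_ij = Ti * Tj / T."""
    if table.total == 0:
        raise ValueError("empty table has no expected counts")
    return np.outer(table.row_totals, table.col_totals) / table.total


def pearson_chi2(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square of independence, no continuity correction."""
    exp = expected_counts(table)
    if np.any(exp == 0):
        raise ValueError(
            "expected count of zero; discard or merge the offending "
            "rows/columns before testing")
    stat = float(((table.counts - exp) ** 2 / exp).sum())
    df = (len(table.row_labels) - 1) * (len(table.col_labels) - 1)
    p = float(sps.chi2.sf(stat, df))
    return ChiSquareResult(stat, df, p, exp)


@dataclass
class Partition2x2:
    """One 2 x 2 partition of a 2 x k table: a category vs the rest."""

    column_label: str
    table: ContingencyTable
    result: ChiSquareResult
    column_shares: dict[str, float]  # row label -> share of this category


def partition_2x2(table: ContingencyTable,
                  discard_min: int = DEFAULT_DISCARD_MIN,
                  scheme: str = COLUMN_VS_REST
                  ) -> tuple[list[Partition2x2], list[tuple[str, str]]]:
    """Partition a 2 x k omnibus table into per-category 2 x 2 tests.

    Categories whose minimum observed count is below ``discard_min``
    are discarded (with a reason string) before partitioning.  The
    default scheme tests each retained category against the pooled
    remaining retained categories; ``scheme="sequential"`` instead uses
    orthogonal partitions (category j against the pooled categories
    after it), which yields k-2 tests.
    """
    if len(table.row_labels) != 2 or len(table.col_labels) < 3:
        raise ValueError("partitioning expects a 2 x k table with k >= 3")
    if scheme not in (COLUMN_VS_REST, SEQUENTIAL):
        raise ValueError(f"unknown partition scheme {scheme!r}")
    keep: list[int] = []
    discarded: list[tuple[str, str]] = []
    for j, lab in enumerate(table.col_labels):
        mn = int(table.counts[:, j].min())
        if mn < discard_min:
            discarded.append(
                (lab, f"observed count {mn} < {discard_min}"))
        else:
            keep.append(j)
    if len(keep) < 2:
        raise ValueError(
            "fewer than two categories retained after the discard rule")
    sub = table.counts[:, keep]
    labels = [table.col_labels[j] for j in keep]
    partitions: list[Partition2x2] = []
    n_tests = len(labels) if scheme == COLUMN_VS_REST else len(labels) - 1
    for jj in range(n_tests):
        col = sub[:, jj]
        if scheme == COLUMN_VS_REST:
            rest = sub.sum(axis=1) - col
            rest_label = "other"
        else:
            rest = sub[:, jj + 1:].sum(axis=1)
            rest_label = "pooled_after"
            if rest.sum() == 0:
                break
        t2 = ContingencyTable(
            np.column_stack([col, rest]),
            table.row_labels, (labels[jj], rest_label))
        res = pearson_chi2(t2)
        shares = {
            row: float(col[i]) / float(col.sum())
            for i, row in enumerate(table.row_labels)
        }
        partitions.append(Partition2x2(labels[jj], t2, res, shares))
    return partitions, discarded


# ---------------------------------------------------------------------------
# nonparametric size comparisons
# ---------------------------------------------------------------------------

def size_comparisons(df: pd.DataFrame, value_col: str, group_col: str,
                     min_n: int = 10) -> dict:
    """KW / MW / KS comparisons of a metric across groups.

    Groups with fewer than ``min_n`` observations are reported as
    ``"not tested"`` rather than raising; ties are handled by the
    default midrank corrections of the underlying scipy tests.
    """
    groups = {g: sub[value_col].to_numpy()
              for g, sub in df.groupby(group_col, observed=True)}
    small = sorted(g for g, v in groups.items() if len(v) < min_n)
    tested = {g: v for g, v in groups.items() if len(v) >= min_n}
    report: dict = {
        "group_sizes": {str(g): int(len(v)) for g, v in groups.items()},
        "not_tested": [str(g) for g in small],
        "min_n": min_n,
    }
    if len(tested) >= 3:
        kw = sps.kruskal(*tested.values())
        report["kruskal_wallis"] = {
            "statistic": float(kw.statistic), "p_value": float(kw.pvalue)}
    if len(tested) == 2:
        a, b = tested.values()
        mw = sps.mannwhitneyu(a, b, alternative="two-sided")
        ks = sps.ks_2samp(a, b)
        report["mann_whitney"] = {
            "statistic": float(mw.statistic), "p_value": float(mw.pvalue)}
        report["kolmogorov_smirnov"] = {
            "statistic": float(ks.statistic), "p_value": float(ks.pvalue)}
    if len(tested) < 2:
        report["note"] = "fewer than two groups large enough to test"
    return report


# ---------------------------------------------------------------------------
# published-table reproduction
# ---------------------------------------------------------------------------

def load_reference_counts(kind: str) -> pd.DataFrame:
    """Packaged control/Alzheimer count tables ('target' or 'shape')."""
    name = {"target": "tec_type_by_target.csv",
            "shape": "tec_type_by_shape.csv"}.get(kind)
    if name is None:
        raise ValueError("kind must be 'target' or 'shape'")
    with resources.files("sasmorph.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh)
    required = {"group", "type", "category", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"count file missing columns {required}")
    return df


def counts_to_table(df: pd.DataFrame, group: str,
                    rows: str = "type",
                    cols: str = "category") -> ContingencyTable:
    """2 x k table of one group from a long-format count file."""
    sub = df[df["group"] == group]
    if sub.empty:
        raise ValueError(f"no rows for group {group!r}")
    pivot = sub.pivot_table(index=rows, columns=cols, values="count",
                            aggfunc="sum", sort=False)
    return ContingencyTable.from_frame(pivot)


def reproduce_reference_tables(
    target_counts: pd.DataFrame | None = None,
    shape_counts: pd.DataFrame | None = None,
    discard_min: int = DEFAULT_DISCARD_MIN,
) -> dict:
    """Recompute every percentage, omnibus chi-square and partition of
    the published count tables from their raw counts.

    Returns a nested report: per table and group, the recomputed
    percentages (one decimal, as printed) with match flags against the
    printed values, the omnibus test, retained partitions with their
    row shares, and the discarded categories; plus grand totals.
    """
    report: dict = {}
    inputs = {
        "type_by_target": (target_counts if target_counts is not None
                           else load_reference_counts("target")),
        "type_by_shape": (shape_counts if shape_counts is not None
                          else load_reference_counts("shape")),
    }
    for name, df in inputs.items():
        entry: dict = {"groups": {}, "grand_total": int(df["count"].sum())}
        for group in df["group"].unique():
            table = counts_to_table(df, group)
            sub = df[df["group"] == group]
            rows = {}
            mismatches = []
            for typ, trow in sub.groupby("type", sort=False):
                total = int(trow["count"].sum())
                cats = {}
                for _, r in trow.iterrows():
                    pct = round(100.0 * r["count"] / total, 1)
                    printed = (float(r["printed_pct"])
                               if "printed_pct" in trow.columns else None)
                    match = (printed is None
                             or abs(pct - printed) < 1e-9)
                    cats[r["category"]] = {
                        "count": int(r["count"]),
                        "recomputed_pct": pct,
                        "printed_pct": printed,
                        "match": bool(match),
                    }
                    if not match:
                        mismatches.append({
                            "type": typ, "category": r["category"],
                            "recomputed_pct": pct, "printed_pct": printed,
                        })
                rows[typ] = {"total": total, "categories": cats}
            omnibus = pearson_chi2(table)
            partitions, discarded = partition_2x2(table, discard_min)
            entry["groups"][group] = {
                "rows": rows,
                "mismatched_cells": mismatches,
                "omnibus": {
                    "statistic": round(omnibus.statistic, 2),
                    "df": omnibus.df,
                    "p_value": omnibus.p_value,
                },
                "partitions": {
                    p.column_label: {
                        "statistic": round(p.result.statistic, 2),
                        "p_value": p.result.p_value,
                        "shares_pct": {
                            row: round(100.0 * s, 1)
                            for row, s in p.column_shares.items()
                        },
                    } for p in partitions
                },
                "discarded": [
                    {"category": lab, "reason": why}
                    for lab, why in discarded
                ],
            }
        report[name] = entry
    report["total_synapses_shape_tables"] = \
        report["type_by_shape"]["grand_total"]
    return report
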