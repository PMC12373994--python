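"""Group-difference statistics reconstructed from printed summary data.

The cohort table of the study reports only group means/SDs and counts, so
the usual tests are recomputed from summary statistics: one-way ANOVA F from
(n, mean, sd) triples, Pearson χ² (no continuity correction) from count
tables, and Welch's unequal-variance t with Welch–Satterthwaite degrees of
freedom (the printed dfs match Welch, not the pooled form).  A transcription
of the printed summaries ships as a packaged fixture; rows whose printed
statistic is not reproducible from the printed summaries are transcribed but
flagged ``check = False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "GroupSummary",
    "welch_t",
    "anova_f",
    "pearson_chi2",
    "load_table1",
    "table1_report",
    "TOLERANCE_ABS",
]

#: |computed - printed| <= max(0.02, 1% of printed) absorbs input rounding
TOLERANCE_ABS = 0.02


@dataclass
class GroupSummary:
    """Printed per-group summary: n, mean, SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ConfigurationError(f"group {self.label}: need n >= 2")
        if self.sd <= 0:
            raise ConfigurationError(f"group {self.label}: SD must be > 0")


def welch_t(a: GroupSummary, b: GroupSummary) -> tuple[float, float]:
    """Welch's t statistic and Welch–Satterthwaite df from summaries."""
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(t), float(df)


def anova_f(groups: list[GroupSummary]) -> tuple[float, int, int]:
    """One-way ANOVA F from group summaries.

    SSB = Σ nᵢ(mᵢ − m̄)², SSW = Σ (nᵢ−1)sᵢ²; F = MSB / MSW with
    df = (k−1, N−k).
    """
    if len(groups) < 2:
        raise ConfigurationError("ANOVA needs >= 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups])
    s = np.array([g.sd for g in groups])
    N, k = n.sum(), len(groups)
    grand = np.sum(n * m) / N
    ssb = np.sum(n * (m - grand) ** 2)
    ssw = np.sum((n - 1) * s**2)
    f = (ssb / (k - 1)) / (ssw / (N - k))
    return float(f), int(k - 1), int(N - k)


def pearson_chi2(table) -> tuple[float, int]:
    """Pearson χ² of independence (no continuity correction) and df."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValidationError("counts must be >= 0")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("zero row/column margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof)


# ---------------------------------------------------------------------------
# packaged transcription of the printed cohort table
# ---------------------------------------------------------------------------

def _fixture(name: str) -> pd.DataFrame:
    with resources.files("cb1pet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_table1() -> dict[str, pd.DataFrame]:
    """The packaged summary transcription: continuous rows, count rows,
    and the printed test statistics."""
    return {
        "continuous": _fixture("table1_continuous.csv"),
        "counts": _fixture("table1_counts.csv"),
        "tests": _fixture("table1_tests.csv"),
    }


def table1_report() -> pd.DataFrame:
    """Recompute every checkable printed statistic from the summaries.

    Returns one row per test with the computed and printed values, the
    absolute difference, and whether it falls within the rounding tolerance
    max(0.02, 1% of printed).  Rows flagged ``check = False`` in the fixture
    are reported but not judged.
    """
    tables = load_table1()
    cont, counts, tests = tables["continuous"], tables["counts"], tables["tests"]
    rows = []
    for _, trow in tests.iterrows():
        var, test = trow["variable"], trow["test"]
        if test == "anova":
            gs = [
                GroupSummary(r["group"], int(r["n"]), r["mean"], r["sd"])
                for _, r in cont[cont["variable"] == var].iterrows()
            ]
            value, df1, df2 = anova_f(gs)
            df_str = f"({df1},{df2})"
        elif test == "welch_t":
            sub = cont[cont["variable"] == var]
            gs = [
                GroupSummary(r["group"], int(r["n"]), r["mean"], r["sd"])
                for _, r in sub.iterrows()
            ]
            value, df = welch_t(gs[0], gs[1])
            value = abs(value)
            df_str = f"({df:.1f})"
        elif test == "chi2":
            sub = counts[counts["variable"] == var]
            tab = np.column_stack([sub["count"], sub["n"] - sub["count"]])
            value, df = pearson_chi2(tab)
            df_str = f"({df})"
        else:
            raise ConfigurationError(f"unknown test kind: {test}")
        printed = float(trow["printed_stat"])
        tol = max(TOLERANCE_ABS, 0.01 * abs(printed))
        rows.append(
            {
                "variable": var,
                "test": test,
                "computed": value,
                "printed": printed,
                "df": df_str,
                "abs_diff": abs(value - printed),
                "check": bool(trow["check"]),
                "within_tolerance": abs(value - printed) <= tol,
            }
        )
    return pd.DataFrame(rows)
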