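"""Arithmetic of grouped clinical outcome tables.

Utilities for the count/summary tables reported alongside uterine-artery
Doppler studies of pregnancy-induced hypertension (PIH): treatment
effective rates, adverse-outcome proportions, Pearson chi-square on 2x2
counts and two-sample t statistics recomputed from group summaries
(mean +/- SD, n).  Three example tables from a magnesium sulfate +
labetalol PIH trial (two arms of n = 250) ship as CSV fixtures.

Percentages are rounded to one decimal, matching the display convention of
such tables.  The bundled delivery-outcome table illustrates a real
reporting quirk: the per-category counts of one arm sum to more than the
printed "total" column, so the printed total is stored verbatim and never
recomputed from the components.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

__all__ = [
    "GroupOutcomeTable",
    "SummaryStat",
    "load_table",
    "load_efficacy_table",
    "load_delivery_table",
    "load_uterine_indices",
    "effective_rate",
    "proportion",
    "chi2_2x2",
    "t_from_summary",
]


@dataclass(frozen=True)
class GroupOutcomeTable:
    """Per-group category counts from a clinical table.

    ``counts`` is indexed by group with one column per category.  For
    exhaustive categorisations the rows must sum to the group sizes; event
    tables instead carry a separately printed total in ``printed_totals``
    which is stored verbatim and not asserted against the component sum.
    """

    counts: pd.DataFrame
    group_sizes: dict[str, int]
    printed_totals: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise DomainError("counts must be non-negative")
        for g in self.counts.index:
            if g not in self.group_sizes:
                raise DomainError(f"missing group size for {g!r}")
        if self.printed_totals is None:
            for g in self.counts.index:
                if int(self.counts.loc[g].sum()) != self.group_sizes[g]:
                    raise DomainError(
                        f"categories of group {g!r} do not sum to its size; "
                        "pass printed_totals for non-exhaustive event tables"
                    )

    @property
    def groups(self) -> list[str]:
        return list(self.counts.index)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    def count(self, group: str, category: str) -> int:
        if group not in self.counts.index or category not in self.counts.columns:
            raise DomainError(f"unknown group/category {group!r}/{category!r}")
        return int(self.counts.loc[group, category])


@dataclass(frozen=True)
class SummaryStat:
    """Group summary: mean +/- sd with sample size n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise DomainError("sd must be positive")
        if self.n < 2:
            raise DomainError("n must be >= 2")


def _data_path(name: str):
    return resources.files("ewtdoppler.data").joinpath(name)


def load_table(source, total_category: str | None = None) -> GroupOutcomeTable:
    """Build a :class:`GroupOutcomeTable` from long-format CSV.

    Expected columns: ``group, category, count, group_size``.  Rows whose
    category equals ``total_category`` are stored as the printed totals
    rather than as a component category.
    """
    df = pd.read_csv(source)
    required = {"group", "category", "count", "group_size"}
    if not required.issubset(df.columns):
        raise DomainError(f"table needs columns {sorted(required)}")
    printed = None
    if total_category is not None:
        mask = df["category"] == total_category
        printed = dict(zip(df.loc[mask, "group"], df.loc[mask, "count"].astype(int)))
        df = df[~mask]
    counts = df.pivot(index="group", columns="category", values="count").astype(int)
    sizes = dict(
        df.drop_duplicates("group").set_index("group")["group_size"].astype(int)
    )
    return GroupOutcomeTable(counts, sizes, printed)


def load_efficacy_table() -> GroupOutcomeTable:
    """Bundled treatment-efficacy counts (exhaustive four-way grading)."""
    with resources.as_file(_data_path("pih_efficacy.csv")) as p:
        return load_table(p)


def load_delivery_table() -> GroupOutcomeTable:
    """Bundled adverse delivery-outcome counts with printed totals."""
    with resources.as_file(_data_path("pih_delivery_outcomes.csv")) as p:
        return load_table(p, total_category="reported_total")


def load_uterine_indices() -> pd.DataFrame:
    """Bundled uterine-artery index summaries (group, index, mean, sd, n)."""
    with resources.as_file(_data_path("pih_uterine_artery_indices.csv")) as p:
        return pd.read_csv(p)


def proportion(count: int, n: int) -> float:
    """Percentage 100*count/n rounded to one decimal."""
    if n <= 0:
        raise DomainError("n must be positive")
    if not 0 <= count <= n:
        raise DomainError("count must lie in [0, n]")
    return round(100.0 * count / n, 1)


def effective_rate(
    table: GroupOutcomeTable,
    group: str,
    ineffective_category: str = "ineffective",
) -> float:
    """Percentage of a group outside the ineffective category."""
    bad = table.count(group, ineffective_category)
    n = table.group_sizes[group]
    return proportion(n - bad, n)


def chi2_2x2(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]].

    Returns ``(statistic, p_value)`` with 1 degree of freedom; ``yates``
    applies the continuity correction.  Symmetric under transposition and
    row/column swaps.
    """
    if min(a, b, c, d) < 0:
        raise DomainError("counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise DomainError("chi-square undefined with a zero margin")
    dev = abs(a * d - b * c)
    if yates:
        dev = max(0.0, dev - n / 2.0)
    stat = n * dev**2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def t_from_summary(
    g1: SummaryStat, g2: SummaryStat, pooled: bool = False
) -> tuple[float, float]:
    """Two-sample t statistic from group summaries.

    Default is the Welch statistic ``(m1-m2)/sqrt(s1^2/n1 + s2^2/n2)`` with
    Welch-Satterthwaite degrees of freedom; ``pooled=True`` uses the
    equal-variance pooled form.  Returns ``(t, df)``.
    """
    v1 = g1.sd**2 / g1.n
    v2 = g2.sd**2 / g2.n
    if pooled:
        sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / (g1.n + g2.n - 2)
        t = (g1.mean - g2.mean) / np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
        df = g1.n + g2.n - 2
    else:
        t = (g1.mean - g2.mean) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return float(t), float(df)
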