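"""Summary-statistic trial analysis: agitation incidence, chi-square, t tests.

Implements the small self-contained computations of a two-arm sedation trial
reported only through summary tables: per-group Riker Sedation-Agitation
Scale (SAS) grade counts, mean +/- sd hemodynamic summaries, and the
associated two-group tests (Pearson chi-square on a 2x2 table, two-sample t
from summary statistics).

Conventions
-----------
* Agitation is SAS grade >= 5 (5 = agitated, 6 = very agitated,
  7 = dangerously agitated).
* Incidence percentages are *truncated* toward zero to whole percents
  (5/30 -> 16, 23/30 -> 76), matching the reporting convention of such
  tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GradingTable",
    "GroupSummary",
    "agitation_incidence",
    "chi_square_2x2",
    "two_sample_t",
    "dex_agitation_table",
]


@dataclass(frozen=True)
class GradingTable:
    """Per-group patient counts over an ordered set of SAS grades."""

    grades: tuple[int, ...]
    counts: Mapping[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "grades", tuple(self.grades))
        object.__setattr__(
            self, "counts", {g: tuple(c) for g, c in self.counts.items()}
        )
        if any(b <= a for a, b in zip(self.grades, self.grades[1:])):
            raise ValueError("grades must be strictly increasing")
        for g, c in self.counts.items():
            if len(c) != len(self.grades):
                raise ValueError(f"group {g!r}: {len(c)} counts for {len(self.grades)} grades")
            if any(x < 0 for x in c):
                raise ValueError(f"group {g!r}: counts must be non-negative")

    def group_size(self, group: str) -> int:
        return sum(self._group(group))

    def _group(self, group: str) -> tuple[int, ...]:
        if group not in self.counts:
            raise KeyError(f"unknown group {group!r}; have {sorted(self.counts)}")
        return self.counts[group]

    def count_at_or_above(self, group: str, threshold_grade: int) -> int:
        if threshold_grade not in self.grades:
            raise ValueError(f"threshold grade {threshold_grade} not among {self.grades}")
        c = self._group(group)
        return sum(x for g, x in zip(self.grades, c) if g >= threshold_grade)


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- sd summary of one group (x +/- s reporting)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")


def dex_agitation_table() -> GradingTable:
    """Bundled SAS grading table of a dexmedetomidine-vs-saline craniotomy trial.

    Thirty patients per arm; group A received dexmedetomidine during
    anesthesia, group B an equal volume of normal saline.
    """
    return GradingTable(
        grades=(3, 4, 5, 6, 7),
        counts={"A": (5, 20, 3, 2, 0), "B": (2, 5, 7, 9, 7)},
    )


def agitation_incidence(table: GradingTable, group: str, threshold_grade: int = 5) -> int:
    """Whole-percent agitation incidence, truncated toward zero.

    100 * (patients with grade >= threshold) / group size, floored to an
    integer percent.
    """
    agitated = table.count_at_or_above(group, threshold_grade)
    return int(100 * agitated // table.group_size(group))


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test on the 2x2 table [[a, b], [c, d]].

    Default is the uncorrected statistic
    N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); ``yates=True`` applies the
    continuity correction.  Returns (statistic, p-value) with p from the
    upper tail of chi-square with 1 degree of freedom.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n < 1:
        raise ValueError("table total must be at least 1")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("a zero marginal makes the chi-square statistic undefined")
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2.0, 0.0)
    stat = n * num * num / float(np.prod(margins, dtype=float))
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def two_sample_t(
    g1: GroupSummary, g2: GroupSummary, variant: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sample t test from summary statistics.

    ``variant='pooled'`` assumes equal variances (df = n1 + n2 - 2);
    ``variant='welch'`` uses the Welch-Satterthwaite degrees of freedom.
    Returns (t, df, two-sided p).
    """
    if g1.sd == 0 and g2.sd == 0:
        raise ValueError("both standard deviations are zero: t is undefined")
    v1, v2 = g1.sd**2, g2.sd**2
    if variant == "pooled":
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * v1 + (g2.n - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    elif variant == "welch":
        se = np.sqrt(v1 / g1.n + v2 / g2.n)
        df = (v1 / g1.n + v2 / g2.n) ** 2 / (
            (v1 / g1.n) ** 2 / (g1.n - 1) + (v2 / g2.n) ** 2 / (g2.n - 1)
        )
    else:
        raise ValueError(f"unknown variant {variant!r}; expected 'pooled' or 'welch'")
    t = (g1.mean - g2.mean) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p
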