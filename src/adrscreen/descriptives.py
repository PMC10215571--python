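"""Stratified descriptive tables and ADR-category extraction.

The counting unit throughout is the ICSR (case report), not the
individual drug–reaction pair: a case reporting two member PTs of the
same category is counted once in that category, though it increments
both PT rows of the per-PT breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
import numpy as np
import pandas as pd

from .icsr import (
    AGE_GROUPS,
    ICSR,
    ORIGIN_LEVELS,
    REPORTER_LEVELS,
    SEX_LEVELS,
    as_frame,
)
from .terms import AdrCategory

STRATIFIERS: dict[str, tuple[str, ...]] = {
    "age_group": AGE_GROUPS,
    "sex": SEX_LEVELS,
    "origin": ORIGIN_LEVELS,
    "reporter": REPORTER_LEVELS,
}


def format_percent(numerator: int, denominator: int) -> str:
    """Render 100*numerator/denominator with exactly two decimals,
    rounded half away from zero (so 0.125 -> "12.50"... i.e. 12.5%
    renders as "12.50" and 3.565% as "3.57")."""
    if denominator <= 0:
        raise ZeroDivisionError("format_percent denominator must be positive")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return str(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percent_value(numerator: int, denominator: int) -> float:
    """Full-precision percentage as a float."""
    if denominator <= 0:
        raise ZeroDivisionError("percent denominator must be positive")
    return 100.0 * numerator / denominator


def case_in_category(case: ICSR, category: AdrCategory) -> bool:
    """True iff the case reports at least one member PT of the category."""
    return not case.reaction_keys.isdisjoint(category.member_keys)


def flag_category(frame: pd.DataFrame, category: AdrCategory) -> np.ndarray:
    """Vectorised :func:`case_in_category` over the internal frame."""
    keys = category.member_keys
    return np.fromiter(
        (not rx.isdisjoint(keys) for rx in frame["rx_keys"]),
        dtype=bool,
        count=len(frame),
    )


def flag_drug(frame: pd.DataFrame, drug: str) -> np.ndarray:
    key = drug.strip().lower()
    return np.fromiter(
        (key in dk for dk in frame["drug_keys"]),
        dtype=bool,
        count=len(frame),
    )


@dataclass
class DescriptiveTable:
    """Counts and percents of one stratification variable for one subset."""

    variable: str
    rows: dict[str, tuple[int, float]]  # stratum -> (count, percent)

    @property
    def total(self) -> int:
        return sum(n for n, _ in self.rows.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stratum": s,
                    "count": n,
                    "percent": format_percent(n, self.total) if self.total else "",
                }
                for s, (n, _) in self.rows.items()
            ],
            columns=["stratum", "count", "percent"],
        )


def distribution_by(data, variable: str) -> DescriptiveTable:
    """Distribution of cases over one of the four stratifiers.

    Every level of the stratifier appears (count 0 if unobserved), in the
    portal's fixed order with ``Not specified`` last.
    """
    if variable not in STRATIFIERS:
        raise ValueError(f"unknown stratifier {variable!r}; use one of {sorted(STRATIFIERS)}")
    frame = as_frame(data)
    counts = frame[variable].value_counts() if len(frame) else pd.Series(dtype=int)
    total = int(counts.sum())
    rows: dict[str, tuple[int, float]] = {}
    for level in STRATIFIERS[variable]:
        n = int(counts.get(level, 0))
        rows[level] = (n, percent_value(n, total) if total else 0.0)
    return DescriptiveTable(variable=variable, rows=rows)


@dataclass
class CategorySummary:
    """Category burden for one drug: how many of its reports fall in the
    category, the fatal fraction among those, and the per-PT breakdown."""

    drug: str
    category: str
    n_cases: int
    n_total: int
    fatal_n: int
    pt_breakdown: dict[str, tuple[int, float]]  # canonical PT -> (count, % of n_cases)

    @property
    def percent(self) -> float:
        return percent_value(self.n_cases, self.n_total)

    @property
    def percent_str(self) -> str:
        return format_percent(self.n_cases, self.n_total)

    @property
    def fatal_percent(self) -> float | None:
        if self.n_cases == 0:
            return None
        return percent_value(self.fatal_n, self.n_cases)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pt": pt,
                "count": n,
                "percent": format_percent(n, self.n_cases) if self.n_cases else "",
            }
            for pt, (n, _) in self.pt_breakdown.items()
        ]
        return pd.DataFrame(rows, columns=["pt", "count", "percent"])


def category_summary(data, drug: str, category: AdrCategory) -> CategorySummary:
    """Summarise one ADR category for one suspected drug.

    ``n_total`` is the number of reports naming the drug as suspected;
    ``n_cases`` those of them with at least one member PT.  The per-PT
    breakdown counts cases containing each member PT (a case with two
    member PTs increments both PT rows but ``n_cases`` once); the fatal
    denominator is ``n_cases``.
    """
    frame = as_frame(data)
    sub = frame[flag_drug(frame, drug)] if len(frame) else frame
    n_total = len(sub)
    if n_total == 0:
        raise ValueError(f"no reports name drug {drug!r}; percentages undefined")
    in_cat = flag_category(sub, category)
    cat_cases = sub[in_cat]
    n_cases = int(in_cat.sum())
    fatal_n = int(cat_cases["fatal"].sum())
    breakdown: dict[str, tuple[int, float]] = {}
    if n_cases:
        member_keys = {m.key: m.label for m in category.members}
        for alias, target in category.aliases.items():
            member_keys[alias] = category.canonical_label(target)  # type: ignore[assignment]
        tallies: dict[str, int] = {}
        for rx in cat_cases["rx_keys"]:
            hit_labels = {member_keys[k] for k in rx if k in member_keys}
            for lbl in hit_labels:
                tallies[lbl] = tallies.get(lbl, 0) + 1
        order = sorted(tallies, key=lambda lbl: (-tallies[lbl], lbl))
        breakdown = {
            lbl: (tallies[lbl], percent_value(tallies[lbl], n_cases)) for lbl in order
        }
    return CategorySummary(
        drug=drug,
        category=category.name,
        n_cases=n_cases,
        n_total=n_total,
        fatal_n=fatal_n,
        pt_breakdown=breakdown,
    )
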