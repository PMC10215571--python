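"""Reporting-odds-ratio (ROR) disproportionality analysis.

For a target drug and a comparator drug, reports are cross-classified
into a 2x2 contingency table::

              in category    not in category
    target         a               b
    comparator     c               d

ROR = (a*d)/(b*c), with the Wald standard error on the log scale
SE = sqrt(1/a + 1/b + 1/c + 1/d) and the 95% confidence interval
exp(ln ROR +/- 1.96*SE).  A signal of disproportionate reporting (SDR)
requires at least five target-drug reports in the category and a CI
lower bound strictly above 1.  Tables with an empty cell are handled by
the Haldane–Anscombe correction (+0.5 on all four cells) by default.

The model-style interface (:class:`DisproportionalityModel` /
:class:`ScreenResults`) wraps the functional operations, in the spirit
of statsmodels: build the model from data, ``fit()`` to obtain results,
then inspect ``summary()`` or the results table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .descriptives import flag_category, flag_drug
from .icsr import RunConfig, as_frame, read_linelist
from .terms import AdrCategory, builtin_categories

logger = logging.getLogger(__name__)

Z_95 = 1.96  # fixed conventional value at alpha = 0.05

MIN_REPORTS_FOR_SIGNAL = 5

STAR_THRESHOLDS = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
)


class ZeroCellError(ValueError):
    """A contingency cell is empty and the policy forbids correction."""


class MissingDrugError(ValueError):
    """A drug named in the analysis has no reports in the dataset."""


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 table for one (target, comparator, category) triple.

    When ``corrected`` is true, the stored entries already include the
    Haldane–Anscombe +0.5.
    """

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency entries must be non-negative")

    @classmethod
    def from_counts(
        cls, a: int, b: int, c: int, d: int, policy: str = "haldane"
    ) -> "ContingencyTable":
        if min(a, b, c, d) < 0:
            raise ValueError("counts must be non-negative")
        if min(a, b, c, d) == 0:
            if policy == "haldane":
                logger.info(
                    "zero cell in (a=%d, b=%d, c=%d, d=%d); Haldane-Anscombe +0.5 applied",
                    a, b, c, d,
                )
                return cls(a + 0.5, b + 0.5, c + 0.5, d + 0.5, corrected=True)
            if policy == "error":
                raise ZeroCellError(f"zero cell in (a={a}, b={b}, c={c}, d={d})")
            raise ValueError(f"unknown zero_cell_policy {policy!r}")
        return cls(float(a), float(b), float(c), float(d), corrected=False)

    @property
    def n_reports(self) -> int:
        """Uncorrected count of target-drug reports in the category."""
        return int(round(self.a - 0.5)) if self.corrected else int(round(self.a))


@dataclass(frozen=True)
class RorResult:
    """Point estimate, uncertainty and signal classification for one pair."""

    ror: float
    se_ln: float
    ci_low: float
    ci_high: float
    p_value: float
    n_reports: int
    signal: bool
    stars: str


def stars_for(p_value: float) -> str:
    """Figure-legend significance stars: * p<0.05, ** p<=0.01,
    *** p<=0.001, **** p<=0.0001."""
    for threshold, mark in STAR_THRESHOLDS:
        if p_value <= threshold:
            return mark
    return "*" if p_value < 0.05 else ""


def detect_signal(result: RorResult) -> bool:
    """Signal of disproportionate reporting: at least five reports and a
    95% CI lower bound strictly above 1."""
    return result.n_reports >= MIN_REPORTS_FOR_SIGNAL and result.ci_low > 1.0


def compute_ror(table: ContingencyTable, alpha: float = 0.05) -> RorResult:
    """ROR with Wald CI and a two-sided normal p-value on ln(ROR)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) <= 0:
        raise ValueError("all four effective cells must be positive; apply a zero-cell policy")
    ror = (a * d) / (b * c)
    se_ln = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = Z_95 if alpha == 0.05 else float(stats.norm.ppf(1 - alpha / 2))
    ln_ror = math.log(ror)
    ci_low = math.exp(ln_ror - z * se_ln)
    ci_high = math.exp(ln_ror + z * se_ln)
    p_value = 2.0 * float(stats.norm.sf(abs(ln_ror) / se_ln))
    partial = RorResult(
        ror=ror, se_ln=se_ln, ci_low=ci_low, ci_high=ci_high,
        p_value=p_value, n_reports=table.n_reports, signal=False, stars=stars_for(p_value),
    )
    return RorResult(
        ror=ror, se_ln=se_ln, ci_low=ci_low, ci_high=ci_high,
        p_value=p_value, n_reports=table.n_reports,
        signal=detect_signal(partial), stars=partial.stars,
    )


def build_contingency(
    data,
    target: str,
    comparator: str,
    category: AdrCategory,
    policy: str = "haldane",
) -> ContingencyTable:
    """Cross-classify reports into the 2x2 table for one drug pair.

    A case naming both drugs as suspected contributes to both margins.
    """
    if target.strip().lower() == comparator.strip().lower():
        raise ValueError(f"target and comparator are the same drug: {target!r}")
    frame = as_frame(data)
    in_cat = flag_category(frame, category) if len(frame) else np.zeros(0, bool)
    t_mask = flag_drug(frame, target) if len(frame) else np.zeros(0, bool)
    c_mask = flag_drug(frame, comparator) if len(frame) else np.zeros(0, bool)
    if not t_mask.any():
        raise MissingDrugError(f"target drug {target!r} has no reports in the dataset")
    if not c_mask.any():
        raise MissingDrugError(f"comparator drug {comparator!r} has no reports in the dataset")
    a = int((t_mask & in_cat).sum())
    b = int((t_mask & ~in_cat).sum())
    c = int((c_mask & in_cat).sum())
    d = int((c_mask & ~in_cat).sum())
    return ContingencyTable.from_counts(a, b, c, d, policy=policy)


@dataclass(frozen=True)
class ScreenRow:
    """One row of the disproportionality screen."""

    target: str
    comparator: str
    category: str
    table: ContingencyTable | None
    result: RorResult | None
    error: str | None = None

    @property
    def available(self) -> bool:
        return self.result is not None


def screen(data, config: RunConfig) -> list[ScreenRow]:
    """Run the full screen: targets x comparators x categories, in config
    order.  Per-pair errors (missing drug, refused zero cell) are logged
    and yield an unavailable row instead of aborting the screen."""
    frame = as_frame(data)
    rows: list[ScreenRow] = []
    for target in config.target_drugs:
        for comparator in config.comparator_drugs:
            for category in config.categories:
                try:
                    table = build_contingency(
                        frame, target, comparator, category,
                        policy=config.zero_cell_policy,
                    )
                    result = compute_ror(table, alpha=config.alpha)
                    rows.append(ScreenRow(target, comparator, category.name, table, result))
                except (MissingDrugError, ZeroCellError) as exc:
                    logger.warning(
                        "screen %s vs %s [%s] unavailable: %s",
                        target, comparator, category.name, exc,
                    )
                    rows.append(
                        ScreenRow(target, comparator, category.name, None, None, str(exc))
                    )
    return rows


def screen_frame(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    """Tabular (machine-readable) form of the screen output."""
    recs = []
    for r in rows:
        if r.available:
            assert r.table is not None and r.result is not None
            recs.append(
                {
                    "target": r.target,
                    "comparator": r.comparator,
                    "category": r.category,
                    "a": r.table.a,
                    "b": r.table.b,
                    "c": r.table.c,
                    "d": r.table.d,
                    "corrected": r.table.corrected,
                    "ror": r.result.ror,
                    "ci_low": r.result.ci_low,
                    "ci_high": r.result.ci_high,
                    "p_value": r.result.p_value,
                    "stars": r.result.stars,
                    "signal": r.result.signal,
                    "error": "",
                }
            )
        else:
            recs.append(
                {
                    "target": r.target, "comparator": r.comparator, "category": r.category,
                    "a": np.nan, "b": np.nan, "c": np.nan, "d": np.nan,
                    "corrected": False, "ror": np.nan, "ci_low": np.nan,
                    "ci_high": np.nan, "p_value": np.nan, "stars": "",
                    "signal": False, "error": r.error or "unavailable",
                }
            )
    return pd.DataFrame(
        recs,
        columns=[
            "target", "comparator", "category", "a", "b", "c", "d", "corrected",
            "ror", "ci_low", "ci_high", "p_value", "stars", "signal", "error",
        ],
    )


class DisproportionalityModel:
    """ROR disproportionality screen as a fittable model.

    Parameters
    ----------
    data
        A list of :class:`~adrscreen.icsr.ICSR` or the internal DataFrame.
    config
        A :class:`~adrscreen.icsr.RunConfig`; alternatively pass
        ``targets``/``comparators`` (and optionally ``categories``,
        ``zero_cell``, ``alpha``) to build one.
    """

    def __init__(
        self,
        data,
        config: RunConfig | None = None,
        *,
        targets: Sequence[str] | None = None,
        comparators: Sequence[str] | None = None,
        categories: Iterable[AdrCategory] | None = None,
        zero_cell: str = "haldane",
        alpha: float = 0.05,
    ) -> None:
        if config is None:
            if targets is None or comparators is None:
                raise ValueError("provide a RunConfig or targets= and comparators=")
            config = RunConfig(
                target_drugs=list(targets),
                comparator_drugs=list(comparators),
                categories=list(categories) if categories is not None else builtin_categories(),
                zero_cell_policy=zero_cell,
                alpha=alpha,
            )
        self.config = config
        self.frame = as_frame(data)

    @classmethod
    def from_linelist(cls, path: str | Path, config: RunConfig, **kw) -> "DisproportionalityModel":
        return cls(read_linelist(path, **kw), config)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config: RunConfig) -> "DisproportionalityModel":
        return cls(frame, config)

    def pair_table(self, target: str, comparator: str, category: AdrCategory) -> ContingencyTable:
        return build_contingency(
            self.frame, target, comparator, category, policy=self.config.zero_cell_policy
        )

    def fit(self) -> "ScreenResults":
        rows = screen(self.frame, self.config)
        return ScreenResults(self, rows)


class ScreenResults:
    """Fitted screen: per-pair RORs, CIs, p-values and signal flags."""

    def __init__(self, model: DisproportionalityModel, rows: list[ScreenRow]) -> None:
        self.model = model
        self.rows = rows
        self.table = screen_frame(rows)

    @property
    def n_signals(self) -> int:
        return int(self.table["signal"].sum())

    def pair_result(self, target: str, comparator: str, category: str) -> RorResult:
        for r in self.rows:
            if (
                r.target.lower() == target.lower()
                and r.comparator.lower() == comparator.lower()
                and r.category == category
            ):
                if r.result is None:
                    raise MissingDrugError(r.error or "pair unavailable")
                return r.result
        raise KeyError((target, comparator, category))

    def summary(self) -> str:
        """Human-readable screen table, one row per drug pair and category."""
        df = self.table.copy()
        for col in ("ror", "ci_low", "ci_high"):
            df[col] = df[col].map(lambda v: f"{v:.4f}" if pd.notna(v) else "")
        df["p_value"] = df["p_value"].map(lambda v: f"{v:.3g}" if pd.notna(v) else "")
        df["signal"] = df["signal"].map({True: "SDR", False: ""})
        cols = ["target", "comparator", "category", "a", "b", "c", "d",
                "ror", "ci_low", "ci_high", "p_value", "stars", "signal"]
        header = (
            f"Disproportionality screen: {len(self.rows)} pairs, "
            f"{self.n_signals} signal(s) of disproportionate reporting\n"
        )
        return header + df[cols].to_string(index=False)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False, lineterminator="\n")
        return path
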