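"""Individual Case Safety Report (ICSR) data model and line-list I/O.

An ICSR is one spontaneous report: suspected drug(s), reaction PTs and
coarse demographics as exposed by public ADR portals — the EMA age bands,
sex, EEA/non-EEA origin, reporter group and a case-level fatal-outcome
flag.  Line-lists are UTF-8 delimited text with one row per case; the
reactions (and drugs) cell holds a semicolon-separated list, since commas
occur inside PT labels.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .terms import AdrCategory, PreferredTerm, builtin_categories, normalize_pt

logger = logging.getLogger(__name__)

NOT_SPECIFIED = "Not specified"

# EMA age bands, in the order portals report them.
AGE_GROUPS = (
    "0-1 month",
    "2 months-2 years",
    "3-11 years",
    "12-17 years",
    "18-64 years",
    "65-85 years",
    ">85 years",
    NOT_SPECIFIED,
)
SEX_LEVELS = ("Female", "Male", NOT_SPECIFIED)
ORIGIN_LEVELS = ("EEA", "Non EEA", NOT_SPECIFIED)
REPORTER_LEVELS = (
    "Healthcare professional",
    "Non healthcare professional",
    NOT_SPECIFIED,
)

LINELIST_COLUMNS = (
    "case_id",
    "drugs",
    "reactions",
    "age_group",
    "sex",
    "origin",
    "reporter",
    "fatal",
)

FIELD_SEP = ";"  # sub-delimiter inside the drugs / reactions cells


class LineListFormatError(ValueError):
    """The file does not have the expected line-list layout."""


class RecordError(ValueError):
    """A row violates a record-level invariant (names the row)."""


def _canon_token(token: str) -> str:
    # en/em dashes appear in portal exports of the age bands
    return " ".join(token.replace("–", "-").replace("—", "-").split()).lower()


def _level_map(levels: Sequence[str]) -> dict[str, str]:
    m = {_canon_token(lv): lv for lv in levels}
    return m


_AGE_MAP = _level_map(AGE_GROUPS)
_SEX_MAP = _level_map(SEX_LEVELS)
_SEX_MAP.update({"f": "Female", "m": "Male"})
_ORIGIN_MAP = _level_map(ORIGIN_LEVELS)
_ORIGIN_MAP.update({"non-eea": "Non EEA", "noneea": "Non EEA"})
_REPORTER_MAP = _level_map(REPORTER_LEVELS)
_REPORTER_MAP.update(
    {
        "hcp": "Healthcare professional",
        "non-hcp": "Non healthcare professional",
        "non-healthcare professional": "Non healthcare professional",
    }
)
for _m in (_AGE_MAP, _SEX_MAP, _ORIGIN_MAP, _REPORTER_MAP):
    _m.update({"": NOT_SPECIFIED, "not specified": NOT_SPECIFIED, "notspecified": NOT_SPECIFIED})


def _coerce_level(token: str, mapping: dict[str, str], field_name: str, case_id: str) -> str:
    key = _canon_token(str(token))
    if key in mapping:
        return mapping[key]
    logger.warning(
        "case %s: unrecognized %s value %r mapped to %r",
        case_id, field_name, token, NOT_SPECIFIED,
    )
    return NOT_SPECIFIED


@dataclass(frozen=True)
class ICSR:
    """One Individual Case Safety Report."""

    case_id: str
    drugs: frozenset[str]
    reactions: frozenset[PreferredTerm]
    age_group: str = NOT_SPECIFIED
    sex: str = NOT_SPECIFIED
    origin: str = NOT_SPECIFIED
    reporter: str = NOT_SPECIFIED
    fatal: bool = False

    def __post_init__(self) -> None:
        if not str(self.case_id).strip():
            raise RecordError("case_id must be non-empty")
        if not self.drugs:
            raise RecordError(f"case {self.case_id}: drugs set is empty")
        if not self.reactions:
            raise RecordError(f"case {self.case_id}: reactions set is empty")
        if self.age_group not in AGE_GROUPS:
            raise RecordError(f"case {self.case_id}: unknown age_group {self.age_group!r}")
        if self.sex not in SEX_LEVELS:
            raise RecordError(f"case {self.case_id}: unknown sex {self.sex!r}")
        if self.origin not in ORIGIN_LEVELS:
            raise RecordError(f"case {self.case_id}: unknown origin {self.origin!r}")
        if self.reporter not in REPORTER_LEVELS:
            raise RecordError(f"case {self.case_id}: unknown reporter {self.reporter!r}")

    @property
    def drug_keys(self) -> frozenset[str]:
        return frozenset(d.strip().lower() for d in self.drugs)

    @property
    def reaction_keys(self) -> frozenset[str]:
        return frozenset(r.key for r in self.reactions)


def _split_cell(cell: str) -> list[str]:
    return [p.strip() for p in str(cell).split(FIELD_SEP) if p.strip()]


def _parse_fatal(token: str, case_id: str) -> bool:
    key = _canon_token(str(token))
    if key in ("true", "1", "yes", "y", "fatal"):
        return True
    if key in ("false", "0", "no", "n", ""):
        return False
    logger.warning("case %s: unrecognized fatal flag %r treated as false", case_id, token)
    return False


def read_linelist(path: str | Path, delimiter: str = ",") -> list[ICSR]:
    """Read a line-list file into a list of :class:`ICSR`.

    Unrecognised or blank values in the four categorical fields map to
    ``Not specified`` with a logged warning.  A duplicate ``case_id`` or
    an empty drugs/reactions cell raises, naming the offending row.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in LINELIST_COLUMNS if c not in df.columns]
    if missing:
        raise LineListFormatError(f"{path}: missing required column(s) {missing}")
    cases: list[ICSR] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        cid = str(row.case_id).strip()
        if cid in seen:
            raise RecordError(f"{path} row {i}: duplicate case_id {cid!r}")
        seen.add(cid)
        drugs = _split_cell(row.drugs)
        if not drugs:
            raise RecordError(f"{path} row {i}: empty drugs cell (case {cid!r})")
        reactions = _split_cell(row.reactions)
        if not reactions:
            raise RecordError(f"{path} row {i}: empty reactions cell (case {cid!r})")
        cases.append(
            ICSR(
                case_id=cid,
                drugs=frozenset(drugs),
                reactions=frozenset(PreferredTerm(r) for r in reactions),
                age_group=_coerce_level(row.age_group, _AGE_MAP, "age_group", cid),
                sex=_coerce_level(row.sex, _SEX_MAP, "sex", cid),
                origin=_coerce_level(row.origin, _ORIGIN_MAP, "origin", cid),
                reporter=_coerce_level(row.reporter, _REPORTER_MAP, "reporter", cid),
                fatal=_parse_fatal(row.fatal, cid),
            )
        )
    return cases


def write_linelist(cases: Iterable[ICSR], path: str | Path, delimiter: str = ",") -> Path:
    """Write cases as a line-list, sorted by case_id, deterministically.

    The output is byte-identical across runs for the same input and
    round-trips through :func:`read_linelist`.
    """
    cases = sorted(cases, key=lambda c: c.case_id)
    ids = [c.case_id for c in cases]
    if len(ids) != len(set(ids)):
        raise RecordError("duplicate case_id in dataset")
    rows = [
        {
            "case_id": c.case_id,
            "drugs": FIELD_SEP.join(sorted(c.drugs)),
            "reactions": FIELD_SEP.join(sorted(r.label for r in c.reactions)),
            "age_group": c.age_group,
            "sex": c.sex,
            "origin": c.origin,
            "reporter": c.reporter,
            "fatal": "true" if c.fatal else "false",
        }
        for c in cases
    ]
    df = pd.DataFrame(rows, columns=list(LINELIST_COLUMNS))
    path = Path(path)
    df.to_csv(path, sep=delimiter, index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# DataFrame bridge — the vectorised in-memory form used by the analysis
# modules.  Columns mirror the line-list plus precomputed key sets.

def cases_to_frame(cases: Iterable[ICSR]) -> pd.DataFrame:
    """Convert ICSRs to the internal DataFrame form (one row per case)."""
    recs = [
        (
            c.case_id,
            sorted(c.drugs),
            sorted(r.label for r in c.reactions),
            c.age_group,
            c.sex,
            c.origin,
            c.reporter,
            c.fatal,
            c.drug_keys,
            c.reaction_keys,
        )
        for c in cases
    ]
    return pd.DataFrame(
        recs,
        columns=[
            "case_id", "drugs", "reactions", "age_group", "sex", "origin",
            "reporter", "fatal", "drug_keys", "rx_keys",
        ],
    )


def frame_to_cases(frame: pd.DataFrame) -> list[ICSR]:
    """Convert the internal DataFrame form back to ICSR objects."""
    return [
        ICSR(
            case_id=row.case_id,
            drugs=frozenset(row.drugs),
            reactions=frozenset(PreferredTerm(r) for r in row.reactions),
            age_group=row.age_group,
            sex=row.sex,
            origin=row.origin,
            reporter=row.reporter,
            fatal=bool(row.fatal),
        )
        for row in frame.itertuples(index=False)
    ]


def as_frame(data) -> pd.DataFrame:
    """Accept a list of ICSRs or an internal DataFrame; return the frame."""
    if isinstance(data, pd.DataFrame):
        return data
    return cases_to_frame(data)


def linelist_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """Configuration of one analysis run.

    ``zero_cell_policy`` controls 2x2 tables with an empty cell:
    ``"haldane"`` applies the Haldane–Anscombe +0.5 correction,
    ``"error"`` refuses the pair.
    """

    target_drugs: list[str]
    comparator_drugs: list[str]
    categories: list[AdrCategory] = field(default_factory=builtin_categories)
    zero_cell_policy: str = "haldane"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zero_cell_policy not in ("haldane", "error"):
            raise ValueError(f"unknown zero_cell_policy {self.zero_cell_policy!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        overlap = {d.lower() for d in self.target_drugs} & {
            d.lower() for d in self.comparator_drugs
        }
        if overlap:
            raise ValueError(f"target and comparator lists overlap: {sorted(overlap)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cats = raw.get("categories")
        if cats is None:
            categories = builtin_categories()
        else:
            categories = [
                AdrCategory.from_labels(c["name"], c["members"], c.get("aliases"))
                for c in cats
            ]
        return cls(
            target_drugs=list(raw["target_drugs"]),
            comparator_drugs=list(raw.get("comparator_drugs", [])),
            categories=categories,
            zero_cell_policy=raw.get("zero_cell_policy", "haldane"),
            alpha=float(raw.get("alpha", 0.05)),
            seed=int(raw.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> Path:
        data = {
            "target_drugs": list(self.target_drugs),
            "comparator_drugs": list(self.comparator_drugs),
            "categories": [
                {
                    "name": c.name,
                    "members": sorted(m.label for m in c.members),
                    "aliases": dict(c.aliases),
                }
                for c in self.categories
            ],
            "zero_cell_policy": self.zero_cell_policy,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path
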