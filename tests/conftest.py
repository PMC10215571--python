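"""Shared fixtures: deterministic exact-count report sets and random
small datasets for oracle-equivalence checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adrscreen import ICSR, PreferredTerm
from adrscreen.icsr import NOT_SPECIFIED
from adrscreen.terms import normalize_pt

FRAME_COLUMNS = [
    "case_id", "drugs", "reactions", "age_group", "sex", "origin",
    "reporter", "fatal", "drug_keys", "rx_keys",
]

BACKGROUND_PT = "Nausea"


def _row(case_id: str, drugs: list[str], reactions: list[str], fatal: bool = False):
    return (
        case_id,
        sorted(drugs),
        sorted(reactions),
        NOT_SPECIFIED,
        NOT_SPECIFIED,
        NOT_SPECIFIED,
        NOT_SPECIFIED,
        fatal,
        frozenset(d.lower() for d in drugs),
        frozenset(normalize_pt(r) for r in reactions),
    )


def drug_block(
    drug: str,
    total: int,
    category_pts: dict[str, dict[str, int]] | None = None,
    fatal_per_category: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Build `total` reports for one drug with exactly the given number of
    category cases, one member PT each (category blocks are disjoint);
    the remainder report only a background PT."""
    category_pts = category_pts or {}
    fatal_per_category = fatal_per_category or {}
    rows = []
    i = 0
    for cat, pt_counts in category_pts.items():
        fatal_left = fatal_per_category.get(cat, 0)
        for pt, cnt in pt_counts.items():
            for _ in range(cnt):
                rows.append(_row(f"{drug}-{i:06d}", [drug], [pt], fatal=fatal_left > 0))
                fatal_left -= 1
                i += 1
    if i > total:
        raise ValueError("category counts exceed total")
    while i < total:
        rows.append(_row(f"{drug}-{i:06d}", [drug], [BACKGROUND_PT]))
        i += 1
    return pd.DataFrame(rows, columns=FRAME_COLUMNS)


def combine(*frames: pd.DataFrame) -> pd.DataFrame:
    return pd.concat(frames, ignore_index=True)


def random_cases(rng: np.random.Generator, n: int, drugs, pts) -> list[ICSR]:
    """Small random datasets for brute-force oracle comparisons."""
    cases = []
    for i in range(n):
        k_d = rng.integers(1, min(3, len(drugs)) + 1)
        k_r = rng.integers(1, min(3, len(pts)) + 1)
        cases.append(
            ICSR(
                case_id=f"C{i:05d}",
                drugs=frozenset(rng.choice(drugs, size=k_d, replace=False)),
                reactions=frozenset(
                    PreferredTerm(p) for p in rng.choice(pts, size=k_r, replace=False)
                ),
                fatal=bool(rng.random() < 0.2),
            )
        )
    return cases


@pytest.fixture
def rng():
    return np.random.default_rng(20220918)
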