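"""Synthetic spontaneous-report (ICSR) generator.

Emulates a multi-drug spontaneous-report database: each drug profile
fixes its report count, the probability that a report falls in each ADR
category, selection weights over the category's member PTs, fatality
probabilities conditional on category membership, and categorical
demographic distributions (EMA age bands, sex, EEA origin, reporter
group).  Category memberships are sampled independently per category; a
case in a category receives one member PT (by weight) on top of 1-3
background PTs drawn from a non-category vocabulary.

All randomness flows from the scenario seed through one independent
sub-stream per drug profile (keyed by a stable hash of the drug name),
so adding or removing a drug never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .icsr import (
    AGE_GROUPS,
    ICSR,
    NOT_SPECIFIED,
    ORIGIN_LEVELS,
    REPORTER_LEVELS,
    SEX_LEVELS,
    frame_to_cases,
)
from .terms import builtin_categories, normalize_pt

_DEMO_LEVELS = {
    "age_group": AGE_GROUPS,
    "sex": SEX_LEVELS,
    "origin": ORIGIN_LEVELS,
    "reporter": REPORTER_LEVELS,
}

# Generic reaction PTs used as background noise; disjoint from the DR/DI
# query sets.
DEFAULT_BACKGROUND_VOCAB = (
    "Nausea",
    "Vomiting",
    "Diarrhoea",
    "Acute kidney injury",
    "Rash",
    "Pyrexia",
    "Headache",
    "Hepatotoxicity",
    "Thrombocytopenia",
    "Seizure",
    "Hypotension",
    "Dyspnoea",
)


def _check_dist(name: str, dist: Mapping[str, float], levels: Sequence[str]) -> None:
    for level in dist:
        if level not in levels:
            raise ValueError(f"{name}: unknown level {level!r}")
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"{name}: distribution sums to {total}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name}: negative probability")


@dataclass
class DrugProfile:
    """Generating parameters for one drug's reports."""

    drug: str
    n_cases: int
    p_category: Mapping[str, float]
    pt_weights: Mapping[str, Mapping[str, float]]
    p_fatal_given_category: Mapping[str, float] = field(default_factory=dict)
    p_fatal_background: float = 0.05
    demographics: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    co_suspect_with: str | None = None
    p_co_suspect: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        for cat, p in self.p_category.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{self.drug}: p_category[{cat!r}] = {p} outside [0,1]")
        for cat, p in self.p_fatal_given_category.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{self.drug}: p_fatal_given_category[{cat!r}] outside [0,1]")
        if not (0.0 <= self.p_fatal_background <= 1.0):
            raise ValueError(f"{self.drug}: p_fatal_background outside [0,1]")
        if not (0.0 <= self.p_co_suspect <= 1.0):
            raise ValueError(f"{self.drug}: p_co_suspect outside [0,1]")
        for cat, weights in self.pt_weights.items():
            if any(w <= 0 for w in weights.values()):
                raise ValueError(f"{self.drug}: non-positive PT weight in {cat!r}")
        for var, dist in self.demographics.items():
            if var not in _DEMO_LEVELS:
                raise ValueError(f"{self.drug}: unknown demographic {var!r}")
            _check_dist(f"{self.drug}.{var}", dist, _DEMO_LEVELS[var])


@dataclass
class ScenarioConfig:
    """A full simulated database: drug profiles + background vocabulary."""

    profiles: list[DrugProfile]
    background_vocab: Sequence[str] = DEFAULT_BACKGROUND_VOCAB
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.background_vocab:
            raise ValueError("background_vocab must be non-empty")
        category_keys = set()
        for prof in self.profiles:
            for weights in prof.pt_weights.values():
                category_keys |= {normalize_pt(pt) for pt in weights}
        for cat in builtin_categories():
            category_keys |= set(cat.member_keys)
        clash = {pt for pt in self.background_vocab if normalize_pt(pt) in category_keys}
        if clash:
            raise ValueError(f"background vocab overlaps category members: {sorted(clash)}")

    def to_yaml(self, path: str | Path) -> Path:
        data = {
            "seed": self.seed,
            "background_vocab": list(self.background_vocab),
            "profiles": [
                {
                    "drug": p.drug,
                    "n_cases": p.n_cases,
                    "p_category": dict(p.p_category),
                    "pt_weights": {c: dict(w) for c, w in p.pt_weights.items()},
                    "p_fatal_given_category": dict(p.p_fatal_given_category),
                    "p_fatal_background": p.p_fatal_background,
                    "demographics": {v: dict(d) for v, d in p.demographics.items()},
                    "co_suspect_with": p.co_suspect_with,
                    "p_co_suspect": p.p_co_suspect,
                }
                for p in self.profiles
            ],
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text())
        profiles = [
            DrugProfile(
                drug=p["drug"],
                n_cases=int(p["n_cases"]),
                p_category=p.get("p_category", {}),
                pt_weights=p.get("pt_weights", {}),
                p_fatal_given_category=p.get("p_fatal_given_category", {}),
                p_fatal_background=float(p.get("p_fatal_background", 0.05)),
                demographics=p.get("demographics", {}),
                co_suspect_with=p.get("co_suspect_with"),
                p_co_suspect=float(p.get("p_co_suspect", 0.0)),
            )
            for p in raw["profiles"]
        ]
        return cls(
            profiles=profiles,
            background_vocab=raw.get("background_vocab", DEFAULT_BACKGROUND_VOCAB),
            seed=int(raw.get("seed", 0)),
        )


def _profile_rng(seed: int, drug: str) -> np.random.Generator:
    # stable per-drug substream: crc32 keeps the derived key < 2**31
    return np.random.default_rng([int(seed), zlib.crc32(drug.encode()) & 0x7FFFFFFF])


def _sample_demographic(
    rng: np.random.Generator, n: int, var: str, dist: Mapping[str, float] | None
) -> np.ndarray:
    levels = _DEMO_LEVELS[var]
    if not dist:
        return np.full(n, NOT_SPECIFIED, dtype=object)
    names = list(dist.keys())
    probs = np.array([dist[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(names), size=n, p=probs)
    arr = np.array(names, dtype=object)[idx]
    # all names validated against the closed level lists at construction
    assert set(names) <= set(levels)
    return arr


def generate_frame(scenario: ScenarioConfig) -> pd.DataFrame:
    """Generate the scenario as the internal case DataFrame (fast path)."""
    vocab = list(scenario.background_vocab)
    parts: list[pd.DataFrame] = []
    for prof in scenario.profiles:
        rng = _profile_rng(scenario.seed, prof.drug)
        n = prof.n_cases
        cat_names = list(prof.p_category.keys())
        in_cat: dict[str, np.ndarray] = {}
        member_pick: dict[str, np.ndarray] = {}
        for cat in cat_names:
            in_cat[cat] = rng.random(n) < prof.p_category[cat]
            weights = prof.pt_weights.get(cat, {})
            if weights:
                labels = list(weights.keys())
                probs = np.array([weights[k] for k in labels], dtype=float)
                probs = probs / probs.sum()
                idx = rng.choice(len(labels), size=n, p=probs)
                member_pick[cat] = np.array(labels, dtype=object)[idx]
            elif prof.p_category[cat] > 0:
                raise ValueError(f"{prof.drug}: p_category[{cat!r}] > 0 but no pt_weights")
        bg_count = rng.integers(1, 4, size=n)
        bg_idx = rng.integers(0, len(vocab), size=(n, 3))
        # fatality: category cases take the (max, if several) conditional
        # probability, all other cases the background rate
        in_any = np.zeros(n, dtype=bool)
        cond = np.full(n, -1.0)
        for cat in cat_names:
            mask = in_cat[cat]
            p_cond = prof.p_fatal_given_category.get(cat, prof.p_fatal_background)
            cond = np.where(mask, np.maximum(cond, p_cond), cond)
            in_any |= mask
        p_fatal = np.where(in_any, cond, prof.p_fatal_background)
        fatal = rng.random(n) < p_fatal
        demo = {
            var: _sample_demographic(rng, n, var, prof.demographics.get(var))
            for var in _DEMO_LEVELS
        }
        co_mask = (
            rng.random(n) < prof.p_co_suspect
            if prof.co_suspect_with and prof.p_co_suspect > 0
            else np.zeros(n, dtype=bool)
        )
        # label -> normalised key cache; the label universe per profile
        # is small, the row count is not
        key_of = {lbl: normalize_pt(lbl) for lbl in vocab}
        for cat in member_pick:
            for lbl in set(member_pick[cat]):
                key_of.setdefault(lbl, normalize_pt(lbl))
        own_drugs = sorted({prof.drug})
        own_drug_keys = frozenset(d.strip().lower() for d in own_drugs)
        co_drugs = sorted({prof.drug, prof.co_suspect_with}) if prof.co_suspect_with else own_drugs
        co_drug_keys = frozenset(d.strip().lower() for d in co_drugs)
        rows = []
        for i in range(n):
            reactions = {vocab[j] for j in bg_idx[i, : bg_count[i]]}
            for cat in cat_names:
                if in_cat[cat][i]:
                    reactions.add(member_pick[cat][i])
            reactions_sorted = sorted(reactions)
            rows.append(
                (
                    f"{prof.drug}-{i:07d}",
                    co_drugs if co_mask[i] else own_drugs,
                    reactions_sorted,
                    demo["age_group"][i],
                    demo["sex"][i],
                    demo["origin"][i],
                    demo["reporter"][i],
                    bool(fatal[i]),
                    co_drug_keys if co_mask[i] else own_drug_keys,
                    frozenset(key_of[r] for r in reactions_sorted),
                )
            )
        parts.append(
            pd.DataFrame(
                rows,
                columns=[
                    "case_id", "drugs", "reactions", "age_group", "sex",
                    "origin", "reporter", "fatal", "drug_keys", "rx_keys",
                ],
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=[
                "case_id", "drugs", "reactions", "age_group", "sex",
                "origin", "reporter", "fatal", "drug_keys", "rx_keys",
            ]
        )
    return pd.concat(parts, ignore_index=True)


def generate_cases(scenario: ScenarioConfig) -> list[ICSR]:
    """Generate the scenario as a list of :class:`ICSR`."""
    return frame_to_cases(generate_frame(scenario))


# ---------------------------------------------------------------------------
# Reference scenario: the EudraVigilance antimicrobial landscape
# (data lock 31 December 2022) for colistin (COL), meropenem (MER) and
# linezolid (LIN) against ten comparator antimicrobials.

TARGET_DRUGS = ("COL", "MER", "LIN")
COMPARATOR_DRUGS = (
    "MOX", "TIG", "PIP/TAZ", "CEF/AVI", "VAN",
    "FLU", "ISA", "CAP", "AMF", "VOR",
)

# Report totals and category probabilities for the three target drugs,
# from the published EudraVigilance aggregates: 986 / 8,864 / 13,381
# reports; DR in 8.42% / 3.56% / 2.38% and DI in 10.14% / 9.45% / 4.15%.
_TARGET_CALIBRATION = {
    "COL": dict(
        n=986, p_dr=0.0842, p_di=0.1014, fatal_dr=0.24, fatal_di=0.35,
        dr_w={"drug resistance": 46, "pathogen resistance": 28, "multiple-drug resistance": 9},
        di_w={
            "drug ineffective": 85, "treatment failure": 5,
            "drug ineffective for unapproved indication": 4,
            "therapeutic product effect decreased": 1,
            "therapeutic product effect incomplete": 1,
            "decreased activity": 1, "therapeutic product ineffective": 1,
            "therapeutic response decreased": 1, "therapy non-responder": 1,
        },
        age={"18-64 years": 0.49, "65-85 years": 0.28, "0-1 month": 0.005,
             "2 months-2 years": 0.025, "3-11 years": 0.04, "12-17 years": 0.03,
             ">85 years": 0.05, NOT_SPECIFIED: 0.08},
        sex={"Female": 0.433, "Male": 0.529, NOT_SPECIFIED: 0.038},
        origin={"EEA": 0.75, "Non EEA": 0.2499, NOT_SPECIFIED: 0.0001},
        reporter={"Healthcare professional": 0.89,
                  "Non healthcare professional": 0.10, NOT_SPECIFIED: 0.01},
    ),
    "MER": dict(
        n=8864, p_dr=0.0356, p_di=0.0945, fatal_dr=0.20, fatal_di=0.28,
        dr_w={"drug resistance": 170, "pathogen resistance": 125, "multiple-drug resistance": 21},
        di_w={
            "drug ineffective": 683, "treatment failure": 54,
            "drug ineffective for unapproved indication": 35,
            "therapeutic product effect decreased": 11,
            "therapeutic product effect incomplete": 11,
            "decreased activity": 11, "therapeutic product ineffective": 11,
            "therapeutic response decreased": 11, "therapy non-responder": 11,
        },
        age={"18-64 years": 0.43, "65-85 years": 0.32, "0-1 month": 0.01,
             "2 months-2 years": 0.04, "3-11 years": 0.05, "12-17 years": 0.03,
             ">85 years": 0.06, NOT_SPECIFIED: 0.06},
        sex={"Female": 0.411, "Male": 0.553, NOT_SPECIFIED: 0.036},
        origin={"EEA": 0.40, "Non EEA": 0.5999, NOT_SPECIFIED: 0.0001},
        reporter={"Healthcare professional": 0.96,
                  "Non healthcare professional": 0.035, NOT_SPECIFIED: 0.005},
    ),
    "LIN": dict(
        n=13381, p_dr=0.0238, p_di=0.0415, fatal_dr=0.06, fatal_di=0.19,
        dr_w={"drug resistance": 142, "pathogen resistance": 165, "multiple-drug resistance": 12},
        di_w={
            "drug ineffective": 372, "treatment failure": 96,
            "drug ineffective for unapproved indication": 34,
            "therapeutic product effect decreased": 9,
            "therapeutic product effect incomplete": 9,
            "decreased activity": 9, "therapeutic product ineffective": 9,
            "therapeutic response decreased": 9, "therapy non-responder": 9,
        },
        age={"18-64 years": 0.41, "65-85 years": 0.35, "0-1 month": 0.005,
             "2 months-2 years": 0.03, "3-11 years": 0.045, "12-17 years": 0.03,
             ">85 years": 0.06, NOT_SPECIFIED: 0.07},
        sex={"Female": 0.388, "Male": 0.544, NOT_SPECIFIED: 0.068},
        origin={"EEA": 0.38, "Non EEA": 0.6199, NOT_SPECIFIED: 0.0001},
        reporter={"Healthcare professional": 0.89,
                  "Non healthcare professional": 0.10, NOT_SPECIFIED: 0.01},
    ),
}

# Comparator DR/DI reporting probabilities.  Where the published target
# RORs pin a comparator's odds down (the same rate is recovered from two
# independent target comparisons, e.g. MOX from both COL and MER), the
# back-solved value is used; the remaining rates and all comparator
# report counts are plausible fills, configurable via the ``overrides``
# argument of :func:`reference_scenario`.
_COMPARATOR_CALIBRATION = {
    "MOX": dict(n=12000, p_dr=0.0054, p_di=0.0312),
    "TIG": dict(n=3000, p_dr=0.0478, p_di=0.0900),
    "PIP/TAZ": dict(n=9000, p_dr=0.0107, p_di=0.0413),
    "CEF/AVI": dict(n=1500, p_dr=0.1190, p_di=0.1000),
    "VAN": dict(n=15000, p_dr=0.0150, p_di=0.0790),
    "FLU": dict(n=14000, p_dr=0.0244, p_di=0.0825),
    "ISA": dict(n=600, p_dr=0.0079, p_di=0.0600),
    "CAP": dict(n=2500, p_dr=0.0531, p_di=0.0500),
    "AMF": dict(n=5000, p_dr=0.0200, p_di=0.0600),
    "VOR": dict(n=4000, p_dr=0.0207, p_di=0.0500),
}

_GENERIC_DEMOGRAPHICS = {
    "age_group": {"18-64 years": 0.45, "65-85 years": 0.33, ">85 years": 0.05,
                  "3-11 years": 0.04, "12-17 years": 0.03, "2 months-2 years": 0.03,
                  "0-1 month": 0.01, NOT_SPECIFIED: 0.06},
    "sex": {"Female": 0.42, "Male": 0.54, NOT_SPECIFIED: 0.04},
    "origin": {"EEA": 0.45, "Non EEA": 0.5499, NOT_SPECIFIED: 0.0001},
    "reporter": {"Healthcare professional": 0.92,
                 "Non healthcare professional": 0.07, NOT_SPECIFIED: 0.01},
}


def reference_scenario(
    seed: int = 0,
    overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> ScenarioConfig:
    """The built-in 13-profile scenario: COL/MER/LIN plus ten comparator
    antimicrobials, calibrated to the published EudraVigilance aggregate
    counts (data lock 31 December 2022).

    ``overrides`` may replace ``n`` / ``p_dr`` / ``p_di`` per comparator.
    """
    dr_members, di_members = (c for c in builtin_categories())
    uniform_dr = {m.label: 1.0 for m in dr_members.members}
    uniform_di = {m.label: 1.0 for m in di_members.members}
    profiles: list[DrugProfile] = []
    for drug in TARGET_DRUGS:
        cal = _TARGET_CALIBRATION[drug]
        profiles.append(
            DrugProfile(
                drug=drug,
                n_cases=cal["n"],
                p_category={"DR": cal["p_dr"], "DI": cal["p_di"]},
                pt_weights={"DR": cal["dr_w"], "DI": cal["di_w"]},
                p_fatal_given_category={"DR": cal["fatal_dr"], "DI": cal["fatal_di"]},
                p_fatal_background=0.08,
                demographics={
                    "age_group": cal["age"], "sex": cal["sex"],
                    "origin": cal["origin"], "reporter": cal["reporter"],
                },
            )
        )
    for drug in COMPARATOR_DRUGS:
        cal = dict(_COMPARATOR_CALIBRATION[drug])
        if overrides and drug in overrides:
            cal.update(overrides[drug])
        profiles.append(
            DrugProfile(
                drug=drug,
                n_cases=int(cal["n"]),
                p_category={"DR": cal["p_dr"], "DI": cal["p_di"]},
                pt_weights={"DR": uniform_dr, "DI": uniform_di},
                p_fatal_given_category={"DR": 0.15, "DI": 0.15},
                p_fatal_background=0.08,
                demographics=_GENERIC_DEMOGRAPHICS,
            )
        )
    return ScenarioConfig(profiles=profiles, seed=seed)


def two_arm_scenario(
    p_target: float,
    p_comparator: float,
    n_per_arm: int,
    seed: int = 0,
    category: str = "DR",
) -> ScenarioConfig:
    """Minimal two-drug, one-category scenario with a known true
    reporting odds ratio (p_t/(1-p_t)) / (p_c/(1-p_c)); used for
    parameter-recovery and null-calibration studies."""
    dr_members = builtin_categories()[0]
    weights = {m.label: 1.0 for m in dr_members.members}
    mk = lambda name, p: DrugProfile(
        drug=name,
        n_cases=n_per_arm,
        p_category={category: p},
        pt_weights={category: weights},
        p_fatal_given_category={category: 0.15},
        p_fatal_background=0.08,
    )
    return ScenarioConfig(
        profiles=[mk("TARGET", p_target), mk("COMPARATOR", p_comparator)],
        seed=seed,
    )
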