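"""Synthetic ICSR generator: determinism, calibration, convergence."""

import math

import pandas as pd
import pytest

from adrscreen import (
    DrugProfile,
    ScenarioConfig,
    builtin_categories,
    build_contingency,
    category_summary,
    compute_ror,
    generate_cases,
    generate_frame,
    read_linelist,
    reference_scenario,
    two_arm_scenario,
    write_linelist,
)
from adrscreen.simulate import COMPARATOR_DRUGS, TARGET_DRUGS

DR, DI = builtin_categories()


def _simple_profile(drug="DRG", n=500, p_dr=0.2, **kw):
    return DrugProfile(
        drug=drug,
        n_cases=n,
        p_category={"DR": p_dr},
        pt_weights={"DR": {"drug resistance": 2.0, "pathogen resistance": 1.0}},
        **kw,
    )


class TestDeterminism:
    def test_same_scenario_same_seed_identical(self):
        sc = ScenarioConfig(profiles=[_simple_profile()], seed=11)
        pd.testing.assert_frame_equal(generate_frame(sc), generate_frame(sc))

    def test_different_seed_differs(self):
        a = generate_frame(ScenarioConfig(profiles=[_simple_profile()], seed=1))
        b = generate_frame(ScenarioConfig(profiles=[_simple_profile()], seed=2))
        assert not a["rx_keys"].equals(b["rx_keys"])

    def test_adding_a_profile_does_not_perturb_existing_draws(self):
        base = [_simple_profile("A"), _simple_profile("B", p_dr=0.1)]
        extra = base + [_simple_profile("C", p_dr=0.3)]
        f1 = generate_frame(ScenarioConfig(profiles=base, seed=5))
        f2 = generate_frame(ScenarioConfig(profiles=extra, seed=5))
        pd.testing.assert_frame_equal(
            f1, f2[f2.case_id.str.startswith(("A-", "B-"))].reset_index(drop=True)
        )


class TestGenerativeStructure:
    def test_zero_probability_yields_no_category_cases(self):
        sc = ScenarioConfig(profiles=[_simple_profile(p_dr=0.0)], seed=3)
        summ = category_summary(generate_frame(sc), "DRG", DR)
        assert summ.n_cases == 0

    def test_empirical_category_fraction_within_3_sigma(self):
        p, n = 0.2, 4000
        sc = ScenarioConfig(profiles=[_simple_profile(n=n, p_dr=p)], seed=42)
        summ = category_summary(generate_frame(sc), "DRG", DR)
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(summ.n_cases / n - p) < 3 * sigma

    def test_empirical_fatal_fraction_conditional_on_category(self):
        p_fatal = 0.4
        sc = ScenarioConfig(
            profiles=[
                _simple_profile(
                    n=4000, p_dr=0.3,
                    p_fatal_given_category={"DR": p_fatal},
                    p_fatal_background=0.05,
                )
            ],
            seed=7,
        )
        summ = category_summary(generate_frame(sc), "DRG", DR)
        frac = summ.fatal_n / summ.n_cases
        sigma = math.sqrt(p_fatal * (1 - p_fatal) / summ.n_cases)
        assert abs(frac - p_fatal) < 3 * sigma

    def test_demographic_sampling_matches_weights_within_3_sigma(self):
        from adrscreen import distribution_by

        weights = {"Female": 0.4, "Male": 0.55, "Not specified": 0.05}
        sc = ScenarioConfig(
            profiles=[_simple_profile(n=5000, demographics={"sex": weights})], seed=9
        )
        table = distribution_by(generate_frame(sc), "sex")
        for level, w in weights.items():
            frac = table.rows[level][0] / 5000
            assert abs(frac - w) < 3 * math.sqrt(w * (1 - w) / 5000)

    def test_every_case_has_background_reactions(self):
        sc = ScenarioConfig(profiles=[_simple_profile(p_dr=0.0, n=50)], seed=1)
        frame = generate_frame(sc)
        assert frame["reactions"].map(len).between(1, 3).all()

    def test_co_suspect_cases_count_on_both_screen_margins(self):
        prof = _simple_profile("A", n=300, p_dr=0.2)
        prof.co_suspect_with = "B"
        prof.p_co_suspect = 0.5
        other = _simple_profile("B", n=300, p_dr=0.2)
        frame = generate_frame(ScenarioConfig(profiles=[prof, other], seed=13))
        table = build_contingency(frame, "A", "B", DR)
        n_b = (table.c + table.d) - (0.5 * 2 if table.corrected else 0)
        assert n_b > 300  # B's own cases plus A's co-suspect cases

    def test_background_vocab_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            ScenarioConfig(profiles=[_simple_profile()], background_vocab=["Drug ineffective"])

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            _simple_profile(p_dr=1.5)

    def test_round_trips_through_line_list_store(self, tmp_path):
        sc = ScenarioConfig(profiles=[_simple_profile(n=80)], seed=21)
        cases = generate_cases(sc)
        path = write_linelist(cases, tmp_path / "sim.csv")
        assert sorted(read_linelist(path), key=lambda c: c.case_id) == sorted(
            cases, key=lambda c: c.case_id
        )

    def test_scenario_yaml_round_trip(self, tmp_path):
        sc = two_arm_scenario(0.1, 0.05, 200, seed=4)
        path = sc.to_yaml(tmp_path / "scenario.yaml")
        back = ScenarioConfig.from_yaml(path)
        pd.testing.assert_frame_equal(generate_frame(back), generate_frame(sc))


class TestReferenceScenario:
    def test_thirteen_profiles_three_targets_ten_comparators(self):
        sc = reference_scenario()
        assert len(sc.profiles) == 13
        assert [p.drug for p in sc.profiles[:3]] == list(TARGET_DRUGS)
        assert tuple(p.drug for p in sc.profiles[3:]) == COMPARATOR_DRUGS

    def test_colistin_profile_matches_public_aggregates(self):
        col = reference_scenario().profiles[0]
        assert col.n_cases == 986
        assert col.p_category == {"DR": 0.0842, "DI": 0.1014}
        assert col.n_cases * col.p_category["DR"] == pytest.approx(83.0, abs=0.05)
        assert col.p_fatal_given_category == {"DR": 0.24, "DI": 0.35}
        assert col.demographics["sex"]["Male"] == 0.529

    def test_target_sizes_and_male_fractions(self):
        sc = reference_scenario()
        sizes = {p.drug: p.n_cases for p in sc.profiles[:3]}
        assert sizes == {"COL": 986, "MER": 8864, "LIN": 13381}
        males = [p.demographics["sex"]["Male"] for p in sc.profiles[:3]]
        assert males == [0.529, 0.553, 0.544]

    def test_comparator_overrides_apply(self):
        sc = reference_scenario(overrides={"MOX": {"n": 100, "p_dr": 0.5}})
        mox = next(p for p in sc.profiles if p.drug == "MOX")
        assert mox.n_cases == 100 and mox.p_category["DR"] == 0.5


class TestKnownOddsRatio:
    def test_screen_recovers_generating_odds_ratio(self):
        # p 0.10 vs 0.05 -> true ROR (0.1/0.9)/(0.05/0.95) = 2.111
        sc = two_arm_scenario(0.10, 0.05, 20000, seed=31)
        frame = generate_frame(sc)
        table = build_contingency(frame, "TARGET", "COMPARATOR", DR)
        res = compute_ror(table)
        true_or = (0.10 / 0.90) / (0.05 / 0.95)
        # single replicate: a CI-coverage assertion would fail 5% of the
        # time by construction, so check to 3.5 sigma on the log scale
        assert abs(math.log(res.ror / true_or)) < 3.5 * res.se_ln
        assert res.signal
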