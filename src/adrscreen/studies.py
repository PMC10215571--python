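"""Monte-Carlo operating characteristics of the ROR screen.

Two standard evaluations on the synthetic generator: parameter recovery
under a known non-null reporting odds ratio, and the false-signal rate
under identical reporting probabilities (the null).  Both drive the
full path — generate reports, build the 2x2 table, estimate the ROR —
so they exercise exactly what a real screen runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disproportionality import build_contingency, compute_ror
from .simulate import generate_frame, two_arm_scenario
from .terms import builtin_categories

_MOD = 2**31


def _replicate_seeds(seed: int, n_reps: int) -> list[int]:
    """Well-separated per-replicate scenario seeds from one root seed."""
    children = np.random.SeedSequence(seed).spawn(n_reps)
    return [int(c.generate_state(1)[0]) % _MOD for c in children]


def true_odds_ratio(p_target: float, p_comparator: float) -> float:
    return (p_target / (1 - p_target)) / (p_comparator / (1 - p_comparator))


@dataclass
class RecoveryStudy:
    true_or: float
    mean_ror: float
    coverage: float
    n_reps: int
    n_per_arm: int


@dataclass
class NullStudy:
    signal_rate: float
    n_reps: int
    n_per_arm: int


def _replicate_ror(p_t: float, p_c: float, n_per_arm: int, seed: int):
    dr = builtin_categories()[0]
    frame = generate_frame(two_arm_scenario(p_t, p_c, n_per_arm, seed=seed))
    return compute_ror(build_contingency(frame, "TARGET", "COMPARATOR", dr))


def recovery_study(
    p_target: float = 0.10,
    p_comparator: float = 0.05,
    n_per_arm: int = 20_000,
    n_reps: int = 200,
    seed: int = 0,
) -> RecoveryStudy:
    """Estimate bias and 95% CI coverage of the ROR at a known truth."""
    truth = true_odds_ratio(p_target, p_comparator)
    rors, covered = [], 0
    for rep_seed in _replicate_seeds(seed, n_reps):
        res = _replicate_ror(p_target, p_comparator, n_per_arm, rep_seed)
        rors.append(res.ror)
        covered += res.ci_low < truth < res.ci_high
    return RecoveryStudy(
        true_or=truth,
        mean_ror=float(np.mean(rors)),
        coverage=covered / n_reps,
        n_reps=n_reps,
        n_per_arm=n_per_arm,
    )


def null_study(
    p_both: float = 0.05,
    n_per_arm: int = 5_000,
    n_reps: int = 400,
    seed: int = 0,
) -> NullStudy:
    """Frequency of false signals when both arms report at the same rate.

    The signal rule needs the CI lower bound above 1, i.e. a one-sided
    exceedance, so the expected rate is ~2.5%, bounded by 5%.
    """
    signals = 0
    for rep_seed in _replicate_seeds(seed, n_reps):
        res = _replicate_ror(p_both, p_both, n_per_arm, rep_seed)
        signals += res.signal
    return NullStudy(signal_rate=signals / n_reps, n_reps=n_reps, n_per_arm=n_per_arm)
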