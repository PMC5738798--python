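"""Simulation studies validating the pipeline: type-I calibration and power.

These routines generate many synthetic cohorts, run the actual analysis steps
on each, and tally rejections.  They back the package's statistical
guarantees: under a shared generating model every step should reject at its
nominal alpha, and a planted persistence boost should be recovered with high
power at realistic group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import DEFAULT_ALPHABET
from .group_stats import (
    AlphaPolicy,
    hypothesized_keys,
    prepare_arf,
    rank_across_subjects,
    run_exploratory_step,
    run_replication_step,
    run_specificity_step,
)
from .sequence_engine import SequenceKey
from .synthetic_cohort import (
    GroupSpec,
    SimulationConfig,
    TransitionModel,
    build_transition_model,
    simulate_cohort,
)


def neutral_model() -> TransitionModel:
    """The unstructured null: the uniform transition matrix over all states.

    Self-transitions equal 1/|states|, i.e. no persistence or switching
    structure whatsoever.  Used as the shared generating model in the
    validation studies so that any structure the pipeline detects is either a
    false positive (calibration) or exactly the planted boost (recovery).
    """
    states = len(DEFAULT_ALPHABET.states)
    return build_transition_model(1.0 / states)


def _cohort_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit cohort seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) >> np.uint32(1)]


@dataclass
class CalibrationResult:
    """Per-key rejection counts of each analysis step over null cohorts."""

    n_cohorts: int
    alpha_hypothesized: float
    alpha_exploratory: float
    rejections_replication: dict[SequenceKey, int]
    rejections_specificity: dict[SequenceKey, int]
    rejections_exploratory: dict[SequenceKey, int]

    def rates(self, step: str) -> dict[SequenceKey, float]:
        counts = getattr(self, f"rejections_{step}")
        return {k: c / self.n_cohorts for k, c in counts.items()}

    def overall_rate(self, step: str) -> float:
        counts = getattr(self, f"rejections_{step}")
        return sum(counts.values()) / (self.n_cohorts * len(counts))


def type_i_calibration(
    n_cohorts: int = 500,
    n_per_group: int = 20,
    seed: int = 20240501,
    miss_prob: float = 0.05,
    alpha_hypothesized: float = 0.014,
    run_exploratory: bool = True,
) -> CalibrationResult:
    """Null calibration: four groups drawn from one shared transition model.

    Every cohort has four groups of ``n_per_group`` subjects simulated from
    the same baseline dynamics, so any rejection is a false positive.  The
    replication and specificity steps run on the seven hypothesized keys at
    ``alpha_hypothesized``; the exploratory scan on the remaining 113 keys at
    .05/k.  Rejection = Wilcoxon significance (replication) or omnibus
    Kruskal–Wallis significance (specificity, exploratory).
    """
    model = neutral_model()
    groups = tuple(
        GroupSpec(name, n_per_group, model) for name in ("G1", "G2", "G3", "G4")
    )
    hyp = hypothesized_keys(DEFAULT_ALPHABET)
    policy = AlphaPolicy.fixed(alpha_hypothesized)
    rej_rep: dict[SequenceKey, int] = {k: 0 for k in hyp}
    rej_spec: dict[SequenceKey, int] = {k: 0 for k in hyp}
    rej_exp: dict[SequenceKey, int] = {}
    for cseed in _cohort_seeds(seed, n_cohorts):
        cohort = simulate_cohort(
            SimulationConfig(groups=groups, miss_prob=miss_prob, seed=cseed)
        )
        arf = prepare_arf(cohort)
        rep = run_replication_step(
            cohort, alpha_policy=policy, arf=arf, include_summary=False
        )
        for r in rep.results:
            rej_rep[r.key] += r.significant
        spec = run_specificity_step(
            cohort, alpha_policy=policy, arf=arf, include_summary=False
        )
        for r in spec.results:
            if r.statistic_name == "H_kw":
                rej_spec[r.key] += r.significant
        if run_exploratory:
            exp = run_exploratory_step(cohort, arf=arf, include_summary=False)
            for r in exp.results:
                if r.statistic_name == "H_kw":
                    rej_exp[r.key] = rej_exp.get(r.key, 0) + r.significant
    return CalibrationResult(
        n_cohorts=n_cohorts,
        alpha_hypothesized=alpha_hypothesized,
        alpha_exploratory=0.05 / DEFAULT_ALPHABET.k,
        rejections_replication=rej_rep,
        rejections_specificity=rej_spec,
        rejections_exploratory=rej_exp,
    )


@dataclass
class RecoveryResult:
    """Power study for a planted anxiety-persistence boost."""

    n_cohorts: int
    key: SequenceKey
    n_flagged: int
    n_boosted_highest_mean_rank: int

    @property
    def flag_rate(self) -> float:
        return self.n_flagged / self.n_cohorts

    @property
    def highest_rank_rate(self) -> float:
        return self.n_boosted_highest_mean_rank / self.n_cohorts


def effect_recovery(
    n_cohorts: int = 200,
    boost: float = 0.25,
    n_boosted: int = 40,
    n_control: int = 28,
    seed: int = 20240502,
    miss_prob: float = 0.05,
    alpha: float = 0.014,
) -> RecoveryResult:
    """Power of the replication step against a planted persistence effect.

    Both groups share the baseline dynamics except that the focal group's
    anxious self-transition is raised by ``boost``.  For each cohort the
    replication step runs on the hypothesized keys; recovery means
    persistence(anxious) is flagged significant, and additionally the
    boosted group has the highest mean ranked ARF for that key.
    """
    base = neutral_model()
    boosted = build_transition_model(
        1.0 / len(DEFAULT_ALPHABET.states), {("anxious", "anxious"): boost}
    )
    groups = (
        GroupSpec("BOOSTED", n_boosted, boosted),
        GroupSpec("CONTROL", n_control, base),
    )
    target = SequenceKey("anxious", "anxious")
    policy = AlphaPolicy.fixed(alpha)
    n_flagged = 0
    n_highest = 0
    for cseed in _cohort_seeds(seed, n_cohorts):
        cohort = simulate_cohort(
            SimulationConfig(groups=groups, miss_prob=miss_prob, seed=cseed)
        )
        arf = prepare_arf(cohort)
        rep = run_replication_step(
            cohort, alpha_policy=policy, arf=arf, include_summary=False
        )
        res = next(r for r in rep.results if r.key == target)
        n_flagged += res.significant
        col = arf.column(target)
        ranks = rank_across_subjects(arf.values[:, col])
        means = {
            g: float(ranks[arf.groups == g].mean()) for g in cohort.groups
        }
        n_highest += max(means, key=means.get) == "BOOSTED"
    return RecoveryResult(
        n_cohorts=n_cohorts,
        key=target,
        n_flagged=n_flagged,
        n_boosted_highest_mean_rank=n_highest,
    )
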