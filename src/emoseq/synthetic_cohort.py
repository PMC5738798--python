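"""Synthetic e-diary cohorts with known Markov emotion dynamics.

The generator reproduces the study design the analysis expects: each subject
is beeped every 15 min (±1 min jitter) during a waking window inside a 24-h
day, and answers each prompt with one state from the emotion alphabet plus the
no-emotion state.  States evolve as a first-order Markov chain at the prompt
cadence — the minimal generator for an analysis that only measures lag-1
structure.  Missed prompts are MCAR (independent per prompt); the sleep
window produces a single long gap that breaks sequence chains downstream.

Group-specific dynamics are expressed as *boosts*: additive increments to
selected transition probabilities on top of a common baseline row (uniform
mixing plus a self-transition floor), with off-target mass renormalised
proportionally.  Shipped presets sketch an HC-like model (high no-emotion and
happy occupancy) and clinical models with boosted negative-emotion
persistence and switching; they are illustrative mechanisms, not estimates of
any real sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alphabet import MISSING, NO_EMOTION, DEFAULT_ALPHABET, EmotionAlphabet
from .ediary_io import CohortDataset, PromptRecord, SubjectDiary

_ROW_TOL = 1e-12


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix over alphabet states + no_emotion."""

    alphabet: EmotionAlphabet
    P: np.ndarray
    pi0: np.ndarray

    def __post_init__(self) -> None:
        s = len(self.states)
        self.P = np.asarray(self.P, dtype=float)
        self.pi0 = np.asarray(self.pi0, dtype=float)
        if self.P.shape != (s, s):
            raise ValueError(f"P must be {s}x{s}, got {self.P.shape}")
        if (self.P < 0).any() or (self.pi0 < 0).any():
            raise ValueError("probabilities must be non-negative")
        if np.abs(self.P.sum(axis=1) - 1.0).max() > _ROW_TOL:
            raise ValueError("every row of P must sum to 1")
        if abs(self.pi0.sum() - 1.0) > _ROW_TOL:
            raise ValueError("pi0 must sum to 1")

    @property
    def states(self) -> tuple[str, ...]:
        return self.alphabet.states

    def state_index(self, state: str) -> int:
        return self.states.index(state)

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of P for eigenvalue 1, normalised to sum 1."""
        vals, vecs = np.linalg.eig(self.P.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass(frozen=True)
class PromptSchedule:
    """Beep schedule: every ``interval_mean`` ± ``interval_jitter`` minutes
    during the waking window of a 24-h (1440 min) day."""

    waking_start: float = 7 * 60.0
    waking_end: float = 23 * 60.0
    interval_mean: float = 15.0
    interval_jitter: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.waking_start < self.waking_end <= 1440.0):
            raise ValueError("need 0 <= waking_start < waking_end <= 1440")
        if self.interval_jitter < 0 or self.interval_jitter >= self.interval_mean:
            raise ValueError("jitter must be in [0, interval_mean)")

    def draw_times(self, rng: np.random.Generator) -> np.ndarray:
        times = [self.waking_start]
        while True:
            t = times[-1] + self.interval_mean + rng.uniform(
                -self.interval_jitter, self.interval_jitter
            )
            if t > self.waking_end:
                break
            times.append(t)
        return np.asarray(times)


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_subjects: int
    model: TransitionModel

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("each group needs at least one subject")


@dataclass(frozen=True)
class SimulationConfig:
    groups: tuple[GroupSpec, ...]
    schedule: PromptSchedule = PromptSchedule()
    miss_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("config needs at least one group")
        if not (0 <= self.miss_prob < 1):
            raise ValueError("miss_prob must be in [0, 1)")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")


def build_transition_model(
    base_persistence: float,
    boosts: Mapping[tuple[str, str], float] | None = None,
    alphabet: EmotionAlphabet = DEFAULT_ALPHABET,
    pi0: Sequence[float] | str = "stationary",
) -> TransitionModel:
    """Construct a transition model from a baseline plus targeted boosts.

    Every row starts with self-transition probability ``base_persistence``
    and the remaining mass spread uniformly over the other states.  Each
    boost ``(from_state, to_state) -> increment`` adds the increment to that
    entry and shrinks the row's non-boosted entries proportionally so the row
    still sums to 1.  ``pi0`` is the stationary distribution of the built
    matrix by default.
    """
    states = alphabet.states
    s = len(states)
    if not (0 <= base_persistence < 1) and s > 1:
        raise ValueError("base_persistence must be in [0, 1)")
    P = np.full((s, s), (1.0 - base_persistence) / (s - 1))
    np.fill_diagonal(P, base_persistence)

    boosts = dict(boosts or {})
    idx = {st: i for i, st in enumerate(states)}
    boosted_by_row: dict[int, list[int]] = {}
    for (a, b), inc in boosts.items():
        if a not in idx or b not in idx:
            raise ValueError(f"boost references unknown state: {(a, b)}")
        i, j = idx[a], idx[b]
        new = P[i, j] + inc
        if new < 0 or new > 1:
            raise ValueError(
                f"boost {(a, b)}:{inc:+g} drives entry to {new:.3g}, outside [0,1]"
            )
        P[i, j] = new
        boosted_by_row.setdefault(i, []).append(j)
    for i, cols in boosted_by_row.items():
        other = np.setdiff1d(np.arange(s), cols)
        target = 1.0 - P[i, cols].sum()
        if target < 0:
            raise ValueError(f"boosts on row {states[i]!r} exceed total probability 1")
        current = P[i, other].sum()
        if current <= 0 and target > 0:
            raise ValueError(f"row {states[i]!r} has no off-target mass to rescale")
        P[i, other] *= target / current if current > 0 else 0.0
    # clean any floating drift so the row-sum invariant holds to 1e-12
    P /= P.sum(axis=1, keepdims=True)

    model = TransitionModel(alphabet=alphabet, P=P, pi0=np.full(s, 1.0 / s))
    if isinstance(pi0, str):
        if pi0 != "stationary":
            raise ValueError(f"unknown pi0 spec {pi0!r}")
        model.pi0 = model.stationary_distribution()
    else:
        model.pi0 = np.asarray(pi0, dtype=float)
        if abs(model.pi0.sum() - 1.0) > _ROW_TOL or (model.pi0 < 0).any():
            raise ValueError("pi0 must be a probability vector")
    return model


def simulate_subject(
    model: TransitionModel,
    schedule: PromptSchedule,
    miss_prob: float,
    rng: np.random.Generator,
    subject_id: str = "S0",
    group_label: str = "G0",
) -> SubjectDiary:
    """Simulate one subject's diary: Markov states at jittered prompt times,
    each prompt independently missing with ``miss_prob`` (the underlying
    state still advances — the emotion exists whether or not it is reported).
    """
    times = schedule.draw_times(rng)
    n = times.size
    cum = np.cumsum(model.P, axis=1)
    states = np.empty(n, dtype=np.int64)
    u = rng.random(n)
    states[0] = np.searchsorted(np.cumsum(model.pi0), u[0], side="right")
    for t in range(1, n):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t], side="right")
    labels = model.states
    missed = rng.random(n) < miss_prob
    records = [
        PromptRecord(float(times[i]), MISSING if missed[i] else labels[states[i]])
        for i in range(n)
    ]
    return SubjectDiary(subject_id=subject_id, group_label=group_label, records=records)


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Simulate all groups of a cohort; fully determined by ``config.seed``.

    Subject-level seeds are spawned from the master seed via
    ``numpy.random.SeedSequence`` (PCG64 generators), so the same config
    always produces the same dataset.
    """
    alphabet = config.groups[0].model.alphabet
    for g in config.groups:
        if g.model.alphabet != alphabet:
            raise ValueError("all group models must share one alphabet")
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(sum(g.n_subjects for g in config.groups))
    diaries: list[SubjectDiary] = []
    i = 0
    for g in config.groups:
        for j in range(g.n_subjects):
            rng = np.random.Generator(np.random.PCG64(children[i]))
            diaries.append(
                simulate_subject(
                    g.model,
                    config.schedule,
                    config.miss_prob,
                    rng,
                    subject_id=f"{g.name}-{j + 1:03d}",
                    group_label=g.name,
                )
            )
            i += 1
    return CohortDataset(
        diaries=diaries,
        alphabet=alphabet,
        groups=tuple(g.name for g in config.groups),
    )


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

#: Baseline self-transition probability shared by all presets.  With 11
#: states this leaves moderate mixing while giving every emotion a realistic
#: chance to persist across one 15-min step.
BASE_PERSISTENCE = 0.25


def _hc_boosts() -> dict[tuple[str, str], float]:
    """Controls: frequent no-emotion and happy states, mild happy persistence."""
    b: dict[tuple[str, str], float] = {(NO_EMOTION, NO_EMOTION): 0.25}
    for e in DEFAULT_ALPHABET:
        b[(e, NO_EMOTION)] = 0.20
        if e != "happy":
            b[(e, "happy")] = 0.04
    b[(NO_EMOTION, "happy")] = 0.08
    b[("happy", "happy")] = 0.10
    return b


def _bpd_boosts() -> dict[tuple[str, str], float]:
    """BPD-like: sticky anxiety and sadness, anxious<->sad oscillation,
    anxious->angry switches; less time in the no-emotion state than HC."""
    b: dict[tuple[str, str], float] = {(NO_EMOTION, NO_EMOTION): 0.10}
    for e in DEFAULT_ALPHABET:
        b[(e, NO_EMOTION)] = 0.06
    b[("anxious", "anxious")] = 0.22
    b[("sad", "sad")] = 0.18
    b[("anxious", "sad")] = 0.10
    b[("sad", "anxious")] = 0.10
    b[("anxious", "angry")] = 0.08
    b[(NO_EMOTION, "anxious")] = 0.06
    b[(NO_EMOTION, "sad")] = 0.05
    return b


def _ptsd_boosts() -> dict[tuple[str, str], float]:
    """PTSD-like: sticky anxiety and anxious->sad switches, intermediate
    no-emotion occupancy."""
    b: dict[tuple[str, str], float] = {(NO_EMOTION, NO_EMOTION): 0.15}
    for e in DEFAULT_ALPHABET:
        b[(e, NO_EMOTION)] = 0.10
    b[("anxious", "anxious")] = 0.20
    b[("anxious", "sad")] = 0.08
    b[(NO_EMOTION, "anxious")] = 0.07
    return b


def _bn_boosts() -> dict[tuple[str, str], float]:
    """BN-like: anger->disgust and disgust->unspecific switches."""
    b: dict[tuple[str, str], float] = {(NO_EMOTION, NO_EMOTION): 0.15}
    for e in DEFAULT_ALPHABET:
        b[(e, NO_EMOTION)] = 0.10
    b[("angry", "disgust")] = 0.15
    b[("disgust", "unspecific")] = 0.12
    b[("disgust", "disgust")] = 0.08
    b[(NO_EMOTION, "disgust")] = 0.03
    return b


_PRESETS = {
    "hc": _hc_boosts,
    "bpd": _bpd_boosts,
    "ptsd": _ptsd_boosts,
    "bn": _bn_boosts,
}


def preset_model(name: str, alphabet: EmotionAlphabet = DEFAULT_ALPHABET) -> TransitionModel:
    """One of the shipped illustrative group models: hc, bpd, ptsd, bn."""
    try:
        boosts = _PRESETS[name.lower()]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return build_transition_model(BASE_PERSISTENCE, boosts, alphabet=alphabet)


def default_study_config(seed: int = 0, miss_prob: float = 0.05) -> SimulationConfig:
    """The default four-group cohort: BPD n=43, PTSD n=28, BN n=20, HC n=28
    (119 subjects), each with its preset dynamics."""
    return SimulationConfig(
        groups=(
            GroupSpec("BPD", 43, preset_model("bpd")),
            GroupSpec("PTSD", 28, preset_model("ptsd")),
            GroupSpec("BN", 20, preset_model("bn")),
            GroupSpec("HC", 28, preset_model("hc")),
        ),
        miss_prob=miss_prob,
        seed=seed,
    )
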