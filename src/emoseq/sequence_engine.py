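"""Sequence taxonomy, pair extraction, counting, and the adjusted relative frequency.

An *emotion sequence* is the ordered pair of responses at two successive
prompts, (E1 -> E2).  With k emotion categories plus the no-emotion state there
are (k+1)^2 ordered pairs; the (no_emotion -> no_emotion) pair is not a
sequence, leaving k(k+2) sequence keys, each of exactly one type:

* **activation**      no_emotion -> emotion
* **persistence**     same emotion twice
* **switch**          one emotion -> a different emotion
* **down-regulation** emotion -> no_emotion

For k = 10 this yields the canonical 120 sequences.

Because the raw count of a sequence scales with how often the subject reports
its two contributing emotions at all, each count is normalised per subject to
the *adjusted relative frequency*

    ARF(E1 -> E2) = f_S(E1 -> E2) / (f_S(E1) * f_S(E2) + 1)

where f_S(E) is the subject's number of prompts reporting E, and the +1 in the
denominator guards against division by zero for never-reported emotions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .alphabet import MISSING, NO_EMOTION, EmotionAlphabet

if TYPE_CHECKING:  # pragma: no cover
    from .ediary_io import CohortDataset, SubjectDiary

#: Chain-breaking gap between two prompts, in minutes.  The schedule is
#: 15 +/- 1 min, so a gap above 20 min means at least one prompt was skipped
#: (or the subject slept) and the two reports are no longer "successive".
DEFAULT_MAX_GAP = 20.0


class SequenceType(str, enum.Enum):
    ACTIVATION = "activation"
    PERSISTENCE = "persistence"
    SWITCH = "switch"
    DOWN_REGULATION = "down_regulation"


def classify_sequence(e1: str, e2: str) -> SequenceType:
    """Map an ordered response pair to its sequence type.

    Raises
    ------
    ValueError
        If both endpoints are ``no_emotion`` — that pair is not a sequence.
    """
    if e1 == NO_EMOTION and e2 == NO_EMOTION:
        raise ValueError("(no_emotion, no_emotion) is not an emotion sequence")
    if e1 == NO_EMOTION:
        return SequenceType.ACTIVATION
    if e2 == NO_EMOTION:
        return SequenceType.DOWN_REGULATION
    if e1 == e2:
        return SequenceType.PERSISTENCE
    return SequenceType.SWITCH


@dataclass(frozen=True, order=True)
class SequenceKey:
    """One ordered pair (e1 -> e2) over the alphabet plus the no-emotion state."""

    e1: str
    e2: str

    def __post_init__(self) -> None:
        if self.e1 == NO_EMOTION and self.e2 == NO_EMOTION:
            raise ValueError("(no_emotion, no_emotion) is not a SequenceKey")

    @property
    def seq_type(self) -> SequenceType:
        return classify_sequence(self.e1, self.e2)

    def __str__(self) -> str:  # e.g. "anxious->sad"
        return f"{self.e1}->{self.e2}"


@lru_cache(maxsize=32)
def _enumerate_cached(alphabet: EmotionAlphabet) -> tuple[SequenceKey, ...]:
    cats = alphabet.categories
    keys: list[SequenceKey] = [SequenceKey(NO_EMOTION, e) for e in cats]
    keys += [SequenceKey(e, e) for e in cats]
    keys += [SequenceKey(a, b) for a in cats for b in cats if a != b]
    keys += [SequenceKey(e, NO_EMOTION) for e in cats]
    return tuple(keys)


def enumerate_sequences(alphabet: EmotionAlphabet) -> list[SequenceKey]:
    """All k(k+2) sequence keys in a stable, documented order.

    Order: k activations (alphabet order), k persistences, k(k-1) switches
    (e1-major, e2-minor, both alphabet order), k down-regulations.
    """
    return list(_enumerate_cached(alphabet))


@dataclass(frozen=True)
class PairObservation:
    """One valid consecutive-prompt pair for one subject."""

    subject_id: str
    t1: float
    t2: float
    key: SequenceKey


@dataclass
class SequenceCountTable:
    """Per-subject sequence counts and single-state marginals.

    ``marginals`` maps every alphabet category *and* ``no_emotion`` to the
    number of non-missing prompts at which it was reported over the whole
    diary.  ``n_none_none`` counts excluded (no_emotion -> no_emotion) pairs;
    conservation holds: sum(counts) + n_none_none == n_pairs.
    """

    subject_id: str
    alphabet: EmotionAlphabet
    counts: dict[SequenceKey, int]
    marginals: dict[str, int]
    n_pairs: int
    n_none_none: int


@dataclass
class ARFTable:
    """Per-subject adjusted relative frequencies, one per sequence key."""

    subject_id: str
    alphabet: EmotionAlphabet
    arf: dict[SequenceKey, float]


def extract_pairs(
    diary: "SubjectDiary",
    max_gap: float = DEFAULT_MAX_GAP,
) -> tuple[list[PairObservation], int]:
    """Form sequence pairs from consecutive prompts of one diary.

    A pair is formed from records i, i+1 iff neither response is missing and
    the time gap is at most ``max_gap`` minutes (a longer gap — a missed
    prompt or the sleep window — breaks the chain).  Pairs where both
    responses are ``no_emotion`` are tallied separately, not emitted.

    Returns
    -------
    (pairs, n_none_none)
    """
    pairs: list[PairObservation] = []
    n_none_none = 0
    recs = diary.records
    for r1, r2 in zip(recs, recs[1:]):
        if r1.response == MISSING or r2.response == MISSING:
            continue
        if (r2.timestamp - r1.timestamp) > max_gap:
            continue
        if r1.response == NO_EMOTION and r2.response == NO_EMOTION:
            n_none_none += 1
            continue
        pairs.append(
            PairObservation(
                subject_id=diary.subject_id,
                t1=r1.timestamp,
                t2=r2.timestamp,
                key=SequenceKey(r1.response, r2.response),
            )
        )
    return pairs, n_none_none


def count_sequences(
    diary: "SubjectDiary",
    alphabet: EmotionAlphabet,
    max_gap: float = DEFAULT_MAX_GAP,
) -> SequenceCountTable:
    """Count every sequence key (zeros included) and all state marginals."""
    pairs, n_none_none = extract_pairs(diary, max_gap=max_gap)
    counts: dict[SequenceKey, int] = {k: 0 for k in enumerate_sequences(alphabet)}
    for p in pairs:
        counts[p.key] += 1
    marginals = {state: 0 for state in alphabet.states}
    for rec in diary.records:
        if rec.response != MISSING:
            marginals[rec.response] += 1
    return SequenceCountTable(
        subject_id=diary.subject_id,
        alphabet=alphabet,
        counts=counts,
        marginals=marginals,
        n_pairs=len(pairs) + n_none_none,
        n_none_none=n_none_none,
    )


def compute_arf(
    table: SequenceCountTable,
    denominator: str = "product",
) -> ARFTable:
    """Adjusted relative frequency per sequence key for one subject.

    ARF(E1->E2) = f_S(E1->E2) / (f_S(E1) * f_S(E2) + 1).

    For activation and down-regulation keys one endpoint is the no-emotion
    state; its marginal is the subject's count of ``no_emotion`` responses, so
    the formula is applied uniformly over all keys (``denominator="product"``,
    the default).  With ``denominator="emotion_only"`` those keys instead use
    f_S(emotion endpoint) + 1, i.e. the no-emotion endpoint is dropped from
    the adjustment.
    """
    if denominator not in ("product", "emotion_only"):
        raise ValueError(f"unknown denominator mode: {denominator!r}")
    arf: dict[SequenceKey, float] = {}
    m = table.marginals
    for key, f in table.counts.items():
        if denominator == "emotion_only" and NO_EMOTION in (key.e1, key.e2):
            emo = key.e2 if key.e1 == NO_EMOTION else key.e1
            denom = m[emo] + 1
        else:
            denom = m[key.e1] * m[key.e2] + 1
        arf[key] = f / denom
    return ARFTable(subject_id=table.subject_id, alphabet=table.alphabet, arf=arf)


def cohort_count_tables(
    dataset: "CohortDataset",
    max_gap: float = DEFAULT_MAX_GAP,
) -> list[SequenceCountTable]:
    """Count tables for every diary of a cohort."""
    return [count_sequences(d, dataset.alphabet, max_gap=max_gap) for d in dataset.diaries]


def cohort_arf_frame(
    dataset: "CohortDataset",
    max_gap: float = DEFAULT_MAX_GAP,
    denominator: str = "product",
) -> pd.DataFrame:
    """Tidy per-subject count/ARF table for a whole cohort.

    Columns: subject_id, group, e1, e2, seq_type, count, arf.  One row per
    subject and sequence key, in the stable enumeration order.
    """
    keys = enumerate_sequences(dataset.alphabet)
    rows: list[tuple] = []
    for diary in dataset.diaries:
        table = count_sequences(diary, dataset.alphabet, max_gap=max_gap)
        arfs = compute_arf(table, denominator=denominator)
        for key in keys:
            rows.append(
                (
                    diary.subject_id,
                    diary.group_label,
                    key.e1,
                    key.e2,
                    key.seq_type.value,
                    table.counts[key],
                    arfs.arf[key],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "group", "e1", "e2", "seq_type", "count", "arf"],
    )


def arf_matrix(
    dataset: "CohortDataset",
    max_gap: float = DEFAULT_MAX_GAP,
    denominator: str = "product",
) -> tuple[np.ndarray, list[SequenceKey], list[str], list[str]]:
    """ARF values as a dense (n_subjects, n_keys) array.

    Returns ``(values, keys, subject_ids, group_labels)``; faster than the
    tidy frame for simulation studies that only need the numbers.
    """
    keys = enumerate_sequences(dataset.alphabet)
    values = np.empty((len(dataset.diaries), len(keys)))
    subjects: list[str] = []
    groups: list[str] = []
    for i, diary in enumerate(dataset.diaries):
        table = count_sequences(diary, dataset.alphabet, max_gap=max_gap)
        arfs = compute_arf(table, denominator=denominator)
        values[i] = [arfs.arf[k] for k in keys]
        subjects.append(diary.subject_id)
        groups.append(diary.group_label)
    return values, keys, subjects, groups
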