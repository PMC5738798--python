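"""Reading, validating, and writing prompt-level e-diary tables.

The on-disk format is a UTF-8 CSV with a mandatory header and columns
``subject_id`` (string), ``group`` (string), ``timestamp_min`` (float,
minutes since the subject's study start), ``response`` (a token from the
configured alphabet, or ``no_emotion``, or ``missing``).  One row is one
prompt; exactly one response per prompt (multi-select is rejected at the
vocabulary level because a combined token is simply not in the alphabet).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alphabet import MISSING, NO_EMOTION, EmotionAlphabet

_COLUMNS = ["subject_id", "group", "timestamp_min", "response"]


class ValidationError(ValueError):
    """An input table violated the diary format contract."""


@dataclass(frozen=True)
class PromptRecord:
    """One timestamped categorical emotion report by one subject."""

    timestamp: float
    response: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.timestamp) and self.timestamp >= 0):
            raise ValidationError(
                f"timestamp must be finite and >= 0, got {self.timestamp!r}"
            )


@dataclass
class SubjectDiary:
    """The ordered prompt series of one subject."""

    subject_id: str
    group_label: str
    records: list[PromptRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ts = [r.timestamp for r in self.records]
        for t1, t2 in zip(ts, ts[1:]):
            if t2 <= t1:
                raise ValidationError(
                    f"subject {self.subject_id!r}: records must be strictly "
                    f"increasing in time (got {t1} then {t2})"
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CohortDataset:
    """A collection of subject diaries with their alphabet and group names."""

    diaries: list[SubjectDiary]
    alphabet: EmotionAlphabet
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        known = set(self.groups)
        for d in self.diaries:
            if d.group_label not in known:
                raise ValidationError(
                    f"subject {d.subject_id!r} has unknown group {d.group_label!r}; "
                    f"known groups: {sorted(known)}"
                )
        ids = [d.subject_id for d in self.diaries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject_id in cohort")

    @property
    def n_subjects(self) -> int:
        return len(self.diaries)

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in self.groups}
        for d in self.diaries:
            sizes[d.group_label] += 1
        return sizes

    def require_groups(self, min_groups: int = 1, min_per_group: int = 1) -> None:
        """Validate the cohort for an analysis entry point."""
        sizes = {g: n for g, n in self.group_sizes().items() if n > 0}
        if len(sizes) < min_groups:
            raise ValidationError(
                f"analysis needs at least {min_groups} non-empty groups, "
                f"found {len(sizes)}"
            )
        small = {g: n for g, n in sizes.items() if n < min_per_group}
        if small:
            raise ValidationError(
                f"analysis needs at least {min_per_group} subjects per group; "
                f"too small: {small}"
            )


def _valid_responses(alphabet: EmotionAlphabet) -> frozenset[str]:
    return frozenset(alphabet.categories) | {NO_EMOTION, MISSING}


def read_diary_table(
    path: str | Path,
    alphabet: EmotionAlphabet,
    groups: Sequence[str],
) -> CohortDataset:
    """Read and validate a prompt-level diary CSV.

    Rows with a ``missing`` response are retained — they break pair chains
    downstream, which is the point of recording them.  Records are sorted per
    subject by timestamp; duplicate timestamps for one subject are an error.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            dtype={"subject_id": str, "group": str, "response": str},
            float_precision="round_trip",
        )
    except FileNotFoundError:
        raise
    missing_cols = [c for c in _COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing required columns {missing_cols}")

    valid = _valid_responses(alphabet)
    known_groups = set(groups)
    ts = pd.to_numeric(frame["timestamp_min"], errors="coerce")
    diaries: list[SubjectDiary] = []
    for (sid, grp), sub in frame.groupby(["subject_id", "group"], sort=False):
        if grp not in known_groups:
            raise ValidationError(
                f"{path}: subject {sid!r} has unknown group {grp!r}"
            )
        sub_ts = ts.loc[sub.index]
        if sub_ts.isna().any():
            row = int(sub.index[sub_ts.isna()][0]) + 2  # 1-based incl. header
            raise ValidationError(
                f"{path}: non-numeric timestamp_min at row {row} (subject {sid!r})"
            )
        for idx, resp in sub["response"].items():
            if resp not in valid:
                raise ValidationError(
                    f"{path}: unknown response {resp!r} at row {int(idx) + 2} "
                    f"(subject {sid!r}); valid: {sorted(valid)}"
                )
        order = sub_ts.to_numpy().argsort(kind="stable")
        times = sub_ts.to_numpy()[order]
        resps = sub["response"].to_numpy()[order]
        if len(times) > 1 and (times[1:] <= times[:-1]).any():
            raise ValidationError(
                f"{path}: duplicate timestamps for subject {sid!r}"
            )
        diaries.append(
            SubjectDiary(
                subject_id=str(sid),
                group_label=str(grp),
                records=[PromptRecord(float(t), str(r)) for t, r in zip(times, resps)],
            )
        )
    return CohortDataset(diaries=diaries, alphabet=alphabet, groups=tuple(groups))


def write_diary_table(dataset: CohortDataset, path: str | Path) -> None:
    """Write a cohort to the diary CSV format (round-trips with the reader)."""
    rows = [
        (d.subject_id, d.group_label, r.timestamp, r.response)
        for d in dataset.diaries
        for r in d.records
    ]
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    # %.17g guarantees the float minutes survive the text round-trip exactly
    frame.to_csv(path, index=False, float_format="%.17g")
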