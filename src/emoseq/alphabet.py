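"""The emotion response vocabulary.

An e-diary prompt asks "Do you feel any of the following emotions right now?"
and records exactly one token: a named emotion category, ``no_emotion`` (no
emotion perceived), or ``missing`` (the prompt was not answered).  The named
categories form the *emotion alphabet*; ``no_emotion`` and ``missing`` are
reserved states and never alphabet members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Reserved response token: the subject reported perceiving no emotion.
NO_EMOTION = "no_emotion"

#: Reserved response token: the prompt was missed / unanswered.
MISSING = "missing"

_RESERVED = frozenset({NO_EMOTION, MISSING})


@dataclass(frozen=True)
class EmotionAlphabet:
    """Ordered set of k distinct emotion category labels.

    Parameters
    ----------
    categories
        Ordered emotion labels.  Must be distinct, non-empty, and must not
        contain the reserved ``no_emotion`` / ``missing`` tokens.
    """

    categories: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        cats = tuple(self.categories)
        object.__setattr__(self, "categories", cats)
        if len(cats) < 1:
            raise ValueError("emotion alphabet needs at least one category")
        if len(set(cats)) != len(cats):
            raise ValueError(f"duplicate emotion labels: {cats}")
        bad = _RESERVED.intersection(cats)
        if bad:
            raise ValueError(f"reserved tokens cannot be alphabet members: {sorted(bad)}")

    @property
    def k(self) -> int:
        """Number of emotion categories."""
        return len(self.categories)

    @property
    def states(self) -> tuple[str, ...]:
        """Categories plus the no-emotion state (valid non-missing responses)."""
        return self.categories + (NO_EMOTION,)

    def __contains__(self, label: object) -> bool:
        return label in self.categories

    def __iter__(self):
        return iter(self.categories)

    def index(self, label: str) -> int:
        return self.categories.index(label)


#: The 10-category response list used throughout: nine named emotions plus
#: "unspecific" (an emotion the subject cannot name).
DEFAULT_ALPHABET = EmotionAlphabet(
    (
        "happy",
        "anxious",
        "angry",
        "shame",
        "disgust",
        "sad",
        "guilt",
        "interest",
        "envy_jealousy",
        "unspecific",
    )
)
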