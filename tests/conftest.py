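import numpy as np
import pytest

from emoseq import DEFAULT_ALPHABET, CohortDataset, PromptRecord, SubjectDiary


def make_diary(responses, subject_id="S1", group="G1", spacing=15.0, start=0.0):
    """Build a diary from a response list at fixed prompt spacing."""
    records = [
        PromptRecord(start + i * spacing, resp) for i, resp in enumerate(responses)
    ]
    return SubjectDiary(subject_id=subject_id, group_label=group, records=records)


def random_diary(rng, n_prompts=50, miss_prob=0.1, subject_id="S1", group="G1"):
    """Random diary over the default alphabet + no_emotion + missing, with
    occasional long gaps that break pair chains."""
    states = list(DEFAULT_ALPHABET.states) + ["missing"]
    responses = [states[rng.integers(len(states))] for _ in range(n_prompts)]
    responses = [
        "missing" if rng.random() < miss_prob else r for r in responses
    ]
    t = 0.0
    records = []
    for r in responses:
        records.append(PromptRecord(t, r))
        t += 15.0 + rng.uniform(-1, 1)
        if rng.random() < 0.05:  # skipped prompt: gap > max_gap
            t += 30.0
    return SubjectDiary(subject_id=subject_id, group_label=group, records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def alphabet():
    return DEFAULT_ALPHABET


def make_cohort(diaries, groups):
    return CohortDataset(diaries=list(diaries), alphabet=DEFAULT_ALPHABET, groups=tuple(groups))
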