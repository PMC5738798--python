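"""Rank-based group comparison of adjusted relative frequencies.

The analysis protocol has three steps, all operating on per-subject ARF values
for one sequence key at a time:

1. **Replication** — Wilcoxon rank-sum contrasts between a focal clinical
   group and healthy controls for a small set of hypothesized sequences, at a
   Bonferroni-reduced alpha (default .014).
2. **Specificity** — Kruskal–Wallis omnibus tests across all groups for the
   same sequences; Dunn–Bonferroni post hoc contrasts only when the omnibus
   rejects (gatekeeping), again at the reduced alpha.
3. **Exploratory scan** — Kruskal–Wallis (plus gated Dunn post hocs) over all
   remaining sequences, at alpha = .05 / k where k is the number of emotion
   categories (.005 for k = 10).

ARFs are heavily tied at zero (most sequences never occur for most subjects),
so every procedure uses mid-ranks with tie-corrected variances.  All tests are
two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alphabet import NO_EMOTION, EmotionAlphabet
from .sequence_engine import (
    DEFAULT_MAX_GAP,
    SequenceKey,
    arf_matrix,
    enumerate_sequences,
)

if TYPE_CHECKING:  # pragma: no cover
    from .ediary_io import CohortDataset

#: Pooled sample size at or below which the Wilcoxon p-value is computed by
#: exhaustive enumeration of rank subsets instead of the normal approximation.
EXACT_WILCOXON_MAX_N = 12


# --------------------------------------------------------------------------
# alpha policies
# --------------------------------------------------------------------------

def bonferroni_alpha(base: float, m: int) -> float:
    """Bonferroni-reduced significance level base/m."""
    if not (0 < base < 1):
        raise ValueError(f"base alpha must be in (0,1), got {base}")
    if m < 1:
        raise ValueError(f"divisor must be a positive integer, got {m}")
    return base / m


@dataclass(frozen=True)
class AlphaPolicy:
    """Significance-level policy: a fixed level, or base/divisor.

    The replication/specificity steps default to the fixed printed level .014
    (which is deliberately *not* .05/7; both are expressible here).  The
    exploratory step divides .05 by the number of emotion categories.
    """

    base_alpha: float = 0.05
    mode: str = "fixed"  # "fixed" | "divide_by_m"
    divisor: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "divide_by_m"):
            raise ValueError(f"unknown alpha mode {self.mode!r}")
        if not (0 < self.base_alpha < 1):
            raise ValueError(f"base alpha must be in (0,1), got {self.base_alpha}")
        if self.divisor < 1:
            raise ValueError("divisor must be >= 1")

    @property
    def alpha(self) -> float:
        if self.mode == "divide_by_m":
            return bonferroni_alpha(self.base_alpha, self.divisor)
        return self.base_alpha

    @classmethod
    def fixed(cls, alpha: float) -> "AlphaPolicy":
        return cls(base_alpha=alpha, mode="fixed")

    @classmethod
    def divide(cls, base: float, m: int) -> "AlphaPolicy":
        return cls(base_alpha=base, mode="divide_by_m", divisor=m)


REPLICATION_ALPHA = AlphaPolicy.fixed(0.014)


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class TestResult:
    """One statistical comparison.

    ``statistic_name`` is one of ``W_ranksum`` (rank-sum of the first group;
    the Mann–Whitney U is carried in ``extra["U"]``), ``H_kw`` or ``z_dunn``.
    """

    key: SequenceKey | None
    comparison: str
    statistic_name: str
    statistic: float
    p_value: float
    alpha: float
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class ComparisonReport:
    """All test results of one analysis step plus mean-rank summaries."""

    step: str
    results: list[TestResult]
    mean_ranks: pd.DataFrame  # columns: key, e1, e2, group, n, mean_rank, se

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "step": self.step,
                    "e1": r.key.e1 if r.key else "",
                    "e2": r.key.e2 if r.key else "",
                    "seq_type": r.key.seq_type.value if r.key else "",
                    "comparison": r.comparison,
                    "statistic_name": r.statistic_name,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "alpha": r.alpha,
                    "significant": r.significant,
                    "degenerate": r.degenerate,
                    **{f"extra_{k}": v for k, v in r.extra.items()},
                }
            )
        return pd.DataFrame(rows)

    def significant_results(self) -> list[TestResult]:
        return [r for r in self.results if r.significant]


# --------------------------------------------------------------------------
# rank machinery and test kernels
# --------------------------------------------------------------------------

def rank_across_subjects(values: Sequence[float]) -> np.ndarray:
    """Pooled mid-ranks (average ranks for ties) of one value per subject."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("ranking needs at least 2 subjects")
    return sps.rankdata(arr, method="average")


def _tie_term(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided exact p for the rank-sum of the first group.

    Enumerates all C(N, n_a) assignments of the pooled mid-ranks to group A
    and doubles the smaller tail (capped at 1) — valid with ties because the
    mid-ranks themselves are permuted.
    """
    total = 0
    le = 0
    ge = 0
    eps = 1e-9
    for subset in itertools.combinations(range(len(ranks)), n_a):
        w = float(ranks[list(subset)].sum())
        total += 1
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def wilcoxon_rank_sum(
    group_a: Sequence[float],
    group_b: Sequence[float],
    key: SequenceKey | None = None,
    comparison: str = "A vs B",
    alpha: float = 0.05,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test with mid-ranks.

    Reports the rank-sum W of ``group_a`` as the statistic and the
    Mann–Whitney U in ``extra["U"]``.  The p-value is exact (exhaustive
    enumeration over rank subsets) when n_a + n_b <= 12, otherwise from the
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled, method="average")
    w = float(ranks[:n_a].sum())
    u = w - n_a * (n_a + 1) / 2.0

    degenerate = bool(np.all(pooled == pooled[0]))
    if degenerate:
        p = 1.0
    elif n <= EXACT_WILCOXON_MAX_N:
        p = _exact_ranksum_p(ranks, n_a, w)
    else:
        tie = _tie_term(ranks)
        var_u = n_a * n_b / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        mu_u = n_a * n_b / 2.0
        diff = u - mu_u
        # continuity correction toward the mean
        cc = min(0.5, abs(diff))
        z = (diff - math.copysign(cc, diff)) / math.sqrt(var_u) if diff != 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(
        key=key,
        comparison=comparison,
        statistic_name="W_ranksum",
        statistic=w,
        p_value=min(p, 1.0),
        alpha=alpha,
        degenerate=degenerate,
        extra={"U": u, "n_a": n_a, "n_b": n_b},
    )


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]],
    key: SequenceKey | None = None,
    alpha: float = 0.05,
) -> TestResult:
    """Kruskal–Wallis H test (mid-ranks, tie-corrected) across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    degenerate = bool(np.all(pooled == pooled[0]))
    if degenerate:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return TestResult(
        key=key,
        comparison="omnibus(" + ", ".join(groups) + ")",
        statistic_name="H_kw",
        statistic=float(h),
        p_value=float(min(p, 1.0)),
        alpha=alpha,
        degenerate=degenerate,
        extra={"df": len(groups) - 1},
    )


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    key: SequenceKey | None = None,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> list[TestResult]:
    """Dunn's pairwise post hoc z tests after a Kruskal–Wallis omnibus.

    z = (mean pooled rank of group i - group j) / SE with the tie-corrected
    standard error SE = sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)),
    T = sum(t^3 - t) over tie groups.  Bonferroni adjustment multiplies each
    p by the number of pairwise contrasts, capped at 1.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if len(groups) < 2:
        raise ValueError("post hoc needs at least 2 groups")
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled, method="average")
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = [
        float(ranks[bounds[i]:bounds[i + 1]].mean()) for i in range(len(names))
    ]
    tie = _tie_term(ranks)
    var_base = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    pairs = list(itertools.combinations(range(len(names)), 2))
    m = len(pairs)
    degenerate_all = bool(np.all(pooled == pooled[0]))
    out: list[TestResult] = []
    for i, j in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0.0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = float(2.0 * sps.norm.sf(abs(z)))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        out.append(
            TestResult(
                key=key,
                comparison=f"{names[i]} vs {names[j]}",
                statistic_name="z_dunn",
                statistic=float(z),
                p_value=p,
                alpha=alpha,
                degenerate=degenerate_all,
                extra={
                    "mean_rank_a": mean_ranks[i],
                    "mean_rank_b": mean_ranks[j],
                    "adjust": adjust,
                    "n_contrasts": m,
                },
            )
        )
    return out


# --------------------------------------------------------------------------
# the three pipeline steps
# --------------------------------------------------------------------------

def hypothesized_keys(alphabet: EmotionAlphabet | None = None) -> list[SequenceKey]:
    """The seven a-priori dysregulation sequences tested in the replication
    step: reduced activation of happy and interest, elevated persistence of
    anxious and sad, and elevated switches sad->anxious, anxious->angry,
    anxious->sad."""
    return [
        SequenceKey(NO_EMOTION, "happy"),
        SequenceKey(NO_EMOTION, "interest"),
        SequenceKey("anxious", "anxious"),
        SequenceKey("sad", "sad"),
        SequenceKey("sad", "anxious"),
        SequenceKey("anxious", "angry"),
        SequenceKey("anxious", "sad"),
    ]


@dataclass
class ARFBundle:
    """Precomputed per-subject ARF matrix for a cohort.

    Lets simulation studies run all three analysis steps without recounting
    the cohort for each step.
    """

    values: np.ndarray  # (n_subjects, n_keys)
    keys: list[SequenceKey]
    groups: np.ndarray  # group label per subject
    group_names: tuple[str, ...]

    def column(self, key: SequenceKey) -> int:
        return self.keys.index(key)


def prepare_arf(
    dataset: "CohortDataset",
    max_gap: float = DEFAULT_MAX_GAP,
    denominator: str = "product",
) -> ARFBundle:
    """Count a cohort once and package its ARF matrix for the three steps."""
    values, keys, _, groups = arf_matrix(
        dataset, max_gap=max_gap, denominator=denominator
    )
    return ARFBundle(
        values=values,
        keys=keys,
        groups=np.asarray(groups),
        group_names=dataset.groups,
    )


def _arf_by_key(
    dataset: "CohortDataset",
    max_gap: float,
    denominator: str,
    arf: ARFBundle | None = None,
) -> tuple[np.ndarray, list[SequenceKey], np.ndarray]:
    if arf is not None:
        return arf.values, arf.keys, arf.groups
    bundle = prepare_arf(dataset, max_gap=max_gap, denominator=denominator)
    return bundle.values, bundle.keys, bundle.groups


def _group_values(
    values: np.ndarray, groups: np.ndarray, col: int, names: Iterable[str]
) -> dict[str, np.ndarray]:
    return {g: values[groups == g, col] for g in names}


def summarize_mean_ranks(
    dataset: "CohortDataset",
    keys: Sequence[SequenceKey] | None = None,
    max_gap: float = DEFAULT_MAX_GAP,
    denominator: str = "product",
    arf: ARFBundle | None = None,
) -> pd.DataFrame:
    """Per-group mean ranked ARF with standard errors, per sequence key.

    For each key all subjects are pooled and mid-ranked; the summary reports
    each group's mean rank and SE = sd/sqrt(n_g).  The grand mean of the
    pooled ranks is always (N+1)/2.
    """
    values, all_keys, groups = _arf_by_key(dataset, max_gap, denominator, arf)
    if keys is None:
        keys = all_keys
    index = {k: i for i, k in enumerate(all_keys)}
    rows = []
    for key in keys:
        col = index[key]
        ranks = rank_across_subjects(values[:, col])
        for g in dataset.groups:
            r = ranks[groups == g]
            if r.size == 0:
                continue
            se = float(r.std(ddof=1) / math.sqrt(r.size)) if r.size > 1 else float("nan")
            rows.append(
                {
                    "key": str(key),
                    "e1": key.e1,
                    "e2": key.e2,
                    "seq_type": key.seq_type.value,
                    "group": g,
                    "n": int(r.size),
                    "mean_rank": float(r.mean()),
                    "se": se,
                }
            )
    return pd.DataFrame(rows)


def run_replication_step(
    dataset: "CohortDataset",
    keys: Sequence[SequenceKey] | None = None,
    alpha_policy: AlphaPolicy = REPLICATION_ALPHA,
    group_a: str | None = None,
    group_b: str | None = None,
    max_gap: float = DEFAULT_MAX_GAP,
    denominator: str = "product",
    arf: ARFBundle | None = None,
    include_summary: bool = True,
) -> ComparisonReport:
    """Step 1: Wilcoxon rank-sum contrasts (focal group vs controls) for the
    hypothesized sequences.

    ``group_a`` defaults to the first configured group (the focal clinical
    group), ``group_b`` to the last (the control group).
    """
    dataset.require_groups(min_groups=2, min_per_group=2)
    group_a = group_a if group_a is not None else dataset.groups[0]
    group_b = group_b if group_b is not None else dataset.groups[-1]
    sizes = dataset.group_sizes()
    for g in (group_a, group_b):
        if sizes.get(g, 0) < 2:
            raise ValueError(f"replication step needs >= 2 subjects in group {g!r}")
    if keys is None:
        keys = hypothesized_keys(dataset.alphabet)
    alpha = alpha_policy.alpha
    values, all_keys, groups = _arf_by_key(dataset, max_gap, denominator, arf)
    index = {k: i for i, k in enumerate(all_keys)}
    results = []
    for key in keys:
        col = index[key]
        results.append(
            wilcoxon_rank_sum(
                values[groups == group_a, col],
                values[groups == group_b, col],
                key=key,
                comparison=f"{group_a} vs {group_b}",
                alpha=alpha,
            )
        )
    if include_summary:
        summary = summarize_mean_ranks(
            dataset, keys, max_gap=max_gap, denominator=denominator, arf=arf
        )
    else:
        summary = pd.DataFrame()
    return ComparisonReport(step="replication", results=results, mean_ranks=summary)


def _omnibus_with_posthoc(
    step: str,
    dataset: "CohortDataset",
    keys: Sequence[SequenceKey],
    alpha: float,
    max_gap: float,
    denominator: str,
    posthoc_gate: bool,
    arf: ARFBundle | None = None,
    include_summary: bool = True,
) -> ComparisonReport:
    dataset.require_groups(min_groups=3, min_per_group=2)
    values, all_keys, groups = _arf_by_key(dataset, max_gap, denominator, arf)
    index = {k: i for i, k in enumerate(all_keys)}
    results: list[TestResult] = []
    for key in keys:
        col = index[key]
        by_group = _group_values(values, groups, col, dataset.groups)
        omni = kruskal_wallis(by_group, key=key, alpha=alpha)
        results.append(omni)
        if omni.significant or not posthoc_gate:
            results.extend(dunn_posthoc(by_group, key=key, alpha=alpha))
    if include_summary:
        summary = summarize_mean_ranks(
            dataset, keys, max_gap=max_gap, denominator=denominator, arf=arf
        )
    else:
        summary = pd.DataFrame()
    return ComparisonReport(step=step, results=results, mean_ranks=summary)


def run_specificity_step(
    dataset: "CohortDataset",
    keys: Sequence[SequenceKey] | None = None,
    alpha_policy: AlphaPolicy = REPLICATION_ALPHA,
    max_gap: float = DEFAULT_MAX_GAP,
    denominator: str = "product",
    posthoc_gate: bool = True,
    arf: ARFBundle | None = None,
    include_summary: bool = True,
) -> ComparisonReport:
    """Step 2: Kruskal–Wallis omnibus across all groups for the hypothesized
    sequences, with Dunn–Bonferroni post hocs gated on omnibus significance."""
    if keys is None:
        keys = hypothesized_keys(dataset.alphabet)
    return _omnibus_with_posthoc(
        "specificity", dataset, keys, alpha_policy.alpha, max_gap, denominator,
        posthoc_gate, arf=arf, include_summary=include_summary,
    )


def run_exploratory_step(
    dataset: "CohortDataset",
    exclude_keys: Sequence[SequenceKey] | None = None,
    alpha_policy: AlphaPolicy | None = None,
    max_gap: float = DEFAULT_MAX_GAP,
    denominator: str = "product",
    posthoc_gate: bool = True,
    arf: ARFBundle | None = None,
    include_summary: bool = True,
) -> ComparisonReport:
    """Step 3: hypothesis-free Kruskal–Wallis scan over every sequence not
    already tested, at alpha = .05 / k (k emotion categories)."""
    if exclude_keys is None:
        exclude_keys = hypothesized_keys(dataset.alphabet)
    if alpha_policy is None:
        alpha_policy = AlphaPolicy.divide(0.05, dataset.alphabet.k)
    excluded = set(exclude_keys)
    keys = [k for k in enumerate_sequences(dataset.alphabet) if k not in excluded]
    return _omnibus_with_posthoc(
        "exploratory", dataset, keys, alpha_policy.alpha, max_gap, denominator,
        posthoc_gate, arf=arf, include_summary=include_summary,
    )
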