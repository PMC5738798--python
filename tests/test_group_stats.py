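"""Rank-based test kernels against brute-force oracles, and the three
pipeline steps on simulated cohorts."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from emoseq import (
    DEFAULT_ALPHABET,
    AlphaPolicy,
    SequenceKey,
    bonferroni_alpha,
    dunn_posthoc,
    hypothesized_keys,
    kruskal_wallis,
    rank_across_subjects,
    run_exploratory_step,
    run_replication_step,
    run_specificity_step,
    summarize_mean_ranks,
    wilcoxon_rank_sum,
)
from emoseq.group_stats import prepare_arf
from emoseq.synthetic_cohort import (
    GroupSpec,
    SimulationConfig,
    build_transition_model,
    simulate_cohort,
)
from emoseq.studies import neutral_model


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def oracle_ranksum_p(a, b):
    """Exhaustive two-sided permutation p for the rank-sum of sample a.

    Independent route: ranks come from sorting with explicit mid-rank
    assignment, and the null distribution enumerates every split of the
    pooled values (not rank subsets) into groups of the observed sizes.
    """
    pooled = list(a) + list(b)
    n_a = len(a)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    w_obs = sum(ranks[:n_a])
    le = ge = total = 0
    for subset in itertools.combinations(range(len(pooled)), n_a):
        w = sum(ranks[i] for i in subset)
        total += 1
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def permutation_p_mean_rank_diff(values, sizes, pair, n_perm, seed):
    """Monte-Carlo permutation p for the difference in mean pooled ranks
    between two of the groups (labels permuted over all subjects)."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    ranks = sps.rankdata(values)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    i, j = pair
    sl_i = slice(bounds[i], bounds[i + 1])
    sl_j = slice(bounds[j], bounds[j + 1])
    obs = abs(ranks[sl_i].mean() - ranks[sl_j].mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        if abs(perm[sl_i].mean() - perm[sl_j].mean()) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


# --------------------------------------------------------------------------
# ranking and alpha policy
# --------------------------------------------------------------------------

class TestRanks:
    def test_no_ties(self):
        assert rank_across_subjects([0.1, 0.2, 0.3]).tolist() == [1, 2, 3]

    def test_mid_rank_ties(self):
        assert rank_across_subjects([0.0, 0.0, 0.5]).tolist() == [1.5, 1.5, 3]

    def test_rank_sum_identity_with_many_zeros(self, rng):
        values = np.where(rng.random(50) < 0.3, 0.0, rng.random(50))
        ranks = rank_across_subjects(values)
        assert ranks.sum() == pytest.approx(50 * 51 / 2)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            rank_across_subjects([1.0])


class TestAlphaPolicy:
    @pytest.mark.parametrize(
        "base,m,expected", [(0.05, 10, 0.005), (0.05, 1, 0.05), (0.05, 7, 0.05 / 7)]
    )
    def test_bonferroni_division(self, base, m, expected):
        assert bonferroni_alpha(base, m) == pytest.approx(expected)

    def test_invalid_divisor(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)

    def test_policy_modes(self):
        assert AlphaPolicy.fixed(0.014).alpha == 0.014
        assert AlphaPolicy.divide(0.05, 10).alpha == pytest.approx(0.005)


# --------------------------------------------------------------------------
# Wilcoxon rank-sum
# --------------------------------------------------------------------------

class TestWilcoxon:
    def test_complete_separation(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.statistic == 6.0
        assert res.extra["U"] == 0.0

    def test_identical_samples(self):
        a = [0.1, 0.4, 0.9, 1.3]
        res = wilcoxon_rank_sum(a, a)
        assert res.extra["U"] == pytest.approx(len(a) ** 2 / 2)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_all_equal(self):
        res = wilcoxon_rank_sum([0.0] * 5, [0.0] * 4)
        assert res.degenerate
        assert res.p_value == 1.0

    @pytest.mark.parametrize("n_a,n_b", [(n_a, n_b) for n_a in range(1, 6) for n_b in range(1, 6)])
    def test_exact_p_matches_enumeration_oracle(self, n_a, n_b, rng):
        """Exact p equals exhaustive enumeration for every small partition,
        including tied data (~40% zeros, like real ARFs)."""
        for _ in range(4):
            a = np.where(rng.random(n_a) < 0.4, 0.0, rng.integers(0, 5, n_a) / 10)
            b = np.where(rng.random(n_b) < 0.4, 0.0, rng.integers(0, 5, n_b) / 10)
            res = wilcoxon_rank_sum(a, b)
            if res.degenerate:
                continue
            assert res.p_value == pytest.approx(oracle_ranksum_p(a, b))

    def test_asymptotic_close_to_enumeration_past_boundary(self, rng):
        """Just past the exact-enumeration cutoff (N=13) the normal
        approximation stays close to the exhaustive permutation p."""
        for _ in range(5):
            a, b = rng.random(7), rng.random(6) + 0.2
            approx = wilcoxon_rank_sum(a, b).p_value  # asymptotic branch
            exact = oracle_ranksum_p(a, b)
            assert abs(approx - exact) < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


# --------------------------------------------------------------------------
# Kruskal-Wallis and Dunn
# --------------------------------------------------------------------------

class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis({"a": [1, 2], "b": [1, 2], "c": [1, 2]})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_evaluated_untied_ranks(self):
        """H on ranks 1..9 split into thirds: 12/(9*10) * 3*((2-5)^2+(8-5)^2) = 7.2."""
        res = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert res.statistic == pytest.approx(7.2)
        assert res.p_value == pytest.approx(sps.chi2.sf(7.2, 2))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"only": [1, 2, 3]})

    def test_two_group_kw_matches_wilcoxon_ordering(self, rng):
        """With two groups, KW and the two-sided Wilcoxon agree on p up to the
        approximation method (chi-square vs normal with continuity)."""
        for _ in range(20):
            a, b = rng.random(15), rng.random(12) + rng.random() * 0.5
            p_kw = kruskal_wallis({"a": a, "b": b}).p_value
            p_w = wilcoxon_rank_sum(a, b).p_value
            assert abs(p_kw - p_w) < 0.05

    def test_monte_carlo_small_n(self, rng):
        """Chi-square p is in the same region as a permutation estimate."""
        a, b, c = [1.0, 4.0], [2.0, 5.0], [8.0, 9.0, 10.0]
        res = kruskal_wallis({"a": a, "b": b, "c": c})
        pooled = np.concatenate([a, b, c])
        stat_obs = res.statistic
        count = 0
        n_perm = 3000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            h, _ = sps.kruskal(perm[:2], perm[2:4], perm[4:])
            count += h >= stat_obs - 1e-12
        p_perm = (count + 1) / (n_perm + 1)
        assert abs(res.p_value - p_perm) < 0.1


class TestDunn:
    def test_identical_groups_inside_three(self):
        same = [0.1, 0.2, 0.3, 0.4]
        other = [1.0, 1.1, 1.2, 1.3]
        results = dunn_posthoc({"a": same, "b": list(same), "c": other})
        ab = next(r for r in results if r.comparison == "a vs b")
        assert ab.statistic == pytest.approx(0.0, abs=1e-9)
        assert ab.p_value == pytest.approx(1.0)

    def test_hand_evaluated_z(self):
        """Ranks 1..9 in thirds, no ties: z_12 = (2-5)/sqrt(7.5*(2/3))."""
        results = dunn_posthoc(
            {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}, adjust="none"
        )
        ab = next(r for r in results if r.comparison == "a vs b")
        assert ab.statistic == pytest.approx(-3 / math.sqrt(7.5 * 2 / 3))

    def test_matches_permutation_oracle(self, rng):
        """Unadjusted Dunn p agrees with a label-permutation estimate of the
        mean-rank-difference distribution on tied data."""
        sizes = [8, 8, 8]
        values = np.where(rng.random(24) < 0.3, 0.0, rng.random(24))
        values[16:] += 0.35  # moderate effect in group 3
        groups = {
            "a": values[:8],
            "b": values[8:16],
            "c": values[16:],
        }
        results = dunn_posthoc(groups, adjust="none")
        for pair, name in [((0, 2), "a vs c"), ((0, 1), "a vs b")]:
            res = next(r for r in results if r.comparison == name)
            p_perm = permutation_p_mean_rank_diff(values, sizes, pair, 20000, seed=5)
            assert abs(res.p_value - p_perm) < 0.03

    def test_bonferroni_monotonicity(self, rng):
        values = {g: rng.random(6) for g in ("a", "b", "c", "d")}
        raw = dunn_posthoc(values, adjust="none")
        adj = dunn_posthoc(values, adjust="bonferroni")
        for r0, r1 in zip(raw, adj):
            assert r1.p_value >= r0.p_value - 1e-12
            assert r1.p_value <= 1.0


# --------------------------------------------------------------------------
# pipeline steps
# --------------------------------------------------------------------------

def two_group_cohort(seed, boost=0.25, n_a=30, n_b=30):
    boosted = build_transition_model(
        1 / 11, {("anxious", "anxious"): boost} if boost else None
    )
    base = neutral_model()
    return simulate_cohort(
        SimulationConfig(
            groups=(GroupSpec("BPD", n_a, boosted), GroupSpec("HC", n_b, base)),
            miss_prob=0.05,
            seed=seed,
        )
    )


def four_group_cohort(seed, n=15, boost=0.0):
    base = neutral_model()
    boosted = (
        build_transition_model(1 / 11, {("anxious", "anxious"): boost})
        if boost
        else base
    )
    return simulate_cohort(
        SimulationConfig(
            groups=(
                GroupSpec("BPD", n, boosted),
                GroupSpec("PTSD", n, base),
                GroupSpec("BN", n, base),
                GroupSpec("HC", n, base),
            ),
            miss_prob=0.05,
            seed=seed,
        )
    )


class TestPipelineSteps:
    def test_replication_recovers_boosted_persistence(self):
        cohort = two_group_cohort(seed=42, boost=0.3, n_a=40, n_b=30)
        report = run_replication_step(cohort)
        res = next(r for r in report.results if r.key == SequenceKey("anxious", "anxious"))
        assert res.significant

    def test_replication_errors_on_single_subject_groups(self):
        cohort = two_group_cohort(seed=3, boost=0.0, n_a=1, n_b=1)
        with pytest.raises(Exception):
            run_replication_step(cohort)

    def test_specificity_needs_three_groups(self):
        cohort = two_group_cohort(seed=4)
        with pytest.raises(Exception):
            run_specificity_step(cohort)

    def test_specificity_gatekeeping(self):
        """Dunn post hocs appear only for keys whose omnibus rejected."""
        cohort = four_group_cohort(seed=5, boost=0.3)
        report = run_specificity_step(cohort)
        omnibus = {id(r): r for r in report.results if r.statistic_name == "H_kw"}
        by_key_sig = {r.key: r.significant for r in omnibus.values()}
        posthoc_keys = {r.key for r in report.results if r.statistic_name == "z_dunn"}
        for key in posthoc_keys:
            assert by_key_sig[key]
        for key, sig in by_key_sig.items():
            assert (key in posthoc_keys) == sig

    def test_exploratory_key_counts(self):
        cohort = four_group_cohort(seed=6)
        report = run_exploratory_step(cohort)
        omnibus = [r for r in report.results if r.statistic_name == "H_kw"]
        assert len(omnibus) == 113
        report_all = run_exploratory_step(cohort, exclude_keys=[])
        assert len([r for r in report_all.results if r.statistic_name == "H_kw"]) == 120
        assert all(r.alpha == pytest.approx(0.005) for r in omnibus)

    def test_hypothesized_keys_are_seven_valid_keys(self):
        keys = hypothesized_keys(DEFAULT_ALPHABET)
        assert len(keys) == len(set(keys)) == 7
        all_keys = set()
        from emoseq import enumerate_sequences

        all_keys = set(enumerate_sequences(DEFAULT_ALPHABET))
        assert set(keys) <= all_keys

    def test_monotone_transform_invariance(self):
        """Rank-based significance flags survive strictly monotone transforms
        of the ARF values."""
        cohort = four_group_cohort(seed=8, boost=0.25)
        arf = prepare_arf(cohort)
        rep0 = run_replication_step(cohort, arf=arf, include_summary=False)
        transformed = prepare_arf(cohort)
        transformed.values = np.log1p(3.0 * transformed.values)
        rep1 = run_replication_step(cohort, arf=transformed, include_summary=False)
        for r0, r1 in zip(rep0.results, rep1.results):
            assert r0.significant == r1.significant
            assert r0.p_value == pytest.approx(r1.p_value)


class TestMeanRankSummary:
    def test_pooled_mean_is_grand_rank_mean(self):
        cohort = four_group_cohort(seed=9)
        keys = hypothesized_keys(DEFAULT_ALPHABET)
        summary = summarize_mean_ranks(cohort, keys)
        n = cohort.n_subjects
        for key_name, sub in summary.groupby("key"):
            pooled_mean = (sub["mean_rank"] * sub["n"]).sum() / sub["n"].sum()
            assert pooled_mean == pytest.approx((n + 1) / 2)

    def test_boosted_group_has_highest_mean_rank(self):
        cohort = four_group_cohort(seed=10, boost=0.3, n=25)
        summary = summarize_mean_ranks(cohort, [SequenceKey("anxious", "anxious")])
        best = summary.loc[summary["mean_rank"].idxmax(), "group"]
        assert best == "BPD"

    def test_identical_groups_have_similar_mean_ranks(self):
        """Two groups simulated from one model: mean ranks differ only by
        sampling noise, far from the separation a boost produces."""
        cohort = two_group_cohort(seed=11, boost=0.0, n_a=40, n_b=40)
        summary = summarize_mean_ranks(cohort, [SequenceKey("anxious", "anxious")])
        ranks = summary.set_index("group")["mean_rank"]
        assert abs(ranks["BPD"] - ranks["HC"]) < 12
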