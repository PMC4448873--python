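"""Stability, size classes, composition and body-size statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flocknet.stats import (
    GroupPairOverlap,
    bin_group_sizes,
    binomial_composition_probability,
    binomial_mean_profile,
    body_size_pc1,
    class_proportion_profile,
    group_size_summaries,
    kurtosis_assortment,
    log_lag_bins,
    pair_stability,
    pearson_kurtosis,
    stability_curve,
    stability_ratio,
    SizeClassBinning,
    StabilityCurve,
)

from conftest import make_matrix, random_matrix


def overlap_from_groups(focal, g1, g2, lag=60.0):
    shared = (g1 & g2) - {focal}
    return GroupPairOverlap(focal, lag, len(shared), len(g1 - g2), len(g2 - g1))


class TestPairStability:
    def test_one_shared_one_exclusive_each(self):
        s = pair_stability(overlap_from_groups("X", {"X", "A", "B"}, {"X", "A", "C"}))
        assert s == pytest.approx(1 / 3)

    def test_identical_membership_is_one(self):
        s = pair_stability(overlap_from_groups("X", {"X", "A", "B"}, {"X", "A", "B"}))
        assert s == 1.0

    def test_two_thirds_overlap_of_even_groups_is_half(self):
        # two groups of 13 sharing 9 members including the focal
        shared = {f"s{i}" for i in range(8)}
        g1 = {"X"} | shared | {f"p{i}" for i in range(4)}
        g2 = {"X"} | shared | {f"q{i}" for i in range(4)}
        assert len(g1) == len(g2) == 13
        assert pair_stability(overlap_from_groups("X", g1, g2)) == pytest.approx(0.5)

    def test_focal_only_pair_is_excluded(self):
        with pytest.raises(ValueError):
            pair_stability(overlap_from_groups("X", {"X"}, {"X"}))

    @given(
        shared=st.integers(0, 20), only1=st.integers(0, 20), only2=st.integers(0, 20)
    )
    @settings(deadline=None, max_examples=50)
    def test_bounded_and_symmetric(self, shared, only1, only2):
        if shared + only1 + only2 == 0:
            return
        s12 = pair_stability(GroupPairOverlap("X", 1.0, shared, only1, only2))
        s21 = pair_stability(GroupPairOverlap("X", 1.0, shared, only2, only1))
        assert 0.0 <= s12 <= 1.0
        assert s12 == s21
        assert (s12 == 1.0) == (only1 == only2 == 0)


def brute_force_curve(matrix, edges, min_shared=1):
    """Independent oracle: exhaustive enumeration over focals and group pairs."""
    members = [matrix.members_of(i) for i in range(matrix.n_groups)]
    times = matrix.abs_times()
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1)
    for j, k in itertools.permutations(range(matrix.n_groups), 2):
        tau = times[k] - times[j]
        if tau <= 0:
            continue
        for focal in members[j] & members[k]:
            shared = len((members[j] & members[k]) - {focal})
            if shared < min_shared:
                continue
            only1 = len(members[j] - members[k])
            only2 = len(members[k] - members[j])
            if shared + only1 + only2 == 0:
                continue
            b = np.searchsorted(edges, tau, side="right") - 1
            if 0 <= b < len(edges) - 1:
                sums[b] += shared / (shared + only1 + only2)
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan), counts


class TestStabilityCurve:
    def test_matches_exhaustive_enumeration(self, rng):
        m = random_matrix(rng, n_groups=60, n_individuals=15)
        edges = log_lag_bins(30, 2e5, 6)
        curve = stability_curve(m, edges)
        oracle_vals, oracle_counts = brute_force_curve(m, edges)
        assert np.allclose(curve.pair_counts, oracle_counts)
        assert np.allclose(curve.s_values, oracle_vals, equal_nan=True)

    def test_identical_groups_score_one_everywhere(self):
        specs = [({"a", "b", "c"}, "F0", 1, 1, 100.0 * (i + 1)) for i in range(5)]
        curve = stability_curve(make_matrix(specs), np.array([1.0, 1e4]))
        assert curve.s_values[0] == pytest.approx(1.0)

    def test_disjoint_nonfocal_membership_scores_zero(self):
        specs = [
            ({"X", "a"}, "F0", 1, 1, 100.0),
            ({"X", "b"}, "F0", 1, 1, 200.0),
        ]
        curve = stability_curve(make_matrix(specs), np.array([1.0, 1e4]), min_shared=0)
        assert curve.s_values[0] == 0.0

    def test_empty_bin_is_nan_not_zero(self):
        specs = [({"a", "b"}, "F0", 1, 1, 0.0), ({"a", "b"}, "F0", 1, 1, 10.0)]
        curve = stability_curve(make_matrix(specs), np.array([1.0, 20.0, 1e5]))
        assert curve.s_values[0] == pytest.approx(1.0)
        assert np.isnan(curve.s_values[1])


class TestStabilityRatio:
    def test_equal_curves_give_one(self):
        edges = np.array([1.0, 10.0, 100.0])
        c = StabilityCurve(edges, np.array([0.4, 0.2]), np.array([5, 5]))
        assert np.allclose(stability_ratio(c, c), 1.0)

    def test_doubled_observed_gives_two(self):
        edges = np.array([1.0, 10.0])
        obs = StabilityCurve(edges, np.array([0.8]), np.array([5]))
        perm = StabilityCurve(edges, np.array([0.4]), np.array([5]))
        assert stability_ratio(obs, perm)[0] == pytest.approx(2.0)

    def test_zero_permuted_is_flagged_nan(self):
        edges = np.array([1.0, 10.0])
        obs = StabilityCurve(edges, np.array([0.8]), np.array([5]))
        perm = StabilityCurve(edges, np.array([0.0]), np.array([5]))
        assert np.isnan(stability_ratio(obs, perm)[0])

    def test_mismatched_bins_rejected(self):
        c1 = StabilityCurve(np.array([1.0, 10.0]), np.array([0.5]), np.array([1]))
        c2 = StabilityCurve(np.array([1.0, 20.0]), np.array([0.5]), np.array([1]))
        with pytest.raises(ValueError):
            stability_ratio(c1, c2)


class TestGroupSizeSummaries:
    def test_mean_max_typical(self):
        m = make_matrix(
            [
                ({f"i{j}" for j in range(2)}, "F0", 1, 1, 1.0),
                ({f"i{j}" for j in range(6)}, "F0", 1, 1, 2.0),
            ]
        )
        assert group_size_summaries(m) == (4.0, 6, 5.0)

    def test_all_singletons(self):
        m = make_matrix([({f"i{j}"}, "F0", 1, 1, float(j)) for j in range(4)])
        assert group_size_summaries(m) == (1.0, 1, 1.0)

    def test_typical_at_least_mean(self, rng):
        m = random_matrix(rng, n_groups=40)
        mean, _, typical = group_size_summaries(m)
        assert typical >= mean - 1e-12


def greedy_merge_oracle(size_counts, start=14, min_share=0.05):
    """Hand-executable greedy merge over a {size: n_groups} distribution."""
    total = sum(s * c for s, c in size_counts.items())
    bins = [(s, s) for s in sorted(size_counts) if s < start]
    large = sorted(s for s in size_counts if s >= start)
    lo, acc, merged = None, 0.0, []
    for s in large:
        lo = s if lo is None else lo
        acc += size_counts[s] * s / total
        if acc >= min_share:
            merged.append((lo, s))
            lo, acc = None, 0.0
    if lo is not None:
        if merged:
            merged[-1] = (merged[-1][0], large[-1])
        else:
            merged.append((lo, large[-1]))
    return bins + merged


def matrix_with_size_counts(size_counts):
    specs = []
    t = 0.0
    for size, count in size_counts.items():
        for _ in range(count):
            specs.append(({f"i{j}" for j in range(size)}, "F0", 1, 1, t))
            t += 10.0
    return make_matrix(specs)


class TestBinGroupSizes:
    def test_small_sizes_stay_singletons(self):
        binning = bin_group_sizes(matrix_with_size_counts({2: 10, 5: 4, 13: 2}))
        assert binning.bins == [(2, 2), (5, 5), (13, 13)]

    def test_two_small_shares_merge(self):
        # sizes 14 and 15 each ~3% of memberships -> one merged class [14, 15]
        counts = {2: 436, 14: 2, 15: 2}   # shares: 28/930 = 3.0%, 30/930 = 3.2%
        binning = bin_group_sizes(matrix_with_size_counts(counts))
        assert (14, 15) in binning.bins

    def test_single_large_size_is_own_class(self):
        binning = bin_group_sizes(matrix_with_size_counts({20: 3}))
        assert binning.bins == [(20, 20)]

    @pytest.mark.parametrize(
        "counts",
        [
            {3: 5, 14: 1, 15: 1, 16: 1, 20: 4},
            {1: 100, 14: 30, 15: 2},
            {5: 10, 18: 1},
            {2: 20, 14: 1, 17: 1, 25: 1},
            {4: 3, 14: 2, 15: 2, 16: 2, 17: 2, 30: 1},
        ],
    )
    def test_matches_greedy_hand_merge(self, counts):
        binning = bin_group_sizes(matrix_with_size_counts(counts))
        assert binning.bins == greedy_merge_oracle(counts)

    def test_every_merged_class_holds_min_share(self, rng):
        m = random_matrix(rng, n_groups=100, n_individuals=40, mean_size=12)
        binning = bin_group_sizes(m)
        for (lo, hi), share in zip(binning.bins, binning.membership_share):
            if lo >= 14 and hi < max(h for _, h in binning.bins):
                assert share >= 0.05


class TestCompositionProfiles:
    def _phen(self, sexes):
        return pd.DataFrame(
            {
                "individual_id": list(sexes),
                "sex": list(sexes.values()),
                "age_class": "adult",
                "residency": "local",
                "wing_mm": 75.0,
                "tarsus_mm": 20.0,
            }
        )

    def test_all_male_population_profile_is_one(self):
        m = make_matrix([({"a", "b"}, "F0", 1, 1, 1.0), ({"a", "c"}, "F0", 1, 1, 2.0)])
        phen = self._phen({"a": "male", "b": "male", "c": "male"})
        binning = bin_group_sizes(m)
        prof = class_proportion_profile(m, phen, binning, "sex", "male")
        assert np.allclose(prof.values[prof.n_groups > 0], 1.0)

    def test_mean_proportion_example(self):
        # groups {M, M} and {M, F}: mean male proportion at size 2 is 0.75
        m = make_matrix([({"a", "b"}, "F0", 1, 1, 1.0), ({"a", "c"}, "F0", 1, 1, 2.0)])
        phen = self._phen({"a": "male", "b": "male", "c": "female"})
        binning = bin_group_sizes(m)
        prof = class_proportion_profile(m, phen, binning, "sex", "male")
        assert prof.values[binning.bin_of(2)] == pytest.approx(0.75)

    def test_unknown_only_group_contributes_nothing(self):
        m = make_matrix([({"u1", "u2"}, "F0", 1, 1, 1.0)])
        phen = self._phen({"a": "male"})
        binning = bin_group_sizes(m)
        prof = class_proportion_profile(m, phen, binning, "sex", "male")
        assert prof.n_groups[binning.bin_of(2)] == 0


class TestBinomialComposition:
    @pytest.mark.parametrize(
        "n,k,p,expected", [(2, 2, 0.5, 0.25), (2, 1, 0.5, 0.5), (3, 3, 0.4, 0.064)]
    )
    def test_examples(self, n, k, p, expected):
        assert binomial_composition_probability(n, k, p) == pytest.approx(expected)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            binomial_composition_probability(2, 3, 0.5)

    @given(n=st.integers(1, 12), p=st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=40)
    def test_probabilities_sum_to_one(self, n, p):
        total = sum(binomial_composition_probability(n, k, p) for k in range(n + 1))
        assert total == pytest.approx(1.0)

    def test_mean_profile_uses_per_size_class_share(self):
        # groups of size 2: {M, M} and {M, F}; unique participants a, b, c
        # with 2 males of 3 -> p = 2/3; probabilities: pmf(2)=4/9, pmf(1)=4/9
        m = make_matrix([({"a", "b"}, "F0", 1, 1, 1.0), ({"a", "c"}, "F0", 1, 1, 2.0)])
        phen = TestCompositionProfiles()._phen({"a": "male", "b": "male", "c": "female"})
        binning = bin_group_sizes(m)
        prof = binomial_mean_profile(m, phen, binning, "sex", "male")
        assert prof.values[binning.bin_of(2)] == pytest.approx(4 / 9)


class TestKurtosisAssortment:
    def test_normal_group_means_score_three(self, rng):
        x = rng.normal(size=100_000)
        assert pearson_kurtosis(x) == pytest.approx(3.0, abs=0.1)

    def test_symmetric_two_point_mass_scores_one(self):
        assert pearson_kurtosis(np.array([-1.0, 1.0] * 50)) == pytest.approx(1.0)

    def test_constant_means_are_flagged(self):
        assert np.isnan(pearson_kurtosis(np.full(10, 2.0)))

    def test_per_bin_matrix_computation(self, rng):
        m = random_matrix(rng, n_groups=30, n_individuals=12, mean_size=3)
        traits = pd.Series(
            rng.normal(size=12), index=[f"i{j:02d}" for j in range(12)]
        )
        binning = bin_group_sizes(m)
        prof = kurtosis_assortment(m, traits, binning)
        # oracle for one populated bin
        sizes = m.group_sizes()
        for b, (lo, hi) in enumerate(binning.bins):
            sel = (sizes >= lo) & (sizes <= hi)
            if sel.sum() < 4:
                assert np.isnan(prof.values[b])
                continue
            means = []
            for gi in np.flatnonzero(sel):
                members = sorted(m.members_of(gi))
                means.append(traits.loc[members].mean())
            assert prof.values[b] == pytest.approx(pearson_kurtosis(np.array(means)))


class TestBodySizePC1:
    def _phen(self, n, rng, corr=0.8):
        cov = np.array([[1.0, corr], [corr, 1.0]])
        sexes = np.array(["male", "female"])[rng.integers(0, 2, n)]
        base = rng.multivariate_normal([0, 0], cov, size=n)
        wing = 75 + 2 * base[:, 0] + (sexes == "male") * 2.5
        tarsus = 20 + 0.5 * base[:, 1] + (sexes == "male") * 0.7
        return pd.DataFrame(
            {
                "individual_id": [f"i{j}" for j in range(n)],
                "sex": sexes,
                "age_class": "adult",
                "residency": "local",
                "wing_mm": wing,
                "tarsus_mm": tarsus,
            }
        )

    def test_equal_measures_reduce_to_standardized_variable(self, rng):
        phen = self._phen(50, rng)
        phen["tarsus_mm"] = phen["wing_mm"]
        pc1 = body_size_pc1(phen)
        for sex in ("male", "female"):
            sel = phen["sex"] == sex
            w = phen.loc[sel.to_numpy(), "wing_mm"]
            z = (w - w.mean()) / w.std(ddof=1)
            assert np.allclose(pc1[phen.loc[sel.to_numpy(), "individual_id"]], z)

    def test_correlates_strongly_with_wing(self, rng):
        phen = self._phen(300, rng)
        pc1 = body_size_pc1(phen).reindex(phen["individual_id"])
        for sex in ("male", "female"):
            sel = (phen["sex"] == sex).to_numpy()
            r = np.corrcoef(pc1[sel], phen["wing_mm"][sel])[0, 1]
            assert r > 0.9

    def test_standardized_within_sex(self, rng):
        phen = self._phen(200, rng)
        pc1 = body_size_pc1(phen).reindex(phen["individual_id"])
        for sex in ("male", "female"):
            sel = (phen["sex"] == sex).to_numpy()
            assert pc1[sel].mean() == pytest.approx(0.0, abs=1e-9)
            assert pc1[sel].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_missing_measures_get_no_score(self, rng):
        phen = self._phen(10, rng)
        phen.loc[0, "wing_mm"] = np.nan
        pc1 = body_size_pc1(phen)
        assert np.isnan(pc1.loc[phen.loc[0, "individual_id"]])
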