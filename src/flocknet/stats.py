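"""Group-level statistics: stability, size structure and composition.

The temporal stability statistic follows the lagged-association-rate idea:
for a focal individual X present in two groups j and k separated by a lag
tau, the pair's stability is

    S = G_jk / (G_j!k + G_k!j + G_jk)

where G_jk counts non-focal individuals shared by both groups and G_j!k,
G_k!j count individuals exclusive to each.  S = 1 when membership is
identical and 0.5 when two-thirds of an evenly sized group persists.
Pair values are pooled into log-spaced lag bins and compared, as a ratio,
with the same curve computed on permuted group memberships.

Composition statistics operate per group-size class: the share of a focal
phenotypic class per group, the binomial probability of each group's
composition (values near the maximum indicate disassortment, small values
indicate assortment), and the Pearson kurtosis of group-mean trait values
(peaked distributions indicate size assortment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .groups import GroupByIndividualMatrix

__all__ = [
    "GroupPairOverlap",
    "StabilityCurve",
    "SizeClassBinning",
    "CompositionProfile",
    "pair_stability",
    "stability_curve",
    "stability_ratio",
    "log_lag_bins",
    "group_size_summaries",
    "bin_group_sizes",
    "class_proportion_profile",
    "binomial_composition_probability",
    "binomial_mean_profile",
    "kurtosis_assortment",
    "body_size_pc1",
]


@dataclass(frozen=True)
class GroupPairOverlap:
    """Membership overlap of two groups sharing a focal individual."""

    focal: str
    lag_s: float
    shared_nonfocal: int
    only_first: int
    only_second: int

    def __post_init__(self):
        if min(self.shared_nonfocal, self.only_first, self.only_second) < 0:
            raise ValueError("overlap counts must be non-negative")
        if self.lag_s <= 0:
            raise ValueError("lag must be positive")


@dataclass
class StabilityCurve:
    """Mean pair stability per lag bin (NaN where a bin holds no pairs)."""

    bin_edges: np.ndarray     # (B + 1,) seconds, increasing
    s_values: np.ndarray      # (B,) in [0, 1] or NaN
    pair_counts: np.ndarray   # (B,) qualifying focal-pair count per bin


@dataclass
class SizeClassBinning:
    """Ordered inclusive group-size intervals with membership shares."""

    bins: list[tuple[int, int]]
    membership_share: np.ndarray

    def bin_of(self, size: int) -> int:
        for i, (lo, hi) in enumerate(self.bins):
            if lo <= size <= hi:
                return i
        return -1

    def labels(self) -> list[str]:
        return [f"{lo}" if lo == hi else f"{lo}-{hi}" for lo, hi in self.bins]


@dataclass
class CompositionProfile:
    """Per-size-class values of a composition statistic."""

    binning: SizeClassBinning
    values: np.ndarray      # (B,) NaN where no group contributes
    n_groups: np.ndarray    # (B,) contributing groups


def pair_stability(overlap: GroupPairOverlap) -> float:
    """S for one group pair; undefined when both groups hold only the focal."""
    denom = overlap.shared_nonfocal + overlap.only_first + overlap.only_second
    if denom == 0:
        raise ValueError("pair with no non-focal individuals is excluded from S")
    return overlap.shared_nonfocal / denom


def log_lag_bins(min_s: float = 60.0, max_s: float = 12 * 3600.0, n_bins: int = 8) -> np.ndarray:
    """Log10-spaced lag-bin edges in seconds."""
    return np.logspace(np.log10(min_s), np.log10(max_s), n_bins + 1)


def stability_curve(
    matrix: GroupByIndividualMatrix,
    lag_bins: np.ndarray | None = None,
    min_shared: int = 1,
    per_focal: bool = False,
) -> StabilityCurve:
    """Mean pair stability by lag bin, pooled over focal individuals.

    A group pair qualifies for a focal X when both groups contain X and at
    least ``min_shared`` non-focal individuals are common to both.  Every
    shared member of a pair acts as focal in turn, so a pair with I common
    members contributes I identically valued focal-pair terms.  By default
    the per-bin mean pools all qualifying focal-pairs; with ``per_focal``
    each focal's pairs are averaged first and the bin value is the mean
    over focals.
    """
    edges = np.asarray(log_lag_bins() if lag_bins is None else lag_bins, dtype=float)
    nb = len(edges) - 1
    inc = matrix.incidence.astype(bool)
    shared = (inc.astype(np.int64)) @ (inc.astype(np.int64).T)
    sizes = matrix.group_sizes()
    times = matrix.abs_times()
    g = matrix.n_groups

    sum_s = np.zeros(nb)
    cnt = np.zeros(nb)
    focal_sum = np.zeros((matrix.n_individuals, nb)) if per_focal else None
    focal_cnt = np.zeros((matrix.n_individuals, nb)) if per_focal else None

    for j in range(g):
        for k in range(g):
            tau = times[k] - times[j]
            if tau <= 0 or j == k:
                continue
            i_jk = int(shared[j, k])
            shared_nonfocal = i_jk - 1
            if shared_nonfocal < min_shared:
                continue
            denom = (int(sizes[j]) - i_jk) + (int(sizes[k]) - i_jk) + shared_nonfocal
            if denom == 0:
                continue
            b = np.searchsorted(edges, tau, side="right") - 1
            if b < 0 or b >= nb:
                continue
            s = shared_nonfocal / denom
            sum_s[b] += i_jk * s
            cnt[b] += i_jk
            if per_focal:
                focals = np.flatnonzero(inc[j] & inc[k])
                focal_sum[focals, b] += s
                focal_cnt[focals, b] += 1

    if per_focal:
        with np.errstate(invalid="ignore"):
            per = np.where(focal_cnt > 0, focal_sum / np.maximum(focal_cnt, 1), np.nan)
        values = np.array(
            [np.nanmean(per[:, b]) if (focal_cnt[:, b] > 0).any() else np.nan for b in range(nb)]
        )
    else:
        with np.errstate(invalid="ignore"):
            values = np.where(cnt > 0, sum_s / np.maximum(cnt, 1), np.nan)
    return StabilityCurve(edges, values, cnt)


def stability_ratio(observed: StabilityCurve, permuted: StabilityCurve) -> np.ndarray:
    """Element-wise observed / permuted stability; NaN where undefined."""
    if len(observed.bin_edges) != len(permuted.bin_edges) or not np.allclose(
        observed.bin_edges, permuted.bin_edges
    ):
        raise ValueError("stability curves must share lag bins")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = observed.s_values / permuted.s_values
    ratio = np.where(
        np.isfinite(permuted.s_values) & (permuted.s_values > 0), ratio, np.nan
    )
    return ratio


def group_size_summaries(matrix: GroupByIndividualMatrix) -> tuple[float, int, float]:
    """(mean, max, typical) group size; typical = sum(n^2)/sum(n)."""
    sizes = matrix.group_sizes()
    if len(sizes) == 0:
        raise ValueError("no groups")
    return float(sizes.mean()), int(sizes.max()), float((sizes**2).sum() / sizes.sum())


def bin_group_sizes(
    matrix: GroupByIndividualMatrix,
    start_binning_at: int = 14,
    min_share: float = 0.05,
) -> SizeClassBinning:
    """Group-size classes: singleton bins below the threshold, merged above.

    Observed sizes below ``start_binning_at`` each form their own class.
    Larger sizes are merged greedily upward until each class carries at
    least ``min_share`` of all group memberships; a trailing class short of
    the share is absorbed into the previous merged class.
    """
    sizes = matrix.group_sizes()
    total_memberships = sizes.sum()
    size_counts = pd.Series(sizes).value_counts().sort_index()
    share = {int(s): s * c / total_memberships for s, c in size_counts.items()}

    bins: list[tuple[int, int]] = []
    shares: list[float] = []
    small = [s for s in share if s < start_binning_at]
    for s in sorted(small):
        bins.append((s, s))
        shares.append(share[s])

    large = sorted(s for s in share if s >= start_binning_at)
    lo = None
    acc = 0.0
    n_large_bins = 0
    for s in large:
        if lo is None:
            lo = s
        acc += share[s]
        if acc >= min_share:
            bins.append((lo, s))
            shares.append(acc)
            n_large_bins += 1
            lo, acc = None, 0.0
    if lo is not None:  # trailing remainder below the share threshold
        if n_large_bins:
            plo, _ = bins[-1]
            bins[-1] = (plo, large[-1])
            shares[-1] += acc
        else:
            bins.append((lo, large[-1]))
            shares.append(acc)
    return SizeClassBinning(bins, np.asarray(shares))


def _trait_values(phenotypes: pd.DataFrame, individuals: np.ndarray, column: str) -> np.ndarray:
    ph = phenotypes.set_index("individual_id")[column]
    vals = np.array(
        [ph.get(i, np.nan) for i in individuals], dtype=object
    )
    return vals


def class_proportion_profile(
    matrix: GroupByIndividualMatrix,
    phenotypes: pd.DataFrame,
    binning: SizeClassBinning,
    trait: str,
    focal_class: str,
) -> CompositionProfile:
    """Mean per-group proportion of a focal class, by group-size class.

    The per-group proportion is taken over members with a known trait
    value; groups with no known-trait member contribute nothing to their
    size class.
    """
    vals = _trait_values(phenotypes, matrix.individuals, trait)
    known = np.array([isinstance(v, str) and v not in ("", "unknown") for v in vals])
    focal = known & (vals == focal_class)
    inc = matrix.incidence.astype(float)
    n_known = inc @ known.astype(float)
    n_focal = inc @ focal.astype(float)
    sizes = matrix.group_sizes()

    nb = len(binning.bins)
    sums = np.zeros(nb)
    counts = np.zeros(nb)
    for g in range(matrix.n_groups):
        if n_known[g] == 0:
            continue
        b = binning.bin_of(int(sizes[g]))
        if b < 0:
            continue
        sums[b] += n_focal[g] / n_known[g]
        counts[b] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return CompositionProfile(binning, values, counts.astype(int))


def binomial_composition_probability(n: int, k: int, p: float) -> float:
    """P[Binomial(n, p) = k]: the chance composition probability of a group."""
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    # direct evaluation: robust for the small n of observed groups
    from math import comb

    return float(comb(n, k) * p**k * (1.0 - p) ** (n - k))


def binomial_mean_profile(
    matrix: GroupByIndividualMatrix,
    phenotypes: pd.DataFrame,
    binning: SizeClassBinning,
    trait: str,
    focal_class: str,
) -> CompositionProfile:
    """Mean binomial composition probability per size class.

    For each exact group size, the class probability p is the focal-class
    share of unique known-trait individuals appearing in groups of that
    size; each group's probability is the binomial pmf of its observed
    focal count.  Higher means (closer to the pmf maximum) indicate
    disassortment; low means indicate assorted (skewed) compositions.
    """
    vals = _trait_values(phenotypes, matrix.individuals, trait)
    known = np.array([isinstance(v, str) and v not in ("", "unknown") for v in vals])
    focal = known & (vals == focal_class)
    inc = matrix.incidence.astype(bool)
    sizes = matrix.group_sizes()

    # per-size class probability from unique participating individuals
    p_by_size: dict[int, float] = {}
    for s in np.unique(sizes):
        rows = sizes == s
        appearing = inc[rows].any(axis=0)
        nk = int((appearing & known).sum())
        if nk:
            p_by_size[int(s)] = int((appearing & focal).sum()) / nk

    nb = len(binning.bins)
    sums = np.zeros(nb)
    counts = np.zeros(nb)
    for g in range(matrix.n_groups):
        s = int(sizes[g])
        if s not in p_by_size:
            continue
        row = inc[g]
        n_known = int((row & known).sum())
        if n_known == 0:
            continue
        k = int((row & focal).sum())
        b = binning.bin_of(s)
        if b < 0:
            continue
        sums[b] += binomial_composition_probability(n_known, k, p_by_size[s])
        counts[b] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return CompositionProfile(binning, values, counts.astype(int))


def pearson_kurtosis(x: np.ndarray) -> float:
    """Pearson (non-excess) kurtosis m4 / m2^2 with population moments.

    A normal distribution scores 3; a symmetric two-point mass scores 1.
    """
    x = np.asarray(x, float)
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        return float("nan")
    return float(np.mean((x - x.mean()) ** 4) / m2**2)


def kurtosis_assortment(
    matrix: GroupByIndividualMatrix,
    trait_values: pd.Series,
    binning: SizeClassBinning,
    min_groups: int = 4,
) -> CompositionProfile:
    """Pearson kurtosis (m4 / m2^2, normal -> 3) of group-mean trait per size class.

    High kurtosis means group means are peaked around the population mean
    (size assortment); low kurtosis means a flat distribution.  Bins with
    fewer than ``min_groups`` groups, or with zero variance of group means,
    are NaN.
    """
    vals = trait_values.reindex(matrix.individuals).to_numpy(float)
    have = np.isfinite(vals)
    inc = matrix.incidence.astype(float)
    n_have = inc @ have.astype(float)
    with np.errstate(invalid="ignore"):
        gmeans = np.where(n_have > 0, (inc @ np.where(have, vals, 0.0)) / np.maximum(n_have, 1), np.nan)
    sizes = matrix.group_sizes()

    nb = len(binning.bins)
    values = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    for b in range(nb):
        lo, hi = binning.bins[b]
        sel = (sizes >= lo) & (sizes <= hi) & np.isfinite(gmeans)
        counts[b] = int(sel.sum())
        if counts[b] < min_groups:
            continue
        x = gmeans[sel]
        if np.var(x) == 0:
            continue
        values[b] = pearson_kurtosis(x)
    return CompositionProfile(binning, values, counts)


def body_size_pc1(phenotypes: pd.DataFrame) -> pd.Series:
    """Within-sex first principal component of wing and tarsus length.

    Wing and tarsus are standardized within each sex, PC1 of their 2x2
    covariance is extracted, oriented so it correlates positively with
    wing, and rescaled to mean 0, variance 1 within sex.  Individuals
    missing a measure, of unknown sex, or in a sex with fewer than two
    scored individuals get NaN.
    """
    out = pd.Series(np.nan, index=phenotypes["individual_id"], name="pc1", dtype=float)
    for sex in ("male", "female"):
        sub = phenotypes[
            (phenotypes["sex"] == sex)
            & phenotypes["wing_mm"].notna()
            & phenotypes["tarsus_mm"].notna()
        ]
        if len(sub) < 2:
            continue
        z = sub[["wing_mm", "tarsus_mm"]].to_numpy(float)
        sd = z.std(axis=0, ddof=1)
        if (sd == 0).any():
            # degenerate spread: fall back to the informative axis
            sd = np.where(sd == 0, 1.0, sd)
        z = (z - z.mean(axis=0)) / sd
        cov = np.cov(z, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        v = eigvecs[:, np.argmax(eigvals)]
        scores = z @ v
        if np.corrcoef(scores, z[:, 0])[0, 1] < 0:
            scores = -scores
        ssd = scores.std(ddof=1)
        if ssd > 0:
            scores = (scores - scores.mean()) / ssd
        out.loc[sub["individual_id"].to_numpy()] = scores
    return out
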