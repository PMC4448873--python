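"""Two contrasting permutation null models and social/spatial attribution.

The *node-label (phenotypic) null* shuffles which phenotype belongs to
which individual while leaving the observation stream untouched: it breaks
every link between phenotype and both space and association, so it is the
reference for "phenotypes are distributed at random over the population".

The *data-stream (spatio-temporally restricted) null*, in the tradition of
restricted swap tests for association data, repeatedly exchanges two
individuals between two groups observed at the same feeder in the same
sampling period.  Group sizes, each individual's number of observations,
and all group metadata are conserved, so spatial and temporal structure of
phenotypes is preserved while within-location group choice is randomized.

Comparing an observed statistic against both nulls attributes structure:
differing from both implies social effects (active grouping decisions);
differing only from the node-label null implies spatial effects (phenotypes
unevenly spread in space); differing from neither implies no detectable
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .groups import GroupByIndividualMatrix

__all__ = [
    "NullDistribution",
    "EffectClassification",
    "node_permutation_null",
    "datastream_swap",
    "datastream_permutation_null",
    "classify_effect",
]

StatisticFn = Callable[[GroupByIndividualMatrix, pd.DataFrame], "float | np.ndarray"]

_PHEN_COLS_EXCLUDED = ("individual_id",)


@dataclass
class NullDistribution:
    """Permuted-statistic samples with the observed value and envelopes."""

    statistic: str
    observed: np.ndarray            # () or (B,)
    samples: np.ndarray             # (S,) or (S, B)
    n_iterations: int
    sampling_interval: int = 1
    n_skipped: int = 0
    final_matrix: GroupByIndividualMatrix | None = field(default=None, repr=False)

    @property
    def envelope(self) -> tuple[np.ndarray, np.ndarray]:
        """Central 95% interval of the permuted statistic (per bin)."""
        lo = np.nanpercentile(self.samples, 2.5, axis=0)
        hi = np.nanpercentile(self.samples, 97.5, axis=0)
        return lo, hi

    @property
    def full_range(self) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(all="ignore"):
            return np.nanmin(self.samples, axis=0), np.nanmax(self.samples, axis=0)


@dataclass
class EffectClassification:
    """Attribution of an observed statistic to social or spatial structure."""

    trait: str
    statistic: str
    verdict: str                    # social | spatial | none | ambiguous
    differs_from_node_null: bool
    differs_from_stream_null: bool


def _shuffled_phenotypes(
    phenotypes: pd.DataFrame, rng: np.random.Generator, trait: str | None
) -> pd.DataFrame:
    perm = rng.permutation(len(phenotypes))
    out = phenotypes.copy()
    if trait is None:
        cols = [c for c in phenotypes.columns if c not in _PHEN_COLS_EXCLUDED]
    else:
        cols = [trait]
    out[cols] = phenotypes[cols].to_numpy()[perm]
    return out


def node_permutation_null(
    matrix: GroupByIndividualMatrix,
    phenotypes: pd.DataFrame,
    statistic_fn: StatisticFn,
    n_iter: int = 1000,
    seed: int = 0,
    trait: str | None = None,
    statistic_name: str = "statistic",
) -> NullDistribution:
    """Node-label null: reshuffle phenotype rows across individuals.

    By default the whole phenotype row moves jointly (trait covariance is
    preserved); pass ``trait`` to shuffle a single column instead.  The
    label multiset and the observation structure are invariant.
    """
    rng = np.random.default_rng(seed)
    observed = np.asarray(statistic_fn(matrix, phenotypes), dtype=float)
    samples = np.empty((n_iter,) + observed.shape)
    for i in range(n_iter):
        samples[i] = statistic_fn(matrix, _shuffled_phenotypes(phenotypes, rng, trait))
    return NullDistribution(statistic_name, observed, samples, n_iter, 1)


class _SwapStrata:
    """Pre-indexed (feeder, period) strata of the group matrix."""

    def __init__(self, matrix: GroupByIndividualMatrix):
        meta = matrix.meta
        groups = meta.groupby(["feeder_id", "sampling_period"]).indices
        self.strata = [np.asarray(v) for v in groups.values() if len(v) >= 2]
        npairs = np.array([len(v) * (len(v) - 1) / 2 for v in self.strata])
        if npairs.sum() > 0:
            self.p = npairs / npairs.sum()
            self.cum_p = np.cumsum(self.p)
        else:
            self.p = None
            self.cum_p = None


def datastream_swap(
    matrix: GroupByIndividualMatrix,
    rng: np.random.Generator,
    strata: _SwapStrata | None = None,
    max_attempts: int = 50,
) -> bool:
    """One restricted swap, in place; returns True when a swap happened.

    Draws a (feeder, period) stratum with probability proportional to its
    number of group pairs, two distinct groups in it, and one individual
    exclusive to each; the two individuals exchange groups.  Group sizes,
    per-individual observation counts and group metadata are unchanged.
    After ``max_attempts`` failed candidate draws the swap is skipped.
    """
    strata = _SwapStrata(matrix) if strata is None else strata
    if strata.p is None:
        return False
    inc = matrix.incidence
    for _ in range(max_attempts):
        s = strata.strata[int(np.searchsorted(strata.cum_p, rng.random()))]
        j = int(rng.integers(len(s)))
        k = int(rng.integers(len(s) - 1))
        if k >= j:
            k += 1
        g1, g2 = int(s[j]), int(s[k])
        r1, r2 = inc[g1], inc[g2]
        only1 = np.flatnonzero(r1 > r2)
        only2 = np.flatnonzero(r2 > r1)
        if len(only1) == 0 or len(only2) == 0:
            continue
        a = int(only1[rng.integers(len(only1))])
        b = int(only2[rng.integers(len(only2))])
        r1[a] = 0
        r1[b] = 1
        r2[b] = 0
        r2[a] = 1
        return True
    return False


def datastream_permutation_null(
    matrix: GroupByIndividualMatrix,
    phenotypes: pd.DataFrame,
    statistic_fn: StatisticFn,
    n_iter: int = 1_000_000,
    sample_every: int = 1000,
    seed: int = 0,
    statistic_name: str = "statistic",
) -> NullDistribution:
    """Data-stream null: a cumulative chain of restricted swaps.

    The chain makes the data increasingly random; the statistic is recorded
    after every ``sample_every`` successful swaps, and the final permuted
    matrix is retained (``final_matrix``) for statistics too expensive to
    evaluate along the chain.  The input matrix is not modified.
    """
    rng = np.random.default_rng(seed)
    observed = np.asarray(statistic_fn(matrix, phenotypes), dtype=float)
    work = matrix.copy()
    strata = _SwapStrata(work)

    n_samples = n_iter // sample_every
    samples = np.empty((n_samples,) + observed.shape)
    skipped = 0
    done = 0
    consecutive_failures = 0
    exhausted = False
    for i in range(n_samples):
        target = (i + 1) * sample_every
        while done < target and not exhausted:
            if datastream_swap(work, rng, strata):
                done += 1
                consecutive_failures = 0
            else:
                # only successful swaps count as iterations; skips are logged
                skipped += 1
                consecutive_failures += 1
                if consecutive_failures > 100:
                    exhausted = True  # no legal swaps remain in any stratum
        try:
            samples[i] = statistic_fn(work, phenotypes)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"statistic failed at iteration {target}") from exc
    return NullDistribution(
        statistic_name, observed, samples, n_iter, sample_every, skipped, final_matrix=work
    )


def _differs(observed: np.ndarray, null: NullDistribution, rule: str) -> bool:
    """Does the observed statistic fall outside the null distribution?

    Scalars use the central 95% envelope; multi-bin profiles default to the
    whole-range criterion (any bin outside the entire permuted range),
    which avoids multiplicity over correlated bins.
    """
    obs = np.atleast_1d(observed)
    if rule == "auto":
        rule = "envelope95" if obs.size == 1 else "range"
    if rule == "envelope95":
        lo, hi = null.envelope
    elif rule == "range":
        lo, hi = null.full_range
    else:
        raise ValueError(f"unknown rule: {rule}")
    lo, hi = np.atleast_1d(lo), np.atleast_1d(hi)
    ok = np.isfinite(obs) & np.isfinite(lo) & np.isfinite(hi)
    return bool(((obs < lo) | (obs > hi))[ok].any())


def classify_effect(
    observed: "float | np.ndarray",
    node_null: NullDistribution,
    stream_null: NullDistribution,
    trait: str = "",
    rule: str = "auto",
) -> EffectClassification:
    """Attribute assortment to social or spatial processes.

    Outside both nulls -> social; outside the node-label null only ->
    spatial; inside both -> none; outside the data-stream null only ->
    ambiguous (structure beyond location that phenotype labels alone do
    not explain).
    """
    observed = np.asarray(observed, dtype=float)
    if np.atleast_1d(node_null.observed).shape != np.atleast_1d(stream_null.observed).shape:
        raise ValueError("null distributions were computed on different statistics")
    d_node = _differs(observed, node_null, rule)
    d_stream = _differs(observed, stream_null, rule)
    if d_node and d_stream:
        verdict = "social"
    elif d_node:
        verdict = "spatial"
    elif d_stream:
        verdict = "ambiguous"
    else:
        verdict = "none"
    return EffectClassification(trait, node_null.statistic, verdict, d_node, d_stream)
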