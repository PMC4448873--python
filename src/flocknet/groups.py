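"""Segment detection streams into gathering events with 1-D Gaussian mixtures.

Visits of flocking birds to a feeder arrive in bursts of high activity
separated by quiet spells.  Each feeder-day's detection times are modelled
as a mixture of Gaussians; the number of components is selected by BIC over
K = 1..k_max with multiple EM restarts, and each detection is hard-assigned
to its maximum-responsibility component.  A component's member set is the
set of unique individuals among its detections.  The result is the
group-by-individual incidence matrix that all downstream analyses consume.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "GatheringEvent",
    "GroupByIndividualMatrix",
    "default_k_max",
    "segment_stream",
    "infer_groups",
    "build_group_matrix",
]

SECONDS_PER_DAY = 86_400.0


@dataclass
class GatheringEvent:
    """One inferred group: a temporal burst of detections at one feeder."""

    group_id: str
    feeder_id: str
    day: int
    sampling_period: int
    centre_time_s: float
    spread_s: float
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError("a gathering must have at least one member")


@dataclass
class GroupByIndividualMatrix:
    """Binary groups x individuals incidence with per-group metadata.

    Rows are sorted by (sampling_period, feeder_id, day, time_s); columns
    are sorted individual ids.  ``meta`` has one row per group with columns
    ``group_id, feeder_id, day, sampling_period, time_s``.
    """

    incidence: np.ndarray                 # (G, N) uint8
    individuals: np.ndarray               # (N,) ids
    meta: pd.DataFrame

    def __post_init__(self):
        self.incidence = np.asarray(self.incidence, dtype=np.uint8)
        self.individuals = np.asarray(self.individuals)
        if self.incidence.ndim != 2:
            raise ValueError("incidence must be 2-D")
        if self.incidence.shape[0] != len(self.meta):
            raise ValueError("meta rows must match incidence rows")
        if self.incidence.shape[1] != len(self.individuals):
            raise ValueError("individual ids must match incidence columns")
        if self.n_groups and not (self.incidence.sum(axis=1) >= 1).all():
            raise ValueError("every group must have at least one member")

    @property
    def n_groups(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.incidence.shape[1]

    def group_sizes(self) -> np.ndarray:
        return self.incidence.sum(axis=1).astype(int)

    def membership_counts(self) -> np.ndarray:
        """Number of group memberships per individual (column sums)."""
        return self.incidence.sum(axis=0).astype(int)

    def abs_times(self) -> np.ndarray:
        """Group times on a common axis: (day - 1) * 86400 + time_s."""
        return (self.meta["day"].to_numpy(float) - 1.0) * SECONDS_PER_DAY + self.meta[
            "time_s"
        ].to_numpy(float)

    def members_of(self, row: int) -> frozenset:
        return frozenset(self.individuals[self.incidence[row].astype(bool)])

    def copy(self) -> "GroupByIndividualMatrix":
        return GroupByIndividualMatrix(
            self.incidence.copy(), self.individuals.copy(), self.meta.copy()
        )


def default_k_max(times: np.ndarray, per_seconds: float = 600.0) -> int:
    """Cap the number of gatherings at one per ``per_seconds`` of day span."""
    span = float(np.max(times) - np.min(times)) if len(times) else 0.0
    return max(1, int(np.ceil(span / per_seconds)))


def _component_order(means: np.ndarray) -> np.ndarray:
    return np.argsort(means, kind="stable")


def segment_stream(
    events: pd.DataFrame,
    k_max: int | None = None,
    min_component_weight: float = 0.0,
    seed: int = 0,
    n_init: int = 3,
    return_labels: bool = False,
):
    """Segment one feeder-day's detections into gatherings.

    ``events`` must hold detections from a single feeder and day with
    columns ``time_s, individual_id`` (``feeder_id, day, sampling_period``
    are carried through to the output).  Components whose mixture weight
    falls below ``min_component_weight`` are merged into the component with
    the nearest mean.  Ties in responsibility break toward the earlier
    component, so segmentation is deterministic given ``seed``.  With
    ``return_labels`` the per-detection gathering index (into the returned
    list) is also returned.
    """
    if len(events) == 0:
        return ([], np.empty(0, dtype=int)) if return_labels else []
    feeders = events["feeder_id"].unique()
    days = events["day"].unique()
    if len(feeders) != 1 or len(days) != 1:
        raise ValueError("segment_stream expects detections from one feeder and one day")
    feeder, day = feeders[0], int(days[0])
    period = int(events["sampling_period"].iloc[0])

    times = events["time_s"].to_numpy(float)
    if not np.isfinite(times).all():
        raise ValueError("detection times must be finite")
    inds = events["individual_id"].to_numpy()

    if k_max is None:
        k_max = default_k_max(times)
    k_cap = min(int(k_max), len(np.unique(times)))

    labels, means = _fit_mixture_labels(times, k_cap, min_component_weight, seed, n_init)

    gatherings: list[GatheringEvent] = []
    out_labels = np.full(len(times), -1, dtype=int)
    for j in _component_order(means):
        sel = labels == j
        if not sel.any():
            continue
        t = times[sel]
        out_labels[sel] = len(gatherings)
        gatherings.append(
            GatheringEvent(
                group_id="",  # assigned by infer_groups / caller
                feeder_id=feeder,
                day=day,
                sampling_period=period,
                centre_time_s=float(t.mean()),
                spread_s=float(t.std()),
                members=frozenset(inds[sel]),
            )
        )
    # components come out ordered by mean, hence gatherings are time-sorted
    if return_labels:
        return gatherings, out_labels
    return gatherings


def _fit_mixture_labels(
    times: np.ndarray, k_cap: int, min_component_weight: float, seed: int, n_init: int
) -> tuple[np.ndarray, np.ndarray]:
    """Return hard component labels and component means for one stream."""
    # degenerate streams: nothing to segment
    if k_cap <= 1 or len(times) < 2:
        return np.zeros(len(times), dtype=int), np.array([times.mean()])

    x = times.reshape(-1, 1) - times.mean()   # centring: shift-invariant fits
    best = None
    best_bic = np.inf
    patience = 5   # stop scanning K once BIC has stalled this many steps
    stalled = 0
    for k in range(1, k_cap + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed % (2**31),
            reg_covar=1e-3,
        )
        gm.fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best = gm
            stalled = 0
        else:
            stalled += 1
            if stalled >= patience:
                break

    resp = best.predict_proba(x)
    means = best.means_.ravel() + times.mean()
    weights = best.weights_.copy()

    # merge under-weight components into the nearest-mean neighbour
    keep = weights >= min_component_weight
    if keep.sum() == 0:
        keep[np.argmax(weights)] = True
    if not keep.all():
        for j in np.flatnonzero(~keep):
            targets = np.flatnonzero(keep)
            tgt = targets[np.argmin(np.abs(means[targets] - means[j]))]
            resp[:, tgt] += resp[:, j]
            resp[:, j] = 0.0

    # hard assignment, ties toward the earlier (smaller-mean) component
    order = _component_order(means)
    resp_ord = resp[:, order]
    labels_ord = np.argmax(np.isclose(resp_ord, resp_ord.max(axis=1, keepdims=True)), axis=1)
    labels = order[labels_ord]
    return labels, means


def infer_groups(
    detections: pd.DataFrame,
    k_max: int | None = None,
    min_component_weight: float = 0.0,
    seed: int = 0,
) -> list[GatheringEvent]:
    """Segment an entire detection stream, one feeder-day at a time.

    Restart seeds are derived from ``seed`` and a CRC of the feeder/day key
    so that results are reproducible and independent of iteration order.
    """
    gatherings: list[GatheringEvent] = []
    for (feeder, day), sub in detections.groupby(["feeder_id", "day"], sort=True):
        sub_seed = (int(seed) + zlib.crc32(f"{feeder}|{day}".encode())) % (2**31)
        gatherings.extend(
            segment_stream(
                sub, k_max=k_max, min_component_weight=min_component_weight, seed=sub_seed
            )
        )
    gatherings.sort(key=lambda g: (g.sampling_period, g.feeder_id, g.day, g.centre_time_s))
    for i, g in enumerate(gatherings, start=1):
        g.group_id = f"G{i:06d}"
    return gatherings


def build_group_matrix(
    gatherings: list[GatheringEvent],
    population: pd.DataFrame | None = None,
) -> GroupByIndividualMatrix:
    """Assemble the binary group-by-individual matrix from gatherings.

    Columns are the union of observed individuals (sorted); individuals in
    ``population`` never seen in a group are not added as empty columns.
    """
    ids = [g.group_id for g in gatherings]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate group ids")
    observed = sorted(set().union(*[g.members for g in gatherings])) if gatherings else []
    col = {ind: j for j, ind in enumerate(observed)}

    order = sorted(
        range(len(gatherings)),
        key=lambda i: (
            gatherings[i].sampling_period,
            gatherings[i].feeder_id,
            gatherings[i].day,
            gatherings[i].centre_time_s,
        ),
    )
    inc = np.zeros((len(gatherings), len(observed)), dtype=np.uint8)
    meta_rows = []
    for r, i in enumerate(order):
        g = gatherings[i]
        for m in g.members:
            inc[r, col[m]] = 1
        meta_rows.append((g.group_id, g.feeder_id, g.day, g.sampling_period, g.centre_time_s))
    meta = pd.DataFrame(
        meta_rows, columns=["group_id", "feeder_id", "day", "sampling_period", "time_s"]
    )
    return GroupByIndividualMatrix(inc, np.array(observed, dtype=object), meta)


def matrix_from_truth(truth_memberships: pd.DataFrame, truth_meta: pd.DataFrame) -> GroupByIndividualMatrix:
    """Build the group matrix directly from a truth bundle (or groups CSVs)."""
    gatherings = []
    mem = truth_memberships.groupby("group_id")["individual_id"].apply(frozenset)
    for _, row in truth_meta.iterrows():
        gid = row["group_id"]
        if gid not in mem.index:
            continue
        gatherings.append(
            GatheringEvent(
                group_id=str(gid),
                feeder_id=row["feeder_id"],
                day=int(row["day"]) if "day" in row else 1,
                sampling_period=int(row["sampling_period"]),
                centre_time_s=float(row["time_s"]),
                spread_s=0.0,
                members=mem.loc[gid],
            )
        )
    return build_group_matrix(gatherings)
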