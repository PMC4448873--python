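"""Weighted association networks from group memberships.

Associations follow the gambit of the group: all members of a gathering are
taken to be associating.  Dyadic edge weights are simple-ratio indices
(SRI), the fraction of gatherings involving either member in which both
were present, so weights run from 0 (never together) to 1 (always
together).  Assortment of node attributes across the weighted edges is
summarised by the Newman assortativity coefficient, in its discrete
(mixing-matrix) and continuous (weighted-correlation) forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .groups import GroupByIndividualMatrix

__all__ = [
    "AssociationNetwork",
    "MixingMatrix",
    "simple_ratio_index",
    "build_network",
    "assortativity_discrete",
    "assortativity_continuous",
    "network_density",
]


class UndefinedStatisticError(ValueError):
    """Raised when a network statistic is undefined for the given input."""


@dataclass
class AssociationNetwork:
    """Symmetric SRI weight matrix with aligned node ids."""

    weights: np.ndarray       # (N, N) float, zero diagonal
    node_ids: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise ValueError("SRI weights must lie in [0, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        self.node_ids = np.asarray(self.node_ids)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def to_graph(self) -> nx.Graph:
        """networkx graph with SRI weights on edges (attribute ``sri``)."""
        g = nx.Graph()
        g.add_nodes_from(self.node_ids.tolist())
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        for i, j in zip(ii, jj):
            g.add_edge(
                self.node_ids[i],
                self.node_ids[j],
                sri=float(self.weights[i, j]),
                weight=float(self.weights[i, j]),
            )
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_ids, columns=self.node_ids)


@dataclass
class MixingMatrix:
    """Edge-weight fractions by class pair, with marginals and coefficient."""

    classes: list
    e: np.ndarray      # class x class fractions of total edge weight, sums to 1
    a: np.ndarray      # row marginals
    b: np.ndarray      # column marginals
    r: float


def simple_ratio_index(x: int, y_a: int, y_b: int) -> float:
    """SRI = x / (x + y_a + y_b) for co-occurrence and single-occurrence counts."""
    if min(x, y_a, y_b) < 0:
        raise ValueError("counts must be non-negative")
    denom = x + y_a + y_b
    if denom == 0:
        raise UndefinedStatisticError("dyad never observed: SRI undefined")
    return x / denom


def build_network(matrix: GroupByIndividualMatrix) -> AssociationNetwork:
    """SRI network over all observed individuals.

    For a dyad (A, B): x = gatherings containing both; the denominator adds
    the gatherings containing exactly one of the two.  Dyads never observed
    in any shared-or-separate gathering would be undefined, but every
    observed individual has at least one gathering, so all dyads here have
    a positive denominator.
    """
    inc = matrix.incidence.astype(np.int64)
    together = inc.T @ inc                         # x, with per-individual totals on diag
    n_obs = np.diag(together)
    either = n_obs[:, None] + n_obs[None, :] - together
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(either > 0, together / np.maximum(either, 1), 0.0)
    np.fill_diagonal(w, 0.0)
    return AssociationNetwork(w, matrix.individuals.copy())


def _known_mask(labels: np.ndarray) -> np.ndarray:
    lab = pd.Series(labels)
    return (~lab.isna() & (lab.astype(str) != "unknown") & (lab.astype(str) != "")).to_numpy()


def mixing_matrix(network: AssociationNetwork, labels: np.ndarray) -> MixingMatrix:
    """Weight-proportional class mixing matrix over undirected edges.

    Each undirected edge contributes half its weight to e[q, r] and half to
    e[r, q]; individuals with unknown labels are excluded.
    """
    labels = np.asarray(labels, dtype=object)
    keep = _known_mask(labels)
    w = network.weights[np.ix_(keep, keep)]
    lab = labels[keep]
    classes = sorted(set(lab.tolist()))
    if w.sum() <= 0:
        raise UndefinedStatisticError("no positive edges among labelled nodes")
    idx = np.array([classes.index(v) for v in lab])
    k = len(classes)
    e = np.zeros((k, k))
    ii, jj = np.nonzero(np.triu(w, k=1))
    for i, j in zip(ii, jj):
        e[idx[i], idx[j]] += w[i, j] / 2.0
        e[idx[j], idx[i]] += w[i, j] / 2.0
    e /= e.sum()
    a = e.sum(axis=1)
    b = e.sum(axis=0)
    ab = float(a @ b)
    if np.isclose(ab, 1.0):
        raise UndefinedStatisticError("single class present: assortativity undefined")
    r = (float(np.trace(e)) - ab) / (1.0 - ab)
    return MixingMatrix(classes, e, a, b, r)


def assortativity_discrete(network: AssociationNetwork, labels: np.ndarray) -> float:
    """Newman assortativity of a categorical trait on the weighted network."""
    return mixing_matrix(network, labels).r


def assortativity_continuous(network: AssociationNetwork, values: np.ndarray) -> float:
    """Weighted Pearson correlation of endpoint trait values over ordered dyads.

    Nodes with missing values are excluded.  Undefined (error) when the
    weighted variance of endpoint values is zero.
    """
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    w = network.weights[np.ix_(keep, keep)]
    x = values[keep]
    total = w.sum()
    if total <= 0:
        raise UndefinedStatisticError("no positive edges among scored nodes")
    mu = float((w.sum(axis=1) @ x) / total)
    dx = x - mu
    cov = float(dx @ w @ dx) / total
    var = float((w.sum(axis=1) @ dx**2)) / total
    if var <= 0:
        raise UndefinedStatisticError("zero weighted trait variance: assortativity undefined")
    return cov / var


def network_density(network: AssociationNetwork) -> float:
    """Fraction of possible dyads with a positive edge."""
    n = network.n_nodes
    if n < 2:
        raise UndefinedStatisticError("density needs at least two nodes")
    pos = int((np.triu(network.weights, k=1) > 0).sum())
    return pos / (n * (n - 1) / 2)


def write_graphml(network: AssociationNetwork, path) -> None:
    nx.write_graphml(network.to_graph(), path)


def write_csv(network: AssociationNetwork, path) -> None:
    network.to_frame().to_csv(path, index_label="individual_id")
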