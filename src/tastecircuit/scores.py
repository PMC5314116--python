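"""Decomposable Gaussian BIC scoring of DAGs on ROI time series.

The score of a DAG is BIC = -2 ln(ML) + k ln(n), minimized, where k counts the
directed edges plus the number of variables. With Gaussian likelihoods and
per-column standardization, each node contributes n ln(sigma^2_hat) to
-2 ln(ML), sigma^2_hat being the ML (1/n) residual variance of the node
regressed on its parents; additive constants common to every model are
dropped. The multi-subject (IMaGES) score averages the per-subject BIC of each
candidate, each subject scored with its own sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graphs import PDAG, GraphError


class TimeSeriesError(ValueError):
    pass


@dataclass
class ROITimeSeriesSet:
    """Per-subject time x region matrices sharing one region-label ordering."""

    subjects: list[tuple[str, np.ndarray]]
    region_labels: tuple[str, ...]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.region_labels = tuple(self.region_labels)
        r = len(self.region_labels)
        if not self.subjects:
            raise TimeSeriesError("at least one subject is required")
        for sid, mat in self.subjects:
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[1] != r:
                raise TimeSeriesError(
                    f"subject {sid}: expected T x {r} matrix, got shape {mat.shape}"
                )
            if mat.shape[0] < r + 2:
                raise TimeSeriesError(
                    f"subject {sid}: needs at least {r + 2} time points, got {mat.shape[0]}"
                )
            if not np.all(np.isfinite(mat)):
                raise TimeSeriesError(f"subject {sid}: non-finite values present")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def standardize(self) -> "ROITimeSeriesSet":
        """Z-score every column of every subject (ML convention, 1/n variance)."""
        if self.standardized:
            return self
        out = []
        for sid, mat in self.subjects:
            mat = np.asarray(mat, dtype=float)
            sd = mat.std(axis=0, ddof=0)
            if np.any(sd == 0):
                raise TimeSeriesError(f"subject {sid}: constant column cannot be standardized")
            out.append((sid, (mat - mat.mean(axis=0)) / sd))
        return ROITimeSeriesSet(out, self.region_labels, standardized=True)

    def pooled(self) -> np.ndarray:
        """Row-stacked matrix of all (standardized) subjects."""
        data = self.standardize()
        return np.vstack([mat for _, mat in data.subjects])


@dataclass
class GESScore:
    """BIC decomposition of one DAG: -2 ln(ML), model dimension k, sample size n."""

    neg2_loglik: float
    k: int
    n: int

    @property
    def bic(self) -> float:
        return self.neg2_loglik + self.k * math.log(self.n)


class LocalScorer:
    """Cached per-node local BIC contributions for one multi-subject dataset.

    ``local(node, parents)`` returns the node's mean-over-subjects contribution
    n_i ln(sigma^2_hat) + (|parents| + 1) ln(n_i); sums of these over nodes give
    the (subject-averaged) BIC of a DAG.
    """

    def __init__(self, data: ROITimeSeriesSet):
        data = data.standardize()
        self.labels = data.region_labels
        self.p = data.n_regions
        self.ns = np.array([mat.shape[0] for _, mat in data.subjects])
        # ML covariances (1/n); columns are standardized so diagonals are 1
        self.covs = np.stack([mat.T @ mat / mat.shape[0] for _, mat in data.subjects])
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def residual_variances(self, node: int, parents: frozenset[int]) -> np.ndarray:
        """Per-subject ML residual variance of node given parents."""
        if not parents:
            return self.covs[:, node, node]
        pa = sorted(parents)
        s_pp = self.covs[np.ix_(range(len(self.ns)), pa, pa)]
        s_py = self.covs[:, pa, node][..., None]
        try:
            beta = np.linalg.solve(s_pp, s_py)
        except np.linalg.LinAlgError as exc:
            raise GraphError(f"singular parent design for node {node}") from exc
        var = self.covs[:, node, node] - (s_py.transpose(0, 2, 1) @ beta)[:, 0, 0]
        return np.maximum(var, 1e-12)

    def local(self, node: int, parents: frozenset[int]) -> float:
        key = (node, parents)
        if key not in self._cache:
            if node in parents:
                raise GraphError("a node cannot be its own parent")
            var = self.residual_variances(node, parents)
            contrib = self.ns * np.log(var) + (len(parents) + 1) * np.log(self.ns)
            self._cache[key] = float(contrib.mean())
        return self._cache[key]

    def delta(self, node: int, parents: frozenset[int], added: int) -> float:
        """Score change from adding ``added`` to the parent set (negative = better)."""
        return self.local(node, parents | {added}) - self.local(node, parents)


def local_gaussian_score(data: np.ndarray, node: int, parents: Sequence[int]) -> float:
    """-2 ln(ML) contribution n ln(sigma^2_hat) of one node given a parent set.

    ``data`` is a single-subject T x R matrix (standardized internally).
    Penalty terms are not included; see LocalScorer.local for the penalized form.
    """
    ds = ROITimeSeriesSet([("s", np.asarray(data, float))],
                          tuple(f"v{i}" for i in range(np.asarray(data).shape[1])))
    scorer = LocalScorer(ds)
    var = scorer.residual_variances(node, frozenset(parents))
    return float(scorer.ns[0] * np.log(var[0]))


def bic_of_dag(data: ROITimeSeriesSet | np.ndarray, dag: PDAG) -> GESScore:
    """Penalized score of a fully directed DAG on one subject (or a pooled set).

    k = number of directed edges + number of variables; for a multi-subject set
    the returned neg2_loglik and n are subject-averaged/summed consistently via
    the per-subject mean convention used by the search.
    """
    if isinstance(data, np.ndarray):
        data = ROITimeSeriesSet(
            [("s", np.asarray(data, float))],
            tuple(f"v{i}" for i in range(np.asarray(data).shape[1])),
        )
    if dag.has_directed_cycle():
        raise GraphError("bic_of_dag requires an acyclic graph")
    if dag.undirected_edges():
        raise GraphError("bic_of_dag requires a fully directed graph")
    scorer = LocalScorer(data)
    n_edges = len(dag.directed_edges())
    p = scorer.p
    neg2 = 0.0
    for node in range(p):
        var = scorer.residual_variances(node, frozenset(dag.parents[node]))
        neg2 += float((scorer.ns * np.log(var)).mean())
    n = int(round(scorer.ns.mean()))
    return GESScore(neg2_loglik=neg2, k=n_edges + p, n=n)
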