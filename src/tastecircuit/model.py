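"""Model/Results interface for effective-connectivity estimation.

``EffectiveConnectivityModel`` wraps a multi-subject ROI time-series set;
``fit()`` runs the multi-subject greedy equivalence search and (optionally) the
fixed-structure non-Gaussian orientation step, returning an
``EffectiveConnectivityResults`` with the pattern graph, per-edge orientation
measures, the search trace and a text ``summary()``. ``run_effective_connectivity``
composes per-group fits and a cross-group edge comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .graphs import PatternGraph
from .orientation import ling_orient_fixed_structure
from .scores import ROITimeSeriesSet, TimeSeriesError
from .search import SearchTrace, ges_search, images_search


class EffectiveConnectivityModel:
    """Score-based causal-graph model of directed influence between ROIs.

    Parameters
    ----------
    data :
        Multi-subject set of time x region matrices. Subjects are z-scored
        per column before scoring.
    """

    def __init__(self, data: ROITimeSeriesSet):
        self.data = data.standardize()

    @classmethod
    def from_dataframes(cls, frames: Sequence[pd.DataFrame]) -> "EffectiveConnectivityModel":
        """Build from per-subject DataFrames (columns = region labels)."""
        if not frames:
            raise TimeSeriesError("no subjects given")
        labels = tuple(frames[0].columns)
        subjects = []
        for i, df in enumerate(frames):
            if tuple(df.columns) != labels:
                raise TimeSeriesError(
                    f"subject {i}: region labels differ from subject 0"
                )
            subjects.append((str(df.attrs.get("subject_id", f"s{i}")), df.to_numpy(float)))
        return cls(ROITimeSeriesSet(subjects, labels))

    def fit(self, orient: bool = True, density: str = "entropy") -> "EffectiveConnectivityResults":
        """Run the equivalence search (+ orientation step when ``orient``)."""
        if len(self.data.subjects) == 1:
            pattern, trace = ges_search(self.data)
        else:
            pattern, trace = images_search(self.data)
        search_pattern = pattern
        if orient:
            pattern = ling_orient_fixed_structure(self.data, pattern, density=density)
        return EffectiveConnectivityResults(self, search_pattern, pattern, trace)


@dataclass
class EffectiveConnectivityResults:
    """Fitted effective-connectivity pattern with diagnostics."""

    model: EffectiveConnectivityModel
    search_pattern: PatternGraph  # pattern straight from the equivalence search
    pattern: PatternGraph  # after orientation post-processing
    trace: SearchTrace

    def edge_table(self, group: str = "", hemisphere: str = "") -> pd.DataFrame:
        rows = []
        for u, v in sorted(self.pattern.directed_edges):
            rows.append((group, hemisphere, u, v, "directed",
                         self.pattern.orientation_measure.get((u, v), np.nan)))
        for u, v in sorted(self.pattern.undirected_edges):
            rows.append((group, hemisphere, u, v, "undirected", np.nan))
        return pd.DataFrame(
            rows, columns=["group", "hemisphere", "from", "to", "edge_type",
                           "orientation_measure"],
        )

    def summary(self) -> str:
        n_sub = len(self.model.data.subjects)
        lines = [
            "Effective connectivity (greedy equivalence search"
            + (" + non-Gaussian orientation)" if self.pattern is not self.search_pattern
               else ")"),
            f"Subjects: {n_sub}   Regions: {self.model.data.n_regions}   "
            f"Search steps: {len(self.trace.steps)}",
            f"Edges: {len(self.pattern.directed_edges)} directed, "
            f"{len(self.pattern.undirected_edges)} undirected",
            "-" * 64,
            f"{'from':<26}{'to':<26}{'type':<11}measure",
        ]
        for u, v in sorted(self.pattern.directed_edges):
            m = self.pattern.orientation_measure.get((u, v))
            lines.append(f"{u:<26}{v:<26}{'directed':<11}"
                         + ("" if m is None else f"{m:+.4f}"))
        for u, v in sorted(self.pattern.undirected_edges):
            lines.append(f"{u:<26}{v:<26}{'undirected':<11}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Draw the pattern (directed arcs with arrows, undirected without)."""
        import matplotlib.pyplot as plt
        import networkx as nx

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        g = nx.DiGraph()
        g.add_nodes_from(self.pattern.vertices)
        g.add_edges_from(self.pattern.directed_edges)
        pos = nx.circular_layout(g)
        nx.draw_networkx_nodes(g, pos, ax=ax, node_color="#c6dbef", node_size=1600)
        nx.draw_networkx_labels(g, pos, ax=ax, font_size=7)
        nx.draw_networkx_edges(g, pos, ax=ax, arrows=True, arrowsize=15)
        if self.pattern.undirected_edges:
            h = nx.Graph()
            h.add_edges_from(self.pattern.undirected_edges)
            nx.draw_networkx_edges(h, pos, ax=ax, style="dashed", arrows=False)
        ax.set_axis_off()
        return ax


def compare_groups(patterns: Mapping[str, PatternGraph]) -> pd.DataFrame:
    """Cross-group edge comparison: shared / group-unique / direction-reversed.

    An edge (as an unordered pair) recovered in every group with the same
    direction everywhere is ``shared``; recovered in every group but with
    opposing directions somewhere is ``direction_reversed``; otherwise it is
    ``unique:<groups>`` naming the groups that recovered it.
    """
    groups = sorted(patterns)
    pair_dirs: dict[frozenset, dict[str, str]] = {}
    for gname in groups:
        pat = patterns[gname]
        for u, v in pat.directed_edges:
            pair_dirs.setdefault(frozenset((u, v)), {})[gname] = f"{u}->{v}"
        for u, v in pat.undirected_edges:
            pair_dirs.setdefault(frozenset((u, v)), {})[gname] = f"{u}--{v}"
    rows = []
    for pair in sorted(pair_dirs, key=sorted):
        dirs = pair_dirs[pair]
        u, v = sorted(pair)
        if len(dirs) < len(groups):
            status = "unique:" + ",".join(g for g in groups if g in dirs)
        else:
            directed = {d for d in dirs.values() if "->" in d}
            status = "shared" if len(set(dirs.values())) == 1 or len(directed) <= 1 \
                else "direction_reversed"
        rows.append((u, v, status) + tuple(dirs.get(g, "") for g in groups))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "status"] + groups)


def run_effective_connectivity(
    group_data: Mapping[str, ROITimeSeriesSet],
    density: str = "entropy",
) -> tuple[dict[str, "EffectiveConnectivityResults"], pd.DataFrame]:
    """Fit every group's pattern and build the cross-group comparison table."""
    if not group_data:
        raise TimeSeriesError("no groups given")
    results = {}
    for gname in sorted(group_data):
        results[gname] = EffectiveConnectivityModel(group_data[gname]).fit(density=density)
    comparison = compare_groups({g: r.pattern for g, r in results.items()})
    return results, comparison
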