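"""Dynamic Network Analysis (DyNA) of windowed mediator correlations.

For each stratum and each adjacent 8 h window of the first day post-injury
(0-8, 8-16, 16-24 h), mediator draws are collapsed to one value per patient
(the window mean of log10 concentration), correlations are computed across
patients, and an undirected network is built with an edge wherever the
correlation coefficient meets the threshold (r >= 0.7 by default, the
"greater or equal" convention applied literally to signed r).

Network density uses the metric

    density = E * N / (N * (N - 1) / 2) = 2E / (N - 1)

with E the edge count and N the node count entering the formula — by
default the nodes with degree >= 1, so that the metric accounts for the
size of the active network rather than the full assay panel.

Model-object surface: ``DynamicNetworkAnalysis(samples, groups).fit()``
returns a :class:`DynamicNetworkResults` holding every (group, window)
network with its density.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AnalysisWindow",
    "DEFAULT_WINDOWS",
    "CorrelationNetwork",
    "DensityValue",
    "window_patient_matrix",
    "correlation_matrix",
    "build_network",
    "network_density",
    "compare_networks",
    "dyna_run",
    "DynamicNetworkAnalysis",
    "DynamicNetworkResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window [start_h, end_h) in hours post-injury."""

    start_h: float
    end_h: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.end_h > self.start_h:
            raise ValueError("window end must exceed start")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.start_h:g}-{self.end_h:g}h"
            )

    def contains(self, time_h) -> np.ndarray:
        t = np.asarray(time_h, dtype=float)
        return (t >= self.start_h) & (t < self.end_h)


#: Adjacent 8 h windows partitioning the first 24 h.
DEFAULT_WINDOWS: tuple[AnalysisWindow, ...] = (
    AnalysisWindow(0.0, 8.0),
    AnalysisWindow(8.0, 16.0),
    AnalysisWindow(16.0, 24.0),
)


@dataclass
class CorrelationNetwork:
    """Thresholded windowed correlation network for one stratum.

    ``edges`` maps unordered mediator pairs (i < j by name) to the
    correlation coefficient; ``edge_n`` carries the number of patients
    behind each retained edge.
    """

    group: str
    window: AnalysisWindow
    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    threshold: float
    mode: str = "signed"
    edge_n: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(group=self.group, window=self.window.label,
                     threshold=self.threshold)
        g.add_nodes_from(self.nodes)
        for (a, b), r in self.edges.items():
            g.add_edge(a, b, r=float(r))
        return g

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (a, b, r, self.edge_n.get((a, b), np.nan),
             self.group, self.window.label)
            for (a, b), r in sorted(self.edges.items())
        ]
        return pd.DataFrame(
            rows, columns=["mediator_a", "mediator_b", "r", "n_patients",
                           "group", "window"]
        )


@dataclass(frozen=True)
class DensityValue:
    group: str
    window: str
    E: int
    N: int
    density: float


def window_patient_matrix(
    samples: pd.DataFrame,
    window: AnalysisWindow,
    patient_ids: Sequence[str],
    log10: bool = True,
    min_pairs: int = 8,
) -> pd.DataFrame:
    """Patients x mediators matrix of window-mean (log10) concentrations.

    Patients with no draw in the window are absent from the matrix; a
    mediator column observed in fewer than ``min_pairs`` patients is
    dropped (logged). Raises when nothing survives.
    """
    sub = samples[
        samples["patient_id"].isin(set(patient_ids))
        & window.contains(samples["time_h"])
    ].copy()
    if log10:
        if (sub["value"] <= 0).any():
            raise ValueError("log10 scale requires positive concentrations")
        sub["value"] = np.log10(sub["value"])
    mat = sub.pivot_table(
        index="patient_id", columns="mediator", values="value", aggfunc="mean"
    )
    thin = [c for c in mat.columns if mat[c].notna().sum() < min_pairs]
    if thin:
        logger.info(
            "window %s: dropped %d mediators with < %d observations",
            window.label, len(thin), min_pairs,
        )
        mat = mat.drop(columns=thin)
    if mat.shape[1] == 0:
        raise ValueError(f"window {window.label} has insufficient data")
    return mat


def correlation_matrix(
    matrix: pd.DataFrame, method: str = "pearson", min_pairs: int = 8
) -> pd.DataFrame:
    """Symmetric, unit-diagonal correlation matrix across patients.

    Pairwise-complete observations; pairs with fewer than ``min_pairs``
    complete cases are set missing (and can never form edges).
    Zero-variance columns yield missing correlations with a logged warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method: {method}")
    constant = [c for c in matrix.columns
                if matrix[c].dropna().nunique() <= 1]
    if constant:
        logger.warning(
            "correlation_matrix: zero-variance columns %s -> missing r",
            constant,
        )
    corr = matrix.corr(method=method, min_periods=max(int(min_pairs), 2))
    np.fill_diagonal(corr.values, 1.0)
    return corr


def build_network(
    corr: pd.DataFrame,
    threshold: float = 0.7,
    mode: str = "signed",
    group: str = "",
    window: AnalysisWindow | None = None,
    counts: pd.DataFrame | None = None,
) -> CorrelationNetwork:
    """Threshold a correlation matrix into an undirected network.

    Edge (i, j), i < j, iff r_ij >= threshold (mode="signed", default) or
    |r_ij| >= threshold (mode="absolute"). Missing correlations never form
    edges. The node list is every mediator in the matrix.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if mode not in ("signed", "absolute"):
        raise ValueError(f"unknown mode: {mode}")
    vals = corr.to_numpy()
    if corr.shape[0] != corr.shape[1] or not np.allclose(
        vals, vals.T, equal_nan=True
    ):
        raise ValueError("correlation matrix must be square and symmetric")
    nodes = tuple(corr.columns)
    edges: dict[tuple[str, str], float] = {}
    edge_n: dict[tuple[str, str], int] = {}
    for i, j in itertools.combinations(range(len(nodes)), 2):
        r = vals[i, j]
        if np.isnan(r):
            continue
        score = abs(r) if mode == "absolute" else r
        if score >= threshold:
            key = (nodes[i], nodes[j])
            edges[key] = float(r)
            if counts is not None:
                edge_n[key] = int(counts.iloc[i, j])
    return CorrelationNetwork(
        group=group,
        window=window if window is not None else AnalysisWindow(0.0, np.inf, "all"),
        nodes=nodes,
        edges=edges,
        threshold=threshold,
        mode=mode,
        edge_n=edge_n,
    )


def network_density(
    network: CorrelationNetwork, node_rule: str = "connected"
) -> DensityValue:
    """Density = E * N / (N (N-1) / 2) = 2E / (N - 1).

    ``node_rule="connected"`` (default) counts only nodes with degree >= 1
    — the size of the active network; ``node_rule="all"`` counts every
    mediator in the matrix. Returns 0 when E = 0 or N < 2.
    """
    e = network.n_edges
    if node_rule == "connected":
        n = sum(1 for d in network.degree().values() if d >= 1)
    elif node_rule == "all":
        n = len(network.nodes)
    else:
        raise ValueError(f"unknown node_rule: {node_rule}")
    if e == 0 or n < 2:
        dens = 0.0
    else:
        dens = e * n / (n * (n - 1) / 2.0)
    return DensityValue(
        group=network.group, window=network.window.label, E=e, N=n,
        density=float(dens),
    )


def compare_networks(
    net_a: CorrelationNetwork, net_b: CorrelationNetwork
) -> dict:
    """Edge-set overlap between two networks on the same node universe.

    Returns shared edges, edges unique to each, and the Jaccard index
    (|intersection| / |union|, 0 when both are empty by convention).
    """
    if set(net_a.nodes) != set(net_b.nodes):
        raise ValueError("networks have mismatched node universes")
    ea, eb = set(net_a.edges), set(net_b.edges)
    union = ea | eb
    inter = ea & eb
    return {
        "shared": sorted(inter),
        "unique_a": sorted(ea - eb),
        "unique_b": sorted(eb - ea),
        "jaccard": (len(inter) / len(union)) if union else 0.0,
    }


class DynamicNetworkAnalysis:
    """DyNA model over a longitudinal mediator table.

    Parameters
    ----------
    samples
        Long-format draws (patient_id, time_h, mediator, value).
    groups
        patient_id -> stratum label.
    windows, threshold, method, mode, node_rule, min_pairs
        Analysis settings; defaults are the three adjacent 8 h windows of
        the first day, Pearson correlation of log10 window means, and a
        signed r >= 0.7 edge rule.
    """

    def __init__(
        self,
        samples: pd.DataFrame,
        groups: Mapping[str, str] | pd.Series,
        windows: Sequence[AnalysisWindow] = DEFAULT_WINDOWS,
        threshold: float = 0.7,
        method: str = "pearson",
        mode: str = "signed",
        node_rule: str = "connected",
        min_pairs: int = 8,
        log10: bool = True,
    ):
        self.samples = samples
        self.groups = dict(groups)
        self.windows = tuple(windows)
        self.threshold = threshold
        self.method = method
        self.mode = mode
        self.node_rule = node_rule
        self.min_pairs = min_pairs
        self.log10 = log10

    def fit(self) -> "DynamicNetworkResults":
        by_group: dict[str, list[str]] = {}
        for pid, grp in self.groups.items():
            by_group.setdefault(grp, []).append(pid)
        networks: dict[tuple[str, str], CorrelationNetwork] = {}
        densities: list[DensityValue] = []
        for grp in sorted(by_group):
            for win in self.windows:
                mat = window_patient_matrix(
                    self.samples, win, by_group[grp],
                    log10=self.log10, min_pairs=self.min_pairs,
                )
                notna = mat.notna().to_numpy().astype(int)
                counts = pd.DataFrame(
                    notna.T @ notna, index=mat.columns, columns=mat.columns
                )
                corr = correlation_matrix(mat, self.method, self.min_pairs)
                net = build_network(
                    corr, self.threshold, self.mode,
                    group=grp, window=win, counts=counts,
                )
                networks[(grp, win.label)] = net
                densities.append(network_density(net, self.node_rule))
        return DynamicNetworkResults(
            model=self, networks=networks, densities=densities
        )


@dataclass
class DynamicNetworkResults:
    """Fitted DyNA: one thresholded network plus density per
    (stratum, window)."""

    model: DynamicNetworkAnalysis
    networks: dict[tuple[str, str], CorrelationNetwork]
    densities: list[DensityValue]

    def density_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(d.group, d.window, d.E, d.N, d.density) for d in self.densities],
            columns=["group", "window", "edges", "nodes", "density"],
        )

    def edge_table(self) -> pd.DataFrame:
        tables = [t for net in self.networks.values()
                  if len(t := net.edge_table())]
        if not tables:
            return pd.DataFrame(
                columns=["mediator_a", "mediator_b", "r", "n_patients",
                         "group", "window"]
            )
        return pd.concat(tables, ignore_index=True)

    def compare(self, group_a: str, group_b: str, window: str) -> dict:
        return compare_networks(
            self.networks[(group_a, window)], self.networks[(group_b, window)]
        )

    def summary(self) -> str:
        lines = [
            "Dynamic network analysis "
            f"(r >= {self.model.threshold:g}, {self.model.method}, "
            f"node rule: {self.model.node_rule})",
            self.density_table().to_string(
                index=False, formatters={"density": "{:.2f}".format}
            ),
        ]
        return "\n".join(lines)


def dyna_run(
    samples: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    windows: Sequence[AnalysisWindow] = DEFAULT_WINDOWS,
    threshold: float = 0.7,
    **kwargs,
) -> DynamicNetworkResults:
    """One-call DyNA: fit networks and densities for every (group, window)."""
    return DynamicNetworkAnalysis(
        samples, groups, windows=windows, threshold=threshold, **kwargs
    ).fit()
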