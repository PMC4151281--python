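"""Markov clustering (MCL) with an inflation sweep.

A behavioural comparator for automatic orthology clustering: the
similarity graph is clustered by plain Markov clustering at a panel of
inflation values, and the resulting partitions are cross-tabulated
against a reference grouping.  This is deliberately plain MCL — the
species-aware edge normalisation of OrthoMCL-style tools is not
reproduced — so it probes the *behaviour* of flow clustering on the
family graph (granularity versus inflation), not any particular tool's
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .similarity import SimilarityHit

DEFAULT_INFLATIONS = (1.5, 5.0, 8.0, 10.0, 12.0, 14.0)
LOG_EVALUE_CAP = 200.0


@dataclass(frozen=True)
class MCLParams:
    inflation: float = 1.5
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iter: int = 200
    convergence_tol: float = 1e-8
    evalue_cutoff: float = 1e-10

    def __post_init__(self):
        if self.inflation < 1:
            raise ValueError("inflation must be >= 1")
        if not (0 < self.prune_threshold < 1):
            raise ValueError("prune threshold must be in (0, 1)")


@dataclass
class Partition:
    clusters: list[frozenset[str]] = field(default_factory=list)
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, int]:
        return {node: i for i, cl in enumerate(self.clusters) for node in cl}


def build_graph(hits: list[SimilarityHit], params: MCLParams = MCLParams(),
                weight_mode: str = "evalue") -> nx.Graph:
    """Build the weighted similarity graph.

    ``weight_mode='evalue'``: keep edges with e-value <= cutoff, weight
    ``-log10(evalue)`` capped at 200 (e-value 0 maps to the cap).
    ``weight_mode='bits'``: keep every edge, weight = bit score.
    Asymmetric hit directions are symmetrised by taking the larger
    weight; every node gets a self-loop at its maximum incident weight.
    """
    g = nx.Graph()
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if weight_mode == "evalue":
            if h.evalue is None:
                raise ValueError(
                    f"hit {h.query_id}->{h.subject_id} lacks an e-value; "
                    "ingest tabular hits or use weight_mode='bits'"
                )
            if h.evalue > params.evalue_cutoff:
                g.add_node(h.query_id)
                g.add_node(h.subject_id)
                continue
            w = LOG_EVALUE_CAP if h.evalue == 0 else min(
                LOG_EVALUE_CAP, -np.log10(h.evalue))
        elif weight_mode == "bits":
            w = h.bit_score
        else:
            raise ValueError(f"unknown weight_mode {weight_mode!r}")
        prev = g.edges.get((h.query_id, h.subject_id), {}).get("weight", -np.inf)
        if w > prev:
            g.add_edge(h.query_id, h.subject_id, weight=w)
    for node in list(g.nodes):
        incident = [d["weight"] for u, v, d in g.edges(node, data=True) if u != v]
        loop = max(incident) if incident else 1.0
        g.add_edge(node, node, weight=loop)
    return g


def mcl(graph: nx.Graph, params: MCLParams = MCLParams(),
        validate: bool = False) -> Partition:
    """Markov clustering of a weighted graph.

    The column-stochastic transition matrix is alternately expanded
    (matrix power), inflated (elementwise power, then column
    renormalisation) and pruned until the iteration is stationary;
    clusters are read from the attractor rows (positive diagonal mass),
    with overlapping attractor supports merged.  Non-convergence within
    ``max_iter`` returns the current partition with ``converged=False``.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return Partition(clusters=[])
    m = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    col = m.sum(axis=0)
    col[col == 0] = 1.0
    m = m / col

    converged = False
    for _ in range(params.max_iter):
        expanded = np.linalg.matrix_power(m, params.expansion)
        inflated = expanded ** params.inflation
        inflated[inflated < params.prune_threshold] = 0.0
        col = inflated.sum(axis=0)
        zero = col == 0
        if zero.any():  # pruned-out column: restore self transition
            inflated[zero, zero] = 1.0
            col = inflated.sum(axis=0)
        inflated /= col
        if validate and not np.allclose(inflated.sum(axis=0), 1.0, atol=1e-9):
            raise AssertionError("column stochasticity lost after inflation")
        if np.abs(inflated - m).max() < params.convergence_tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        warnings.warn("MCL did not converge within max_iter")

    attractors = [i for i in range(len(nodes)) if m[i, i] > params.prune_threshold]
    supports = [frozenset(np.nonzero(m[i] > params.prune_threshold)[0])
                for i in attractors]
    clusters: list[set[int]] = []
    for sup in supports:
        merged = set(sup)
        keep = []
        for cl in clusters:
            if cl & merged:
                merged |= cl
            else:
                keep.append(cl)
        keep.append(merged)
        clusters = keep
    covered = set().union(*clusters) if clusters else set()
    for i in range(len(nodes)):  # orphans (fully pruned rows) as singletons
        if i not in covered:
            clusters.append({i})
    clusters_named = sorted(
        (frozenset(nodes[i] for i in cl) for cl in clusters), key=min)
    return Partition(clusters=clusters_named, converged=converged)


def inflation_sweep(graph: nx.Graph,
                    inflations: tuple[float, ...] = DEFAULT_INFLATIONS,
                    params: MCLParams = MCLParams()
                    ) -> list[tuple[float, int, Partition]]:
    """Cluster the graph at each inflation value (granularity sweep)."""
    out = []
    for infl in inflations:
        p = MCLParams(inflation=infl, expansion=params.expansion,
                      prune_threshold=params.prune_threshold,
                      max_iter=params.max_iter,
                      convergence_tol=params.convergence_tol,
                      evalue_cutoff=params.evalue_cutoff)
        part = mcl(graph, p)
        out.append((infl, part.n_clusters, part))
    return out


def cross_tab(partition: Partition, labels_of: dict[str, str]) -> pd.DataFrame:
    """Contingency table of MCL clusters (rows) vs reference labels."""
    records = []
    for i, cl in enumerate(partition.clusters):
        for node in cl:
            records.append((f"C{i}", labels_of.get(node, "?")))
    df = pd.DataFrame(records, columns=["cluster", "label"])
    return pd.crosstab(df["cluster"], df["label"])
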