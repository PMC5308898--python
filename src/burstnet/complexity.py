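"""The directed burst-sequence graph and the network complexity score.

Each node is a catalog entry (a distinct network burst position); a directed
edge X -> Y is added whenever, in some ROI's sequence, burst Y immediately
followed burst X.  Edges are deduplicated across ROIs, so any number of ROIs
sharing one identical sequence produce a simple chain.

The canonical score averages the mean out-degree over nodes that have at
least one outgoing edge with the mean in-degree over nodes that have at
least one incoming edge:

    out_ratio = n_edges / |{v : outdeg(v) >= 1}|
    in_ratio  = n_edges / |{v : indeg(v)  >= 1}|
    score     = (out_ratio + in_ratio) / 2

A movie whose ROIs all share the same burst sequence yields a chain and the
baseline score 1; the score rises exactly when ROIs share some bursts but
not all, so nodes accumulate extra incoming or outgoing edges.  A stricter
literal variant — the fraction of nodes with more than one outgoing
(incoming) edge, which is 0 rather than 1 for a chain — is available as
``variant="fraction"`` for comparison.  A graph with no edges has no
defined score and is reported as not computable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class ComplexityResult:
    """Complexity score with its in/out components; ``score`` is None when
    the graph has no edges (``computable`` False)."""

    out_ratio: float | None
    in_ratio: float | None
    score: float | None
    n_nodes: int
    n_edges: int
    variant: str = "degree"

    @property
    def computable(self) -> bool:
        return self.score is not None


def build_graph(sequences: Mapping[int, Sequence[int]]) -> nx.DiGraph:
    """Directed burst-adjacency graph from per-ROI catalog-id sequences.

    For every ROI, consecutive sequence entries (X, Y) contribute the edge
    X -> Y; the edge set is deduplicated across ROIs.  Every id appearing in
    any sequence becomes a node, so isolated bursts are retained as
    edge-less nodes.
    """
    g = nx.DiGraph()
    for seq in sequences.values():
        g.add_nodes_from(seq)
        for x, y in zip(seq, seq[1:]):
            if x != y:
                g.add_edge(x, y)
    return g


def complexity_score(graph: nx.DiGraph, variant: str = "degree") -> ComplexityResult:
    """Score a burst-adjacency graph (see the module docstring for the formula)."""
    if variant not in ("degree", "fraction"):
        raise ValueError(f"unknown variant {variant!r}; use 'degree' or 'fraction'")
    n_nodes = graph.number_of_nodes()
    n_edges = graph.number_of_edges()
    if n_edges == 0:
        return ComplexityResult(out_ratio=None, in_ratio=None, score=None,
                                n_nodes=n_nodes, n_edges=0, variant=variant)
    if variant == "degree":
        out_nodes = sum(1 for _, d in graph.out_degree() if d >= 1)
        in_nodes = sum(1 for _, d in graph.in_degree() if d >= 1)
        out_ratio = n_edges / out_nodes
        in_ratio = n_edges / in_nodes
    else:
        out_ratio = sum(1 for _, d in graph.out_degree() if d > 1) / n_nodes
        in_ratio = sum(1 for _, d in graph.in_degree() if d > 1) / n_nodes
    return ComplexityResult(out_ratio=out_ratio, in_ratio=in_ratio,
                            score=(out_ratio + in_ratio) / 2.0,
                            n_nodes=n_nodes, n_edges=n_edges, variant=variant)


def score_sequences(sequences: Mapping[int, Sequence[int]],
                    variant: str = "degree") -> ComplexityResult:
    """Convenience: build the graph and score it in one call."""
    return complexity_score(build_graph(sequences), variant=variant)


def compare_groups_ks(scores_a, scores_b) -> tuple[float, float, str]:
    """Two-sided two-sample Kolmogorov-Smirnov test between score groups.

    Returns (D, p, method); the exact p-value is used for small samples
    (combined n <= 25), the asymptotic approximation otherwise.
    """
    from scipy import stats

    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if a.size + b.size <= 25 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue), method


def bootstrap_median_se(scores, n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Median and its bootstrap standard error.

    The SE is the standard deviation of medians over ``n_boot`` resamples
    with replacement; deterministic given ``seed``.
    """
    x = np.asarray(scores, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    medians = np.median(x[idx], axis=1)
    return float(np.median(x)), float(np.std(medians, ddof=1))
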