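"""One-mode projections, similarity, and the spanning-forest communities.

The projection collapses the bipartite panel onto one node set as a Gram
matrix (``C = W W^T`` for countries); the Dice-type similarity
``S_ij = 2 C_ij / (C_ii + C_jj)`` lies in [0, 1]. The forest is grown by
scanning candidate edges in decreasing weight and accepting an edge only
while at least one endpoint is still isolated, which splits the node set
into disconnected sub-trees (tightly correlated communities) instead of
a single spanning tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from foodnet.panel import BipartitePanel

logger = logging.getLogger(__name__)

DEFAULT_MIN_COMPONENT = 4  # sub-trees below this size are not reported


@dataclass
class ProjectionMatrix:
    side: str  # "country" or "product"
    source: str  # "binary" or "weighted"
    labels: list[str]
    C: np.ndarray  # symmetric Gram matrix


@dataclass
class SimilarityMatrix:
    labels: list[str]
    S: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]


@dataclass
class Forest:
    nodes: list[str]
    edges: list[tuple[str, str, float]]  # in acceptance order
    components: list[list[str]] = field(default_factory=list)

    def component_of(self) -> dict[str, int]:
        return {node: idx for idx, comp in enumerate(self.components) for node in comp}


def project(panel: BipartitePanel, side: str = "country", source: str = "weighted") -> ProjectionMatrix:
    """One-mode Gram projection of a panel.

    For the binary source the diagonal equals the side's degrees and
    off-diagonal entries count shared partners; for the weighted source
    entries are inner products of per-capita volume vectors.
    """
    if source == "weighted":
        X = panel.W
    elif source == "binary":
        X = panel.M.astype(float)
    else:
        raise ValueError(f"source must be 'binary' or 'weighted', got {source!r}")
    if side == "country":
        labels = panel.countries
    elif side == "product":
        labels = panel.products
        X = X.T
    else:
        raise ValueError(f"side must be 'country' or 'product', got {side!r}")
    return ProjectionMatrix(side=side, source=source, labels=list(labels), C=X @ X.T)


def similarity(proj: ProjectionMatrix) -> SimilarityMatrix:
    """Dice-type similarity ``S_ij = 2 C_ij / (C_ii + C_jj)``.

    Rows with a zero diagonal (no production at all) are dropped with a
    warning; the diagonal of the result is forced to exactly 1.
    """
    diag = np.diag(proj.C).astype(float)
    keep = diag > 0
    if not keep.any():
        logger.warning("all-zero projection: empty similarity matrix")
        return SimilarityMatrix(labels=[], S=np.empty((0, 0)))
    if not keep.all():
        dropped = [lab for lab, k in zip(proj.labels, keep) if not k]
        logger.warning("dropping %d zero-diagonal nodes from similarity: %s",
                       len(dropped), ", ".join(dropped))
    C = proj.C[np.ix_(keep, keep)]
    d = diag[keep]
    S = 2.0 * C / (d[:, None] + d[None, :])
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(labels=[lab for lab, k in zip(proj.labels, keep) if k], S=S)


def msf(sim: SimilarityMatrix, rule: str = "isolated") -> Forest:
    """Greedy descending-weight spanning forest.

    Candidate edges are the strictly positive off-diagonal similarities,
    sorted by decreasing weight with ties broken by the lexicographic
    label pair (deterministic output). Under the default ``"isolated"``
    rule an edge is accepted only if at least one endpoint has no edge
    yet, which yields disconnected sub-trees; ``"kruskal"`` rejects only
    same-component edges and returns maximum spanning trees per
    connected cluster (for comparison).
    """
    if rule not in {"isolated", "kruskal"}:
        raise ValueError(f"rule must be 'isolated' or 'kruskal', got {rule!r}")
    labels = sim.labels
    n = len(labels)
    candidates = []
    for i in range(n):
        for j in range(i + 1, n):
            w = float(sim.S[i, j])
            if w > 0.0:  # positivity floor: zero-weight edges never enter
                a, b = sorted((labels[i], labels[j]))
                candidates.append((a, b, w))
    candidates.sort(key=lambda e: (-e[2], e[0], e[1]))

    graph = nx.Graph()
    graph.add_nodes_from(labels)
    accepted: list[tuple[str, str, float]] = []
    if rule == "isolated":
        degree = dict.fromkeys(labels, 0)
        for a, b, w in candidates:
            if degree[a] == 0 or degree[b] == 0:
                accepted.append((a, b, w))
                degree[a] += 1
                degree[b] += 1
                graph.add_edge(a, b, weight=w)
    else:
        for a, b, w in candidates:
            if not nx.has_path(graph, a, b):
                accepted.append((a, b, w))
                graph.add_edge(a, b, weight=w)

    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return Forest(nodes=list(labels), edges=accepted, components=comps)


def components(forest: Forest, min_size: int = DEFAULT_MIN_COMPONENT) -> list[dict]:
    """Sub-trees of at least ``min_size`` nodes, largest first.

    Each entry carries the member labels and the accepted edges internal
    to the sub-tree.
    """
    member_of = forest.component_of()
    out = []
    for idx, comp in enumerate(forest.components):
        if len(comp) < min_size:
            continue
        edges = [e for e in forest.edges if member_of[e[0]] == idx]
        out.append({"members": comp, "size": len(comp), "edges": edges})
    return out


def import_composition(panel: BipartitePanel, country: str, top_k: int = 3) -> list[tuple[str, float]]:
    """Top ``top_k`` import shares for one country.

    Shares are the country's weighted row normalized to sum to 1, sorted
    decreasing (ties broken by product label). Raises on a zero-import
    country.
    """
    row = panel.W[panel.country_index(country)]
    total = row.sum()
    if total <= 0:
        raise ValueError(f"country {country!r} has no imports in {panel.year}")
    shares = row / total
    ranked = sorted(zip(panel.products, shares), key=lambda t: (-t[1], t[0]))
    ranked = [(p, float(s)) for p, s in ranked if s > 0]
    return ranked[: min(top_k, len(ranked))]


# ---------------------------------------------------------------------------
# exports


def forest_to_tsv(forest: Forest, path: str | Path, header: dict | None = None) -> None:
    member_of = forest.component_of()
    lines = [f"# {k}={v}" for k, v in (header or {}).items()]
    lines.append("node_i\tnode_j\tweight\tcomponent_id")
    for a, b, w in forest.edges:
        lines.append(f"{a}\t{b}\t{w!r}\t{member_of[a]}")
    Path(path).write_text("\n".join(lines) + "\n")


def forest_to_dot(forest: Forest, path: str | Path) -> None:
    lines = ["graph forest {"]
    for node in forest.nodes:
        lines.append(f'  "{node}";')
    for a, b, w in forest.edges:
        lines.append(f'  "{a}" -- "{b}" [label="{w:.4f}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
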