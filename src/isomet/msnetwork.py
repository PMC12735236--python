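"""Feature-based molecular networking.

Spectra become nodes; edges carry the modified cosine similarity, a
spectral match that lets fragment peaks pair either directly or shifted
by the precursor-mass difference, so structural analogs (e.g. an
acetylated congener) still align. Edge filtering follows the standard
FBMN workflow: a cosine threshold and a minimum matched-peak count, a
mutual top-K rule, and a molecular-family size cap enforced by removing
the weakest edges of any oversized connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .spectra_io import MsmsSpectrum

__all__ = [
    "NetworkParams",
    "NetworkEdge",
    "MolecularNetwork",
    "modified_cosine",
    "build_network",
    "network_stats",
    "write_graphml",
    "write_edge_list",
]


@dataclass(frozen=True)
class NetworkParams:
    """FBMN parameters (defaults follow the workflow's published settings)."""

    fragment_tol: float = 0.02  # Da
    precursor_tol: float = 0.01  # Da
    cosine_min: float = 0.7  # edges must score strictly above this
    min_matched_peaks: int = 5  # "more than four" matching peaks
    top_k: int = 10
    max_family_size: int = 100

    def __post_init__(self) -> None:
        if min(self.fragment_tol, self.precursor_tol) <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.cosine_min <= 1):
            raise ValueError("cosine_min must be in (0, 1]")
        if min(self.min_matched_peaks, self.top_k, self.max_family_size) <= 0:
            raise ValueError("count parameters must be positive")


@dataclass(frozen=True)
class NetworkEdge:
    id_a: str
    id_b: str
    cosine: float
    n_matched: int


@dataclass
class MolecularNetwork:
    """Nodes (feature ids), retained edges, and component statistics."""

    nodes: list[str]
    edges: list[NetworkEdge]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.id_a, e.id_b, cosine=e.cosine, n_matched=e.n_matched)
        return g

    def components(self) -> list[set[str]]:
        return sorted(
            (set(c) for c in nx.connected_components(self.graph())),
            key=lambda c: (-len(c), min(c)),
        )

    @property
    def n_singletons(self) -> int:
        degree = {n: 0 for n in self.nodes}
        for e in self.edges:
            degree[e.id_a] += 1
            degree[e.id_b] += 1
        return sum(1 for d in degree.values() if d == 0)


def modified_cosine(
    a: MsmsSpectrum,
    b: MsmsSpectrum,
    fragment_tol: float = 0.02,
    precursor_tol: float = 0.01,
) -> tuple[float, int]:
    """Modified cosine similarity between two spectra.

    A peak of ``a`` may pair with a peak of ``b`` either directly
    (offset 0) or shifted by the precursor-mass difference
    delta = precursor(b) - precursor(a), within ``fragment_tol``. When
    |delta| <= ``precursor_tol`` the spectra are treated as same-mass and
    only direct matching applies. Each peak is used at most once; pairs
    are chosen greedily by descending product of square-root-scaled
    intensities (ties: lower m/z in ``a``, then in ``b``). The score is
    the sum of matched sqrt-intensity products after L2-normalizing each
    spectrum's sqrt-intensity vector, hence symmetric and in [0, 1].

    Returns ``(score, n_matched)``.
    """
    if len(a.peaks) == 0 or len(b.peaks) == 0:
        raise ValueError("modified_cosine requires non-empty peak lists")
    delta = b.precursor_mz - a.precursor_mz
    offsets = [0.0] if abs(delta) <= precursor_tol else [0.0, delta]

    sa = np.sqrt(a.intensity)
    sb = np.sqrt(b.intensity)
    norm = float(np.linalg.norm(sa) * np.linalg.norm(sb))
    if norm == 0.0:
        return 0.0, 0

    # candidate pairs across both offsets
    cands: list[tuple[float, float, float, int, int]] = []
    mzb = b.mz
    for off in offsets:
        shifted = a.mz + off
        lo = np.searchsorted(mzb, shifted - fragment_tol, side="left")
        hi = np.searchsorted(mzb, shifted + fragment_tol, side="right")
        for i in range(len(shifted)):
            for j in range(lo[i], hi[i]):
                cands.append((-(sa[i] * sb[j]), a.mz[i], mzb[j], i, j))
    cands.sort()

    used_a = np.zeros(len(sa), dtype=bool)
    used_b = np.zeros(len(sb), dtype=bool)
    score = 0.0
    n_matched = 0
    for negprod, _, _, i, j in cands:
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        score += -negprod
        n_matched += 1
    return min(score / norm, 1.0), n_matched


def _mutual_top_k(edges: list[NetworkEdge], k: int) -> list[NetworkEdge]:
    """Keep an edge iff each endpoint ranks within the other's top-k neighbors.

    Neighbor ranking: cosine descending, partner id ascending.
    """
    nbrs: dict[str, list[tuple[float, str]]] = {}
    for e in edges:
        nbrs.setdefault(e.id_a, []).append((e.cosine, e.id_b))
        nbrs.setdefault(e.id_b, []).append((e.cosine, e.id_a))
    topk: dict[str, set[str]] = {}
    for node, lst in nbrs.items():
        lst.sort(key=lambda t: (-t[0], t[1]))
        topk[node] = {partner for _, partner in lst[:k]}
    return [
        e
        for e in edges
        if e.id_b in topk.get(e.id_a, set()) and e.id_a in topk.get(e.id_b, set())
    ]


def _cap_family_size(
    nodes: Sequence[str], edges: list[NetworkEdge], max_size: int
) -> list[NetworkEdge]:
    """Remove the lowest-cosine edge of any oversized component until all fit.

    Ties broken by lexicographically smallest (id_a, id_b); deterministic.
    """
    edges = list(edges)
    while True:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for e in edges:
            g.add_edge(e.id_a, e.id_b)
        oversized = [c for c in nx.connected_components(g) if len(c) > max_size]
        if not oversized:
            return edges
        big: set[str] = set().union(*oversized)
        victim = min(
            (e for e in edges if e.id_a in big and e.id_b in big),
            key=lambda e: (e.cosine, e.id_a, e.id_b),
        )
        edges.remove(victim)


def build_network(
    spectra: Sequence[MsmsSpectrum], params: NetworkParams = NetworkParams()
) -> MolecularNetwork:
    """All-pairs modified cosine followed by the three FBMN filters.

    1. score every spectrum pair;
    2. keep edges with cosine strictly above ``cosine_min`` and at least
       ``min_matched_peaks`` matched peaks;
    3. mutual top-K pruning;
    4. family-size capping (weakest-edge removal per oversized component).
    """
    ids = [s.feature_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("feature ids must be unique")
    edges: list[NetworkEdge] = []
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            a, b = spectra[i], spectra[j]
            if len(a.peaks) == 0 or len(b.peaks) == 0:
                continue
            score, n = modified_cosine(a, b, params.fragment_tol, params.precursor_tol)
            if score > params.cosine_min and n >= params.min_matched_peaks:
                ia, ib = sorted((a.feature_id, b.feature_id))
                edges.append(NetworkEdge(ia, ib, score, n))
    edges.sort(key=lambda e: (e.id_a, e.id_b))
    edges = _mutual_top_k(edges, params.top_k)
    edges = _cap_family_size(ids, edges, params.max_family_size)
    return MolecularNetwork(nodes=list(ids), edges=edges)


def network_stats(net: MolecularNetwork) -> tuple[int, int, dict[int, int]]:
    """(n_nodes, n_singletons, component-size histogram).

    Singletons are degree-0 nodes; the histogram counts connected
    components of each size >= 2 plus the singleton bin (size 1).
    """
    hist: dict[int, int] = {}
    for comp in net.components():
        hist[len(comp)] = hist.get(len(comp), 0) + 1
    return len(net.nodes), net.n_singletons, hist


def write_graphml(
    net: MolecularNetwork,
    path: str | Path,
    node_attrs: dict[str, dict[str, object]] | None = None,
) -> None:
    """Export the network as GraphML with deterministic element order.

    ``node_attrs`` may carry per-node metadata (m/z, RT, per-sample
    shares for pie-chart rendering in viewers such as Cytoscape).
    """
    g = nx.Graph()
    for node in sorted(net.nodes):
        attrs = dict(node_attrs.get(node, {})) if node_attrs else {}
        g.add_node(node, **attrs)
    for e in sorted(net.edges, key=lambda e: (e.id_a, e.id_b)):
        g.add_edge(e.id_a, e.id_b, cosine=round(e.cosine, 6), n_matched=e.n_matched)
    nx.write_graphml(g, Path(path))


def write_edge_list(net: MolecularNetwork, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {"id_a": e.id_a, "id_b": e.id_b, "cosine": round(e.cosine, 6), "n_matched": e.n_matched}
            for e in sorted(net.edges, key=lambda e: (e.id_a, e.id_b))
        ],
        columns=["id_a", "id_b", "cosine", "n_matched"],
    )
    df.to_csv(Path(path), index=False)
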